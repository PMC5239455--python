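"""ROC dichotomization, Kaplan-Meier, Cox models and Fisher tests.

Implements the survival side of the pipeline: FRET efficiency is
dichotomized at the Youden-optimal ROC threshold (sensitivity +
specificity - 1 maximized over all candidate cutpoints, ties toward the
lower threshold), distant-metastasis-free survival is summarized by
Kaplan-Meier curves and univariate / full multivariate Cox proportional-
hazards models at 5- and 10-year horizons, and FRET-high/low group
composition is compared with Fisher's exact test.

Kaplan-Meier and Cox fitting are delegated to lifelines (Efron tie
handling); the test-suite cross-checks them against hand product-limit
computation and a grid-search partial-likelihood oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

__all__ = [
    "ROCResult",
    "CoxResult",
    "KMCurve",
    "CohortAnalysisConfig",
    "youden_threshold",
    "dichotomize_fret",
    "apply_horizon",
    "km_estimate",
    "cox_fit",
    "fisher_exact",
    "roc_labels",
    "run_cohort_analysis",
]


@dataclass(frozen=True)
class ROCResult:
    """Full ROC curve with the Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    youden_threshold: float
    youden_j: float
    auc: float


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t), right-continuous step evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratios with Wald 95% CIs from a proportional-hazards fit."""

    summary: pd.DataFrame  # index covariate; log_hr, hr, ci_low, ci_high, p
    n_used: int
    n_events: int
    horizon: float | None
    model_type: str  # "univariate" | "multivariate"
    unreliable: bool = False  # separation / convergence trouble


# ---------------------------------------------------------------------------


def youden_threshold(scores, labels) -> ROCResult:
    """Exhaustive-scan ROC with the Youden-index-optimal cutpoint.

    Candidate thresholds are the midpoints between consecutive sorted unique
    scores; classification is score > threshold.  Ties in J are broken toward
    the lower threshold.  AUC is the Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("at least 2 distinct scores are required")
    cand = (uniq[:-1] + uniq[1:]) / 2.0
    pred = scores[None, :] > cand[:, None]
    sens = (pred & (labels == 1)).sum(axis=1) / n_pos
    spec = (~pred & (labels == 0)).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (=lowest) threshold on ties
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return ROCResult(
        thresholds=cand,
        sensitivities=sens,
        specificities=spec,
        youden_threshold=float(cand[best]),
        youden_j=float(j[best]),
        auc=float(auc),
    )


def dichotomize_fret(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Add a ``fret_high`` flag: strictly fret_eff > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = table.copy()
    out["fret_high"] = (out["fret_eff"] > threshold).astype(int)
    return out


def apply_horizon(times, events, horizon: float | None):
    """Administratively censor at the horizon (times capped, events zeroed)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if horizon is None:
        return times, events
    capped = np.minimum(times, horizon)
    ev = np.where(times <= horizon, events, 0)
    return capped, ev


def km_estimate(times, events, horizon: float | None = None) -> KMCurve:
    """Product-limit survival estimate, optionally horizon-censored first."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    t, e = apply_horizon(times, events, horizon)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n=int(times.size),
        n_events=int(np.sum(e)),
    )


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    horizon: float | None = None,
    duration_col: str = "time_years",
    event_col: str = "event",
    model_type: str = "multivariate",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) on complete cases.

    Separation / monotone-likelihood trouble is flagged ``unreliable`` rather
    than raised, mirroring how such fits are reported with a caveat.
    """
    cols = [duration_col, event_col] + list(covariates)
    df = table[cols].dropna().copy()
    t, e = apply_horizon(df[duration_col], df[event_col], horizon)
    df[duration_col] = t
    df[event_col] = e
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events after horizon censoring")
    cph = CoxPHFitter()
    unreliable = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit failed to converge: {exc}") from exc
        unreliable = any("convergence" in str(w.message).lower() or "collinear" in str(w.message).lower() for w in caught)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "log_hr": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        n_used=len(df),
        n_events=n_events,
        horizon=horizon,
        model_type=model_type,
        unreliable=unreliable,
    )


def fisher_exact(table2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities no larger than the observed table's
    (scipy's two-sided rule; cross-checked by enumeration in the tests).
    """
    t = np.asarray(table2x2)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# full cohort analysis


@dataclass(frozen=True)
class CohortAnalysisConfig:
    """Options for :func:`run_cohort_analysis`.

    ``threshold='auto'`` selects the Youden cutpoint on event-within-
    ``roc_horizon`` labels (patients censored before the horizon without an
    event are excluded from labelling only); a float uses a fixed cutpoint.
    """

    threshold: float | str = "auto"
    roc_horizon: float = 10.0
    horizons: tuple[float, ...] = (5.0, 10.0)


# covariate groups of the multivariate model: name -> design columns
_DESIGN = {
    "fret": ["fret_high"],
    "her2": ["her2_pos"],
    "her3_loc": ["her3_cm", "her3_m"],
    "er": ["er_pos"],
    "pr": ["pr_pos"],
    "size": ["size_gt20"],
    "grade": ["grade3"],
    "nodes": ["nodes_1to3", "nodes_gt3"],
}


def _design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns with NaN for unavailable categories."""
    out = pd.DataFrame(index=df.index)
    out["time_years"] = df["time_years"].astype(float)
    out["event"] = df["event"].astype(int)
    if "fret_high" in df:
        out["fret_high"] = df["fret_high"].astype(float)
    out["her2_pos"] = df["her2_ihc"].map({"pos": 1.0, "neg": 0.0})
    out["her3_cm"] = df["her3_loc"].map({"C": 0.0, "C+M": 1.0, "M/M+C": 0.0})
    out["her3_m"] = df["her3_loc"].map({"C": 0.0, "C+M": 0.0, "M/M+C": 1.0})
    out["er_pos"] = df["er"].map({"pos": 1.0, "neg": 0.0})
    out["pr_pos"] = df["pr"].map({"pos": 1.0, "neg": 0.0})
    out["size_gt20"] = df["size_gt20"].astype(float)
    out["grade3"] = df["grade3"].astype(float)
    out["nodes_1to3"] = df["nodes_grp"].map({"0": 0.0, "1-3": 1.0, ">3": 0.0})
    out["nodes_gt3"] = df["nodes_grp"].map({"0": 0.0, "1-3": 0.0, ">3": 1.0})
    return out


def roc_labels(df: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Rows usable for ROC labelling and their binary outcome.

    Label 1: event within the horizon.  Label 0: event-free follow-up through
    the horizon.  Censored before the horizon without an event: excluded.
    """
    event_in = (df["event"] == 1) & (df["time_years"] <= horizon)
    followed = df["time_years"] >= horizon
    usable = event_in | followed
    out = df.loc[usable, ["fret_eff"]].copy()
    out["label"] = event_in[usable].astype(int)
    return out


def run_cohort_analysis(table: pd.DataFrame, config: CohortAnalysisConfig = CohortAnalysisConfig()) -> dict:
    """End-to-end cohort report: ROC threshold, KM, Cox, Fisher.

    Returns a nested dict: ``roc``, ``threshold``, ``group_counts``,
    ``km`` (per horizon, per grouping), ``cox_univariate`` and
    ``cox_multivariate`` (per horizon), ``fisher`` (FRET-high/low vs each
    binary covariate contrast).
    """
    report: dict = {}

    if config.threshold == "auto":
        lab = roc_labels(table, config.roc_horizon)
        roc = youden_threshold(lab["fret_eff"].to_numpy(), lab["label"].to_numpy())
        threshold = roc.youden_threshold
        report["roc"] = {
            "youden_threshold": roc.youden_threshold,
            "youden_j": roc.youden_j,
            "auc": roc.auc,
            "n_labelled": int(len(lab)),
        }
    else:
        threshold = float(config.threshold)
    report["threshold"] = threshold

    df = dichotomize_fret(table, threshold)
    report["group_counts"] = {
        "fret_high": int(df["fret_high"].sum()),
        "fret_low": int((1 - df["fret_high"]).sum()),
    }

    dm = _design_matrix(df)

    report["km"] = {}
    for horizon in config.horizons:
        by = {}
        for group_col, name in [("fret_high", "fret"), ("her2_pos", "her2")]:
            sub = dm.dropna(subset=[group_col])
            curves = {}
            for level, grp in sub.groupby(group_col):
                curves[f"{name}={int(level)}"] = km_estimate(grp["time_years"], grp["event"], horizon)
            by[name] = curves
        report["km"][horizon] = by

    report["cox_univariate"] = {}
    report["cox_multivariate"] = {}
    all_cols = [c for cols in _DESIGN.values() for c in cols]
    for horizon in config.horizons:
        uni = {}
        for name, cols in _DESIGN.items():
            try:
                uni[name] = cox_fit(dm, cols, horizon, model_type="univariate")
            except ValueError as exc:
                uni[name] = {"error": str(exc)}
        report["cox_univariate"][horizon] = uni
        try:
            report["cox_multivariate"][horizon] = cox_fit(dm, all_cols, horizon, model_type="multivariate")
        except ValueError as exc:
            report["cox_multivariate"][horizon] = {"error": str(exc)}

    # Fisher association of FRET group with each binary contrast
    fisher = {}
    for name, col in [
        ("her2", "her2_pos"),
        ("er", "er_pos"),
        ("pr", "pr_pos"),
        ("size", "size_gt20"),
        ("grade", "grade3"),
        ("her3_loc_cm_vs_c", "her3_cm"),
        ("nodes_any_vs_none", None),
    ]:
        if col is None:
            x = dm[["nodes_1to3", "nodes_gt3"]].sum(axis=1)
        else:
            x = dm[col]
        sub = pd.DataFrame({"g": dm["fret_high"], "x": x}).dropna()
        tab = np.array(
            [
                [int(((sub.g == 1) & (sub.x == 1)).sum()), int(((sub.g == 1) & (sub.x == 0)).sum())],
                [int(((sub.g == 0) & (sub.x == 1)).sum()), int(((sub.g == 0) & (sub.x == 0)).sum())],
            ]
        )
        try:
            fisher[name] = fisher_exact(tab)
        except ValueError as exc:
            fisher[name] = {"error": str(exc)}
    report["fisher"] = fisher
    report["n_total"] = int(len(table))
    report["n_complete_cases"] = int(dm.dropna(subset=all_cols).shape[0])
    return report
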
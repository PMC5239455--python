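"""ROC/Youden, Kaplan-Meier, Cox and Fisher machinery against hand oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from herfret.cohort import (
    CohortAnalysisConfig,
    cox_fit,
    dichotomize_fret,
    fisher_exact,
    km_estimate,
    roc_labels,
    run_cohort_analysis,
    youden_threshold,
)
from herfret.synthetic import CohortSimConfig, simulate_cohort


from oracles import (  # noqa: E402
    cox_partial_loglik_no_ties,
    fisher_enumeration_oracle,
    youden_scan_oracle,
)


# ---------------------------------------------------------------------------
# Youden / ROC


def test_youden_perfectly_separable():
    res = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert res.youden_threshold == pytest.approx(0.5)
    assert res.youden_j == pytest.approx(1.0)
    assert res.auc == pytest.approx(1.0)


def test_youden_null_labels_give_low_j_and_auc_half():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=400)
    labels = rng.integers(0, 2, size=400)
    res = youden_threshold(scores, labels)
    assert res.auc == pytest.approx(0.5, abs=0.08)
    assert res.youden_j < 0.25


def test_youden_matches_exhaustive_scan_on_gaussian_mixture():
    rng = np.random.default_rng(7)
    scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
    labels = np.concatenate([np.zeros(100, int), np.ones(100, int)])
    res = youden_threshold(scores, labels)
    t_oracle, j_oracle = youden_scan_oracle(scores.tolist(), labels.tolist())
    assert res.youden_threshold == pytest.approx(t_oracle, abs=1e-12)
    assert res.youden_j == pytest.approx(j_oracle, abs=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 10_000))
def test_youden_equals_scan_oracle_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    scores = np.round(rng.normal(size=n), 2)
    labels = rng.integers(0, 2, size=n)
    if labels.sum() in (0, n) or len(set(scores)) < 2:
        return
    res = youden_threshold(scores, labels)
    t_oracle, j_oracle = youden_scan_oracle(scores.tolist(), labels.tolist())
    assert res.youden_threshold == pytest.approx(t_oracle, abs=1e-12)
    assert res.youden_j == pytest.approx(j_oracle, abs=1e-12)


def test_youden_rejects_single_class():
    with pytest.raises(ValueError, match="both classes"):
        youden_threshold([0.1, 0.2, 0.3], [1, 1, 1])


# ---------------------------------------------------------------------------
# dichotomization


def test_dichotomize_boundary_is_strict_greater():
    df = pd.DataFrame({"fret_eff": [8.55, 8.56, 8.57]})
    out = dichotomize_fret(df, 8.56)
    assert out["fret_high"].tolist() == [0, 0, 1]


def test_dichotomize_all_below_threshold():
    df = pd.DataFrame({"fret_eff": [1.0, 2.0]})
    assert dichotomize_fret(df, 5.0)["fret_high"].sum() == 0


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_hand_example():
    km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
    assert km.at(1.0) == pytest.approx(2.0 / 3.0)
    assert km.at(3.0) == pytest.approx(0.0)


def test_km_all_censored_stays_at_one():
    km = km_estimate([1.0, 2.0, 5.0], [0, 0, 0])
    assert km.at(5.0) == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_km_reduces_to_empirical_survival_without_censoring(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    times = np.round(rng.exponential(5.0, n), 3)
    km = km_estimate(times, np.ones(n, int))
    for t in times:
        assert km.at(t) == pytest.approx(np.mean(times > t), abs=1e-12)


def test_km_matches_exponential_closed_form():
    rng = np.random.default_rng(3)
    lam = 0.25
    times = rng.exponential(1.0 / lam, 10_000)
    km = km_estimate(times, np.ones(times.size, int))
    assert km.at(1.0 / lam) == pytest.approx(np.exp(-1.0), abs=0.02)


def test_km_rejects_empty_input():
    with pytest.raises(ValueError, match="empty"):
        km_estimate([], [])


# ---------------------------------------------------------------------------
# Cox


def _tiny_cox_df():
    # 6 subjects, binary covariate, distinct times (no ties)
    return pd.DataFrame(
        {
            "time_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
        }
    )


def test_cox_symmetric_groups_give_zero_loghr():
    df = pd.DataFrame(
        {
            "time_years": [1, 2, 3, 4, 1, 2, 3, 4],
            "event": [1, 1, 0, 1, 1, 1, 0, 1],
            "x": [0, 0, 0, 0, 1, 1, 1, 1],
        }
    )
    res = cox_fit(df, ["x"])
    assert res.summary.loc["x", "log_hr"] == pytest.approx(0.0, abs=1e-6)


def test_cox_matches_grid_search_partial_likelihood_oracle():
    df = _tiny_cox_df()
    res = cox_fit(df, ["x"])
    x, t, e = df["x"].to_numpy(), df["time_years"].to_numpy(), df["event"].to_numpy()
    opt = minimize_scalar(
        lambda b: -cox_partial_loglik_no_ties(b, x, t, e), bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10},
    )
    assert res.summary.loc["x", "log_hr"] == pytest.approx(opt.x, abs=1e-4)


def test_cox_zero_events_raises():
    df = _tiny_cox_df().assign(event=0)
    with pytest.raises(ValueError, match="no events"):
        cox_fit(df, ["x"])


def test_cox_complete_case_bookkeeping():
    df = _tiny_cox_df()
    df.loc[0, "x"] = np.nan
    res = cox_fit(df, ["x"])
    assert res.n_used == 5


# ---------------------------------------------------------------------------
# Fisher


def test_fisher_balanced_table_is_one():
    assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_diagonal_2x2_enumeration_value():
    assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1.0 / 3.0)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.integers(0, 10_000))
def test_fisher_matches_enumeration_and_transpose_symmetry(seed):
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 11, size=(2, 2))
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return
    p = fisher_exact(t)
    assert p == pytest.approx(fisher_enumeration_oracle(t.tolist()), abs=1e-9)
    assert p == pytest.approx(fisher_exact(t.T), abs=1e-12)


def test_fisher_rejects_zero_margin_and_bad_cells():
    with pytest.raises(ValueError, match="margin"):
        fisher_exact([[0, 0], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 2], [3, 4]])


# ---------------------------------------------------------------------------
# full report


def test_roc_labels_exclude_early_censored():
    df = pd.DataFrame(
        {
            "fret_eff": [1.0, 2.0, 3.0, 4.0],
            "time_years": [2.0, 12.0, 5.0, 11.0],
            "event": [1, 0, 0, 1],
        }
    )
    lab = roc_labels(df, horizon=10.0)
    # row 2 (censored at 5y, no event) is excluded; row 3's event is after 10y
    assert len(lab) == 3
    assert lab["label"].tolist() == [1, 0, 0]


def test_run_cohort_analysis_structure_and_bookkeeping():
    table = simulate_cohort(CohortSimConfig(n_patients=150, seed=9))
    rep = run_cohort_analysis(table, CohortAnalysisConfig())
    assert set(rep) >= {"roc", "threshold", "group_counts", "km", "cox_univariate", "cox_multivariate", "fisher"}
    assert rep["group_counts"]["fret_high"] + rep["group_counts"]["fret_low"] == 150
    assert rep["n_complete_cases"] < rep["n_total"]  # NA-bearing covariates
    for p in rep["fisher"].values():
        if isinstance(p, float):
            assert 0.0 <= p <= 1.0


def test_run_cohort_analysis_fixed_threshold_skips_roc():
    table = simulate_cohort(CohortSimConfig(n_patients=100, seed=2))
    rep = run_cohort_analysis(table, CohortAnalysisConfig(threshold=8.56))
    assert rep["threshold"] == 8.56
    assert "roc" not in rep
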
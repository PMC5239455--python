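"""Mass-action dimerization equilibria of the HER (ErbB) receptor family.

The HER receptors HER1..HER4 (E1..E4) form reversible homo- and heterodimers
E_ij.  At equilibrium each enabled pair satisfies

    [E_ij] * Kd_ij = [free_i] * [free_j]        (i != j)
    [E_ii] * Kd_ii = [free_i]^2                 (homodimer, statistical-factor
                                                 convention; conservation
                                                 counts 2*[E_ii])

together with mass conservation per receptor

    free_i + sum_{j != i} [E_ij] + 2*[E_ii] = total_i.

Two independent routes to the steady state are provided: an algebraic solver
on the free-monomer concentrations (damped fixed point with Newton polish)
and integration of the binding kinetics to stationarity (the oracle used in
cross-validation tests).

The population simulation draws per-patient receptor abundances from
zero-truncated normal distributions, solves each patient's equilibrium and
quantifies the correlation between the HER2-HER3 dimer [E23] and the total
HER2 / HER3 abundances — the decorrelation argument for why dimer level is
not a surrogate of receptor expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import pearsonr, spearmanr

from .errors import EquilibriumError

__all__ = [
    "RECEPTORS",
    "RateConstants",
    "EquilibriumState",
    "PopulationSimResult",
    "equilibrium_state",
    "solve_equilibrium_batch",
    "steady_state_ode",
    "simulate_population",
    "regime_report",
    "default_regimes",
    "truncated_normal",
]

RECEPTORS = ("HER1", "HER2", "HER3", "HER4")


@dataclass(frozen=True)
class RateConstants:
    """Symmetric dissociation constants per dimer pair; np.inf disables a pair.

    Optionally carries on/off rates with Kd = koff/kon for the kinetic oracle;
    when absent the oracle uses kon = 1, koff = Kd.
    """

    kd: np.ndarray
    kon: np.ndarray | None = None

    def __post_init__(self):
        kd = np.asarray(self.kd, dtype=float)
        if kd.ndim != 2 or kd.shape[0] != kd.shape[1]:
            raise ValueError("kd must be a square matrix")
        if not np.allclose(kd, kd.T, equal_nan=True):
            raise ValueError("kd must be symmetric")
        finite = np.isfinite(kd)
        if np.any(kd[finite] <= 0):
            raise ValueError("dissociation constants must be positive")
        object.__setattr__(self, "kd", kd)
        if self.kon is not None:
            kon = np.asarray(self.kon, dtype=float)
            if kon.shape != kd.shape or not np.allclose(kon, kon.T):
                raise ValueError("kon must be a symmetric matrix matching kd")
            if np.any(kon[finite] <= 0):
                raise ValueError("association rates of enabled pairs must be positive")
            object.__setattr__(self, "kon", kon)

    @property
    def n_receptors(self) -> int:
        return self.kd.shape[0]

    @property
    def kdinv(self) -> np.ndarray:
        """1/Kd with disabled pairs as exact zeros."""
        with np.errstate(divide="ignore"):
            out = 1.0 / self.kd
        out[~np.isfinite(self.kd)] = 0.0
        return out

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(kon, koff) consistent with Kd, defaulting kon to 1 where enabled."""
        enabled = np.isfinite(self.kd)
        kon = self.kon if self.kon is not None else np.where(enabled, 1.0, 0.0)
        koff = np.where(enabled, kon, 0.0) * np.where(enabled, self.kd, 0.0)
        return np.where(enabled, kon, 0.0), koff

    @classmethod
    def simple_model(cls, kd_hetero: float = 1.0) -> "RateConstants":
        """3-receptor model: HER1/2/3 heterodimers only (E12, E13, E23)."""
        kd = np.full((3, 3), np.inf)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            kd[i, j] = kd[j, i] = kd_hetero
        return cls(kd)

    @classmethod
    def detailed_model(cls, kd_hetero: float = 1.0, kd_homo: float = 100.0) -> "RateConstants":
        """4-receptor model: all 10 pairs; homodimerization is weak by default.

        Heterodimerization (HER2 the preferred partner) is the dominant mode;
        HER3 is kinase-impaired and homodimerizes poorly, so homodimer Kd
        defaults to 100x the heterodimer Kd.
        """
        kd = np.full((4, 4), kd_hetero)
        np.fill_diagonal(kd, kd_homo)
        return cls(kd)

    @classmethod
    def single_pair(cls, i: int = 1, j: int = 2, kd: float = 1.0, n_receptors: int = 4) -> "RateConstants":
        """Only one dimer pair enabled (isolated-binding baseline)."""
        mat = np.full((n_receptors, n_receptors), np.inf)
        mat[i, j] = mat[j, i] = kd
        return cls(mat)


@dataclass(frozen=True)
class EquilibriumState:
    """Free monomer and dimer concentrations at steady state."""

    free: np.ndarray  # (R,)
    dimers: np.ndarray  # (R, R) symmetric, [i, j] = [E_ij]; diagonal = homodimers
    totals: np.ndarray

    def dimer(self, i: int, j: int) -> float:
        return float(self.dimers[i, j])

    @property
    def e23(self) -> float:
        """The HER2-HER3 heterodimer concentration."""
        return float(self.dimers[1, 2])

    def conservation_residual(self) -> float:
        """Max relative mass-conservation error over receptors."""
        bound = self.dimers.sum(axis=1) + np.diag(self.dimers)  # counts 2*E_ii
        tot = self.free + bound
        scale = np.maximum(self.totals, 1e-300)
        return float(np.max(np.abs(tot - self.totals) / scale))

    def equilibrium_residual(self, k: RateConstants) -> float:
        """Max relative detailed-balance error over enabled pairs."""
        kdinv = k.kdinv
        expected = np.outer(self.free, self.free) * kdinv
        enabled = kdinv > 0
        if not enabled.any():
            return 0.0
        scale = np.maximum(np.abs(expected[enabled]), 1e-300)
        return float(np.max(np.abs(self.dimers[enabled] - expected[enabled]) / scale))


def _dimers_from_free(free: np.ndarray, kdinv: np.ndarray) -> np.ndarray:
    return np.outer(free, free) * kdinv


def solve_equilibrium_batch(
    totals: np.ndarray,
    k: RateConstants,
    *,
    tol: float = 1e-12,
    max_fixed_point: int = 500,
    max_newton: int = 50,
) -> np.ndarray:
    """Free monomer concentrations for a batch of total-abundance vectors.

    Geometric-damped fixed point (globally stable, preserves positivity)
    followed by Newton polish on the conservation system.  Raises
    :class:`EquilibriumError` with diagnostics if any row fails to converge.
    """
    totals = np.atleast_2d(np.asarray(totals, dtype=float))
    if np.any(totals < 0):
        raise ValueError("total abundances must be non-negative")
    kdinv = k.kdinv
    if totals.shape[1] != k.n_receptors:
        raise ValueError("totals width must match the number of receptors")
    diag = np.diag(kdinv)
    free = totals.copy()

    def residual(f):
        s = f @ kdinv
        return f * (1.0 + (s - f * diag) + 2.0 * f * diag) - totals

    for _ in range(max_fixed_point):
        s = free @ kdinv
        denom = 1.0 + (s - free * diag) + 2.0 * free * diag
        new = totals / denom
        free = np.sqrt((free + 1e-300) * new)
    free[totals == 0] = 0.0

    # Newton polish: J_ij = d residual_i / d free_j
    for _ in range(max_newton):
        res = residual(free)
        scale = np.maximum(totals, 1e-300)
        if np.max(np.abs(res) / scale) < tol:
            break
        s = free @ kdinv
        B, R = free.shape
        jac = np.zeros((B, R, R))
        diag_term = 1.0 + (s - free * diag) + 4.0 * free * diag
        for i in range(R):
            jac[:, i, :] = free[:, i : i + 1] * kdinv[i][None, :]
            jac[:, i, i] = diag_term[:, i]
        step = np.linalg.solve(jac, res[..., None])[..., 0]
        new_free = free - step
        bad = new_free <= 0
        new_free[bad] = free[bad] * 0.5  # damp into the positive orthant
        new_free[totals == 0] = 0.0
        free = new_free

    res = residual(free)
    rel = np.abs(res) / np.maximum(totals, 1e-300)
    if np.max(rel) >= tol * 10:
        worst = int(np.argmax(rel.max(axis=1)))
        raise EquilibriumError(
            f"equilibrium solver did not converge: max relative residual "
            f"{np.max(rel):.3e} (row {worst}, totals={totals[worst]})"
        )
    return free


def equilibrium_state(totals: np.ndarray, k: RateConstants) -> EquilibriumState:
    """Steady state of the coupled mass-action dimerization system."""
    totals = np.asarray(totals, dtype=float)
    free = solve_equilibrium_batch(totals[None, :], k)[0]
    return EquilibriumState(free=free, dimers=_dimers_from_free(free, k.kdinv), totals=totals)


def steady_state_ode(
    totals: np.ndarray,
    k: RateConstants,
    *,
    deriv_tol: float = 1e-10,
    max_time: float = 1e8,
) -> EquilibriumState:
    """Kinetic route to the same steady state (oracle for the algebraic solver).

    Integrates d[E_ij]/dt = kon_ij*free_i*free_j - koff_ij*[E_ij] (free
    concentrations eliminated through conservation) from the all-monomer
    initial condition until the largest relative derivative falls below
    ``deriv_tol``.
    """
    totals = np.asarray(totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("total abundances must be non-negative")
    R = k.n_receptors
    kon, koff = k.rates()
    pairs = [(i, j) for i in range(R) for j in range(i, R) if np.isfinite(k.kd[i, j])]

    def free_from(d):
        dm = np.zeros((R, R))
        for (i, j), v in zip(pairs, d):
            dm[i, j] = dm[j, i] = v
        return totals - dm.sum(axis=1) - np.diag(dm), dm

    def rhs(_, d):
        free, _dm = free_from(d)
        return np.array([kon[i, j] * free[i] * free[j] - koff[i, j] * v for (i, j), v in zip(pairs, d)])

    scale = max(totals.max(), 1.0)
    y = np.zeros(len(pairs))
    t_end = 10.0 / max(koff[np.isfinite(k.kd)].min(), 1e-12) if pairs else 1.0
    for _ in range(40):
        sol = solve_ivp(rhs, (0.0, t_end), y, method="LSODA", rtol=1e-12, atol=1e-14 * scale)
        if not sol.success:
            raise EquilibriumError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        if len(pairs) == 0 or np.max(np.abs(rhs(0.0, y))) / scale < deriv_tol:
            break
        t_end *= 4.0
    else:
        raise EquilibriumError("ODE did not reach stationarity within the time budget")
    free, dimers = free_from(y)
    return EquilibriumState(free=free, dimers=dimers, totals=totals)


# ---------------------------------------------------------------------------
# population simulation


def truncated_normal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Normal(mean, cv*mean) truncated at zero by re-drawing negatives."""
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, cv * mean, size)
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, cv * mean, int(bad.sum()))


@dataclass(frozen=True)
class PopulationSimResult:
    """Per-patient equilibria and E23-vs-total correlations for one regime."""

    totals: np.ndarray  # (n, R)
    free: np.ndarray
    e23: np.ndarray
    correlations: dict  # keys r_e23_total2/3 (Pearson), rho_... (Spearman)
    n_solved: int
    n_failed: int
    seed: int
    regime: str | None = None

    @property
    def dimer_table(self):
        import pandas as pd

        cols = {f"total_{name}": self.totals[:, i] for i, name in enumerate(RECEPTORS[: self.totals.shape[1]])}
        cols["e23"] = self.e23
        return pd.DataFrame(cols)


def _correlations(e23: np.ndarray, totals: np.ndarray) -> dict:
    out: dict = {}
    for idx, key in ((1, "total2"), (2, "total3")):
        x = totals[:, idx]
        if np.std(x) == 0 or np.std(e23) == 0:
            out[f"r_e23_{key}"] = None
            out[f"rho_e23_{key}"] = None
            out["degenerate_reason"] = "zero variance in abundances or dimer level"
        else:
            out[f"r_e23_{key}"] = float(pearsonr(e23, x)[0])
            out[f"rho_e23_{key}"] = float(spearmanr(e23, x)[0])
    return out


def simulate_population(
    n: int,
    abundance_means,
    abundance_cvs,
    k: RateConstants,
    seed: int,
    regime: str | None = None,
) -> PopulationSimResult:
    """Draw n patients' receptor abundances, solve each equilibrium, correlate.

    ``abundance_cvs`` may be a scalar applied to every receptor or a
    per-receptor sequence.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    means = np.asarray(abundance_means, dtype=float)
    if np.any(means < 0):
        raise ValueError("abundance means must be non-negative")
    cvs = np.broadcast_to(np.asarray(abundance_cvs, dtype=float), means.shape)
    rng = np.random.default_rng(seed)
    totals = np.column_stack(
        [truncated_normal(rng, m, c, n) for m, c in zip(means, cvs)]
    )
    failed = 0
    try:
        free = solve_equilibrium_batch(totals, k)
    except EquilibriumError:
        # fall back to per-patient solves so failures can be excluded
        free = np.full_like(totals, np.nan)
        for i in range(n):
            try:
                free[i] = solve_equilibrium_batch(totals[i][None, :], k)[0]
            except EquilibriumError:
                failed += 1
        keep = ~np.isnan(free).any(axis=1)
        totals, free = totals[keep], free[keep]
    e23 = free[:, 1] * free[:, 2] * k.kdinv[1, 2]
    return PopulationSimResult(
        totals=totals,
        free=free,
        e23=e23,
        correlations=_correlations(e23, totals),
        n_solved=len(totals),
        n_failed=failed,
        seed=seed,
        regime=regime,
    )


def default_regimes(model: str = "detailed") -> dict:
    """Named abundance-mean settings reproducing the decorrelation scenarios.

    Keys: ``C`` ([HER2]~[HER3]<<[HER1]), ``D`` ([HER2]<<[HER3]<<[HER1]),
    ``her2_over``, ``her3_over`` (one receptor dominant) — in arbitrary
    concentration units with heterodimer Kd = 1.
    """
    if model == "simple":
        return {
            "C": (100.0, 1.0, 1.0),
            "D": (100.0, 0.1, 1.0),
            "her2_over": (1.0, 100.0, 1.0),
            "her3_over": (1.0, 1.0, 100.0),
        }
    if model == "detailed":
        return {
            "C": (100.0, 1.0, 1.0, 1.0),
            "D": (100.0, 0.1, 1.0, 1.0),
            "her2_over": (1.0, 100.0, 1.0, 1.0),
            "her3_over": (1.0, 1.0, 100.0, 1.0),
        }
    raise ValueError("model must be 'simple' or 'detailed'")


def regime_report(
    regimes: dict,
    k: RateConstants,
    n: int = 400,
    seed: int = 0,
    abundance_cv: float = 0.3,
):
    """One row per regime: Pearson/Spearman correlations of E23 with totals."""
    import pandas as pd

    rows = []
    for idx, (name, means) in enumerate(regimes.items()):
        res = simulate_population(n, means, abundance_cv, k, seed + idx, regime=name)
        c = res.correlations
        rows.append(
            {
                "regime": name,
                "r_e23_total2": c["r_e23_total2"],
                "r_e23_total3": c["r_e23_total3"],
                "rho_e23_total2": c["rho_e23_total2"],
                "rho_e23_total3": c["rho_e23_total3"],
                "n_solved": res.n_solved,
            }
        )
    return pd.DataFrame(rows)
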
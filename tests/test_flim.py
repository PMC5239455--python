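"""Decay fitting, lifetime maps, filtering and FRET arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from herfret.errors import CoreExcludedError, InsufficientPhotonsError, NoEvaluablePixelsError
from herfret.flim import (
    FlimConfig,
    LifetimeMap,
    TCSPCCube,
    build_lifetime_map,
    core_fret,
    decay_shape,
    fit_biexponential,
    fit_monoexponential,
    fret_efficiency,
    lifetime_filter,
    roi_mean_lifetime,
)
from herfret.synthetic import DecaySimConfig, simulate_core_pair

BIN_WIDTH = 12.5 / 256


# ---------------------------------------------------------------------------
# mono-exponential fitting


def test_mono_fit_recovers_noiseless_model():
    """Self-consistency: the MLE on exact model data returns the true lifetime."""
    for tau in (0.5, 2.0, 3.5):
        hist = decay_shape(tau, 256, 12.5) * 1e6
        fit = fit_monoexponential(hist, BIN_WIDTH)
        assert fit.converged
        assert fit.lifetimes[0] == pytest.approx(tau, rel=1e-4)
        assert fit.amplitude_fractions == (1.0,)


def test_mono_fit_degenerate_histogram_hits_bound():
    hist = np.zeros(256)
    hist[0] = 500
    fit = fit_monoexponential(hist, BIN_WIDTH)
    assert not fit.converged


def test_mono_fit_rejects_insufficient_photons():
    hist = decay_shape(2.0, 256, 12.5) * 50
    with pytest.raises(InsufficientPhotonsError, match="insufficient photons"):
        fit_monoexponential(hist, BIN_WIDTH, min_photons=100)


def test_mono_fit_is_deterministic():
    rng = np.random.default_rng(0)
    hist = rng.poisson(decay_shape(2.3, 256, 12.5) * 5e3)
    fits = {fit_monoexponential(hist, BIN_WIDTH).lifetimes[0] for _ in range(3)}
    assert len(fits) == 1


# ---------------------------------------------------------------------------
# bi-exponential fitting


def test_biexp_fit_recovers_noiseless_mixture():
    p = 0.3 * decay_shape(0.8, 256, 12.5) + 0.7 * decay_shape(2.6, 256, 12.5)
    fit = fit_biexponential(p * 1e6, BIN_WIDTH)
    assert fit.converged and len(fit.lifetimes) == 2
    assert fit.lifetimes[0] == pytest.approx(0.8, rel=0.01)
    assert fit.lifetimes[1] == pytest.approx(2.6, rel=0.01)
    assert fit.amplitude_fractions[0] == pytest.approx(0.3, abs=0.02)


def test_biexp_fit_falls_back_to_mono_on_pure_decay():
    hist = decay_shape(2.0, 256, 12.5) * 1e6
    fit = fit_biexponential(hist, BIN_WIDTH)
    assert len(fit.lifetimes) == 1
    assert fit.lifetimes[0] == pytest.approx(2.0, rel=1e-3)


def test_biexp_fit_long_component_monte_carlo():
    """Long-lifetime component recovered within 3% at 1e5 photons."""
    p = 0.3 * decay_shape(0.8, 256, 12.5) + 0.7 * decay_shape(2.6, 256, 12.5)
    rng = np.random.default_rng(42)
    longs = []
    for _ in range(100):
        fit = fit_biexponential(rng.poisson(p * 1e5), BIN_WIDTH)
        longs.append(fit.lifetimes[-1])
    assert np.median(np.abs(np.array(longs) - 2.6) / 2.6) < 0.03


# ---------------------------------------------------------------------------
# lifetime maps


def _uniform_cube(tau, photons, shape=(16, 16), n_bins=256, window=12.5, seed=0):
    rng = np.random.default_rng(seed)
    mu = decay_shape(tau, n_bins, window) * photons
    counts = rng.poisson(mu, size=shape + (n_bins,))
    return TCSPCCube(counts=counts, time_window=window)


def test_lifetime_map_uniform_cube_within_tolerance():
    cube = _uniform_cube(2.0, 1e4)
    lm = build_lifetime_map(cube)
    assert lm.valid_mask.all()
    assert lm.tau.min() > 1.9 and lm.tau.max() < 2.1


def test_lifetime_map_zero_photon_border_invalid():
    cube = _uniform_cube(2.0, 5e3)
    counts = cube.counts.copy()
    counts[0, :, :] = 0
    lm = build_lifetime_map(TCSPCCube(counts=counts, time_window=12.5))
    assert not lm.valid_mask[0].any()
    assert lm.valid_mask[1:].all()


def test_lifetime_map_all_invalid_raises():
    counts = np.zeros((4, 4, 64), dtype=int)
    with pytest.raises(NoEvaluablePixelsError, match="no evaluable pixels"):
        build_lifetime_map(TCSPCCube(counts=counts, time_window=12.5))


def test_spatial_binning_halves_dispersion():
    """2x2 binning quadruples photons per fit: SD of tau should drop ~2x."""
    cube = _uniform_cube(2.0, 1e3, shape=(64, 64), seed=3)
    sd1 = np.nanstd(build_lifetime_map(cube, FlimConfig(min_photons=50)).tau)
    sd2 = np.nanstd(build_lifetime_map(cube, FlimConfig(min_photons=50, binning=2)).tau)
    assert sd1 / sd2 == pytest.approx(2.0, rel=0.2)


# ---------------------------------------------------------------------------
# filtering and ROI averaging


def _map_from(taus, photons):
    taus = np.asarray(taus, dtype=float)
    photons = np.asarray(photons, dtype=float)
    return LifetimeMap(tau=taus, photons=photons, valid_mask=np.isfinite(taus))


def test_lifetime_filter_set_membership():
    lm = _map_from([[0.5, 2.0, 6.0]], [[100, 100, 100]])
    out = lifetime_filter(lm, (1.0, 4.0))
    assert out.valid_mask.tolist() == [[False, True, False]]


def test_lifetime_filter_idempotent_and_never_adds():
    rng = np.random.default_rng(1)
    lm = _map_from(rng.uniform(0.2, 6.0, (8, 8)), rng.integers(50, 500, (8, 8)))
    once = lifetime_filter(lm, (1.0, 4.0))
    twice = lifetime_filter(once, (1.0, 4.0))
    assert np.array_equal(once.valid_mask, twice.valid_mask)
    assert not np.any(once.valid_mask & ~lm.valid_mask)


def test_roi_mean_lifetime_weighted_example():
    lm = _map_from([[2.0, 3.0]], [[100, 300]])
    assert roi_mean_lifetime(lm) == pytest.approx(2.75)
    assert roi_mean_lifetime(lm, weighting="uniform") == pytest.approx(2.5)


def test_roi_mean_lifetime_single_pixel_and_uniform_map():
    assert roi_mean_lifetime(_map_from([[2.4]], [[150]])) == pytest.approx(2.4)
    lm = _map_from(np.full((5, 5), 1.7), np.full((5, 5), 200))
    assert roi_mean_lifetime(lm) == pytest.approx(1.7)


def test_roi_mean_lifetime_requires_valid_pixels():
    lm = _map_from([[np.nan]], [[0]])
    with pytest.raises(NoEvaluablePixelsError):
        roi_mean_lifetime(lm)


# ---------------------------------------------------------------------------
# FRET efficiency


@pytest.mark.parametrize(
    "tau_d,tau_da,expected",
    [(2.0, 2.0, 0.0), (2.0, 1.8, 0.10), (2.0, 2.1, -0.05)],
)
def test_fret_efficiency_examples(tau_d, tau_da, expected):
    assert fret_efficiency(tau_d, tau_da) == pytest.approx(expected)


def test_fret_efficiency_rejects_nonpositive_lifetimes():
    with pytest.raises(ValueError):
        fret_efficiency(0.0, 1.0)
    with pytest.raises(ValueError):
        fret_efficiency(2.0, -1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tau_d=st.floats(0.1, 10.0),
    delta=st.floats(0.01, 0.5),
)
def test_fret_efficiency_zero_at_equality_and_monotone(tau_d, delta):
    assert fret_efficiency(tau_d, tau_d) == 0.0
    shorter = fret_efficiency(tau_d, tau_d * (1 - delta))
    even_shorter = fret_efficiency(tau_d, tau_d * (1 - delta) * 0.9)
    assert 0 < shorter < even_shorter < 1


# ---------------------------------------------------------------------------
# core-level FRET


def _mixture_fit_oracle(tau_donor, tau_fret, ff, window):
    """Closed-form oracle: lifetime a mean-arrival-matching fit reports for a
    truncated two-component mixture (continuous-time limit)."""

    def trunc_mean(tau):
        return tau - window * np.exp(-window / tau) / (1.0 - np.exp(-window / tau))

    target = (1 - ff) * trunc_mean(tau_donor) + ff * trunc_mean(tau_fret)
    return brentq(lambda t: trunc_mean(t) - target, 0.01, window)


def test_core_fret_null_construction(small_decay_config):
    donor, da = simulate_core_pair(small_decay_config)  # fret_fraction = 0
    res = core_fret(donor, da)
    assert abs(res.fret_efficiency) < 0.01
    assert res.n_pixels_d > 0 and res.n_pixels_da > 0


def test_core_fret_matches_mixture_mean_oracle():
    cfg = DecaySimConfig(
        image_shape=(48, 48),
        photons_per_pixel=10_000.0,
        fret_fraction=0.2,
        tau_donor=2.8,
        tau_fret=1.4,
        seed=7,
    )
    donor, da = simulate_core_pair(cfg)
    res = core_fret(donor, da)
    tau_mix = _mixture_fit_oracle(2.8, 1.4, 0.2, 12.5)
    expected = 1.0 - tau_mix / 2.8
    assert res.fret_efficiency == pytest.approx(expected, abs=0.01)


def test_core_fret_exclusion_reason_when_filter_removes_everything(small_decay_config):
    donor, da = simulate_core_pair(small_decay_config)
    cfg = FlimConfig(filter_window=(9.0, 10.0))  # excludes the donor band entirely
    with pytest.raises(CoreExcludedError, match="donor"):
        core_fret(donor, da, cfg)
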
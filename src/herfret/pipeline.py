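"""End-to-end run: simulate cores -> fit -> FRET -> cohort -> survival report.

Every stochastic stage receives a seed spawned from the master seed through
``numpy.random.SeedSequence(master_seed, spawn_key)`` with a fixed per-stage
key, so a run is fully determined by its :class:`RunConfig`; the manifest
records per-artifact SHA-256 checksums to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as hio
from .cohort import CohortAnalysisConfig, CoxResult, run_cohort_analysis
from .errors import CoreExcludedError
from .flim import FlimConfig, core_fret
from .network import RateConstants, default_regimes, regime_report
from .synthetic import CohortSimConfig, DecaySimConfig, simulate_cohort, simulate_core_pair

log = logging.getLogger("herfret")

# spawn keys of the per-stage child seeds
_STAGE_KEYS = {"cohort": 1, "cores": 2, "network": 3}


@dataclass(frozen=True)
class RunConfig:
    """Master configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "herfret_run"
    n_cores: int = 20  # imaged core pairs (first n_cores patients)
    decay: DecaySimConfig = field(default_factory=lambda: DecaySimConfig(image_shape=(64, 64)))
    cohort: CohortSimConfig = field(default_factory=lambda: CohortSimConfig(n_patients=300))
    flim: FlimConfig = field(default_factory=FlimConfig)
    analysis: CohortAnalysisConfig = field(default_factory=CohortAnalysisConfig)
    network_regimes: bool = True
    network_n: int = 400


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed below 2**31 for a named stage."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fret_to_fraction(fret_percent: float, decay: DecaySimConfig) -> float:
    """FRET-population fraction whose fitted mixture lifetime yields E.

    Inverts E(ff) = 1 - tau_fit(ff)/tau_fit(0), where tau_fit is the lifetime
    a mono-exponential fit reports for the window-truncated mixture, by
    bisection (E is strictly increasing in ff).
    """
    from .flim import mono_equivalent_tau

    target = np.clip(fret_percent / 100.0, 0.0, None)
    if target == 0.0:
        return 0.0
    tau_d = mono_equivalent_tau([(decay.tau_donor, 1.0)], decay.n_bins, decay.time_window)

    def eff(ff):
        tau = mono_equivalent_tau(
            [(decay.tau_donor, 1.0 - ff), (decay.tau_fret, ff)], decay.n_bins, decay.time_window
        )
        return 1.0 - tau / tau_d

    lo, hi = 0.0, 0.95
    if target >= eff(hi):
        return hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if eff(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _summarize_cox(obj) -> dict:
    if isinstance(obj, CoxResult):
        return {
            "n_used": obj.n_used,
            "n_events": obj.n_events,
            "unreliable": obj.unreliable,
            "coefficients": {
                str(k): {c: float(obj.summary.loc[k, c]) for c in ("log_hr", "hr", "ci_low", "ci_high", "p")}
                for k in obj.summary.index
            },
        }
    return obj


def _jsonable_report(report: dict) -> dict:
    out = {}
    for key, val in report.items():
        if key == "km":
            out[key] = {
                str(h): {
                    grp: {lvl: {"final_s": float(c.survival[-1]), "n": c.n, "events": c.n_events} for lvl, c in curves.items()}
                    for grp, curves in by.items()
                }
                for h, by in val.items()
            }
        elif key in ("cox_univariate",):
            out[key] = {str(h): {n: _summarize_cox(r) for n, r in d.items()} for h, d in val.items()}
        elif key == "cox_multivariate":
            out[key] = {str(h): _summarize_cox(r) for h, r in val.items()}
        else:
            out[key] = val
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, write artifacts + manifest, return manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d outdir=%s", config.seed, outdir)
    artifacts: dict[str, str] = {}
    manifest: dict = {"seed": config.seed, "stages": {}}

    # 1. cohort simulation ---------------------------------------------------
    stage = "cohort_simulation"
    cohort_cfg = replace(config.cohort, seed=stage_seed(config.seed, "cohort"))
    try:
        cohort = simulate_cohort(cohort_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    p = hio.write_cohort_csv(outdir / "cohort.csv", cohort)
    artifacts["cohort.csv"] = _sha256(p)
    manifest["stages"][stage] = {"n_patients": len(cohort), "seed": cohort_cfg.seed}
    log.info("%s: %d patients", stage, len(cohort))

    # 2. core simulation + FLIM fitting --------------------------------------
    stage = "flim_cores"
    core_seed0 = stage_seed(config.seed, "cores")
    fret_rows = {}
    est, truth = [], []
    n_excluded = 0
    for i in range(min(config.n_cores, len(cohort))):
        target = float(cohort["fret_eff"].iloc[i])
        decay_cfg = replace(
            config.decay,
            fret_fraction=_fret_to_fraction(target, config.decay),
            seed=(core_seed0 + i) % (2**31),
        )
        donor, da = simulate_core_pair(decay_cfg)
        core_id = cohort["patient_id"].iloc[i]
        try:
            res = core_fret(donor, da, config.flim)
            fret_rows[core_id] = res
            est.append(res.fret_efficiency * 100.0)
            truth.append(max(target, 0.0))
        except CoreExcludedError as exc:
            fret_rows[core_id] = exc.reason
            n_excluded += 1
    p = hio.write_fret_results_csv(outdir / "fret_results.csv", fret_rows)
    artifacts["fret_results.csv"] = _sha256(p)
    mae = float(np.mean(np.abs(np.array(est) - np.array(truth)))) if est else None
    manifest["stages"][stage] = {
        "n_cores": len(fret_rows),
        "n_excluded": n_excluded,
        "fret_recovery_mae_percent": mae,
    }
    log.info("%s: %d cores, %d excluded, MAE=%.3f%%", stage, len(fret_rows), n_excluded, mae or -1)

    # 3. cohort survival analysis --------------------------------------------
    stage = "cohort_analysis"
    try:
        report = run_cohort_analysis(cohort, config.analysis)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    rep_json = _jsonable_report(report)
    p = outdir / "cohort_report.json"
    p.write_text(json.dumps(rep_json, indent=2, sort_keys=True, default=str))
    artifacts["cohort_report.json"] = _sha256(p)
    manifest["stages"][stage] = {
        "threshold": report["threshold"],
        "n_complete_cases": report["n_complete_cases"],
    }

    # 4. network regimes (optional) ------------------------------------------
    if config.network_regimes:
        stage = "network_regimes"
        k = RateConstants.detailed_model()
        rep = regime_report(default_regimes("detailed"), k, n=config.network_n, seed=stage_seed(config.seed, "network"))
        p = outdir / "regime_report.csv"
        rep.to_csv(p, index=False, float_format="%.10g")
        artifacts["regime_report.csv"] = _sha256(p)
        manifest["stages"][stage] = {"n_regimes": len(rep)}

    manifest["artifacts"] = artifacts
    manifest["config"] = _config_echo(config)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline done: %s", mpath)
    return manifest


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, RateConstants):
            return {"kd": obj.kd.tolist()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return float(obj)
        return obj

    return enc(config)
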
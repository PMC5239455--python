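"""On-disk formats: TCSPC cubes as multi-page TIFF + JSON sidecar, tables as CSV.

A cube is stored as one TIFF page per time bin (unsigned 16-bit counts, page
order = increasing time) next to a ``<stem>.json`` sidecar holding
``n_bins``, ``time_window_ns``, ``image_shape`` and an optional config echo.
Round-trips are bit-exact for integer counts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .flim import FretResult, LifetimeMap, TCSPCCube

__all__ = [
    "write_tcspc_cube",
    "read_tcspc_cube",
    "write_lifetime_map",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_fret_results_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_tcspc_cube(path, cube: TCSPCCube, config_echo=None, seed: int | None = None) -> Path:
    """Write a cube as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    counts = cube.counts
    if counts.max() > np.iinfo(np.uint16).max:
        raise FormatError("per-bin counts exceed the uint16 range")
    stack = np.moveaxis(counts.astype(np.uint16), 2, 0)  # (n_bins, rows, cols)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "n_bins": cube.n_bins,
        "time_window_ns": cube.time_window,
        "image_shape": list(cube.image_shape),
        "seed": seed,
        "config": _jsonable(config_echo),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_tcspc_cube(path) -> TCSPCCube:
    """Read a cube written by :func:`write_tcspc_cube`, validating metadata."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable sidecar {sidecar}: {exc}") from exc
    try:
        stack = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.shape[0] != meta["n_bins"]:
        raise FormatError(
            f"{path}: page count {stack.shape[0]} does not match sidecar n_bins {meta['n_bins']}"
        )
    if list(stack.shape[1:]) != list(meta["image_shape"]):
        raise FormatError(f"{path}: image shape mismatch with sidecar")
    return TCSPCCube(counts=np.moveaxis(stack, 0, 2).astype(np.int64), time_window=float(meta["time_window_ns"]))


def write_lifetime_map(path, lifetime_map: LifetimeMap) -> Path:
    """Write tau as float32 TIFF and the validity mask as a companion TIFF."""
    path = Path(path)
    tifffile.imwrite(path, lifetime_map.tau.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, lifetime_map.valid_mask.astype(np.uint8))
    return path


def write_cohort_csv(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"her2_ihc": str, "her3_loc": str, "nodes_grp": str})
    required = {"fret_eff", "time_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_fret_results_csv(path, results: dict[str, FretResult | str]) -> Path:
    """Per-core FRET rows; excluded cores carry the exclusion reason."""
    rows = []
    for core_id, res in results.items():
        if isinstance(res, FretResult):
            rows.append(
                {
                    "core_id": core_id,
                    "tau_d_ns": res.tau_d,
                    "tau_da_ns": res.tau_da,
                    "fret_eff": res.fret_efficiency,
                    "n_px_d": res.n_pixels_d,
                    "n_px_da": res.n_pixels_da,
                    "flags": "negative_E" if res.negative_efficiency else "",
                }
            )
        else:
            rows.append({"core_id": core_id, "flags": f"excluded: {res}"})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return path
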
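"""Output formats: time-series CSV, legacy VTK snapshots, checkpoints,
run manifests."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import NarrowBand
from .observables import TimeSeries

__all__ = ["write_series_csv", "read_series_csv", "write_vtk_snapshot",
           "write_checkpoint", "read_checkpoint", "write_manifest"]

CSV_COLUMNS = ["t", "R_bar", "energy", "mass"]


def write_series_csv(series: TimeSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series_csv(path) -> TimeSeries:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return TimeSeries.from_frame(df, meta={"path": str(path)})


def write_vtk_snapshot(path, band: NarrowBand, fields: dict) -> None:
    """Legacy-ASCII VTK structured points file.

    Writes each band field scattered onto the full grid (zero off band)
    plus the signed distance and a band mask, for external visualization.
    """
    grid = band.grid
    n = grid.n
    h = grid.h
    lines = ["# vtk DataFile Version 3.0", "surfchc snapshot", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {n} {n} {n}",
             f"ORIGIN {grid.lower[0]} {grid.lower[1]} {grid.lower[2]}",
             f"SPACING {h} {h} {h}",
             f"POINT_DATA {n**3}"]
    i, j, k = band.indices.T
    # VTK structured points vary x fastest
    flat = (k * n + j) * n + i

    def scatter(vals):
        full = np.zeros(n**3)
        full[flat] = vals
        return full

    out = dict(fields)
    out["phi"] = band.phi
    out["band_mask"] = np.ones(band.size)
    for name, vals in out.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        full = scatter(np.asarray(vals))
        lines.extend(" ".join(f"{v:.7g}" for v in full[r:r + 9])
                     for r in range(0, n**3, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def write_checkpoint(path, state) -> None:
    """Binary checkpoint (npz): f, f_prev, mu, t, step, M0, seed."""
    np.savez(path, f=state.f.values, f_prev=state.f_prev.values,
             mu=state.mu.values, t=state.t, step=state.step,
             M0=state.M0, seed=state.seed)


def read_checkpoint(path) -> dict:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_manifest(path, config: dict, seeds, outputs: dict) -> None:
    """JSON manifest: full resolved config, seeds, versions, outputs."""
    from . import __version__
    manifest = {
        "config": _jsonable(config),
        "seeds": _jsonable(seeds),
        "outputs": _jsonable(outputs),
        "versions": {"surfchc": __version__,
                     "numpy": np.__version__,
                     "python": platform.python_version()},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
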
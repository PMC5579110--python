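"""Run configuration: YAML schema, validation and defaults.

Defaults are the unit-sphere study conditions (mean concentration 0.3,
perturbation 0.01, Pe = 1, Cn = 0.015, dt = 5.12e-3 * h).  A config is a
plain nested dict; :func:`load_config`/:func:`validate_config` resolve
defaults and raise a single error listing every offending key.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import yaml

from .geometry import GridSpec, build_band, dumbbell_geometry, sphere_geometry
from .model import ModelParams
from .solver import SolverOptions

__all__ = ["ConfigError", "DEFAULT_CONFIG", "load_config",
           "validate_config", "build_run"]

DT_PER_H = 5.12e-3   # reference time step dt = 5.12e-3 * h

DEFAULT_CONFIG = {
    "shape": "sphere",
    "grid": {"N": 129, "lower": [-1.25, -1.25, -1.25],
             "upper": [1.25, 1.25, 1.25]},
    "band": {"half_width_in_h": 4.0},
    "params": {
        "Pe": 1.0, "Cn": 0.015, "sigma": 0.0,
        "mobility": "constant", "mean_concentration": 0.3,
        "perturbation_amplitude": 0.01,
        "dt": None,                    # None -> 5.12e-3 * h
        "ic_distribution": "uniform",
    },
    "run": {"t_end": 10.0, "seed": 0, "record_stride": 10,
            "snapshot_times": []},
    "solver": {"rtol": 1e-8, "restart": 30, "maxiter": 200,
               "s_inverse": "auto", "direct_threshold": 8000},
    "quadrature": {"width_in_h": 1.5},
    "analysis": {"fit_window": [0.1, 10.0]},
}


class ConfigError(ValueError):
    pass


def _merge(defaults: dict, user: dict, errors: list, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}{key}"
        if key not in defaults:
            errors.append(f"unknown key: {here}")
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{here}: expected a mapping")
            else:
                out[key] = _merge(defaults[key], val, errors, here + ".")
        else:
            out[key] = val
    return out


def validate_config(user: dict) -> dict:
    """Merge a user config into the defaults; raise listing bad keys."""
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user or {}, errors)
    if cfg["shape"] not in ("sphere", "dumbbell"):
        errors.append("shape: must be 'sphere' or 'dumbbell'")
    if not (isinstance(cfg["grid"]["N"], int) and cfg["grid"]["N"] >= 2):
        errors.append("grid.N: must be an integer >= 2")
    p = cfg["params"]
    for key, lo in (("Pe", 0.0), ("Cn", 0.0)):
        if not p[key] > lo:
            errors.append(f"params.{key}: must be > {lo}")
    if p["sigma"] < 0:
        errors.append("params.sigma: must be >= 0")
    if not 0.0 < p["mean_concentration"] < 1.0:
        errors.append("params.mean_concentration: must lie in (0, 1)")
    if p["mobility"] not in ("constant", "degenerate"):
        errors.append("params.mobility: must be 'constant' or 'degenerate'")
    if cfg["run"]["t_end"] < 0:
        errors.append("run.t_end: must be >= 0")
    t_end = cfg["run"]["t_end"]
    for ts in cfg["run"]["snapshot_times"]:
        if ts < 0 or ts > t_end:
            errors.append(f"run.snapshot_times: {ts} outside [0, {t_end}]")
    if errors:
        raise ConfigError("invalid configuration:\n  "
                          + "\n  ".join(errors))
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(user)


@dataclass
class RunSetup:
    """Everything needed to run one realization."""

    config: dict
    geom: object
    grid: GridSpec
    band: object
    params: ModelParams
    options: SolverOptions


def build_run(cfg: dict) -> RunSetup:
    """Instantiate geometry, grid, band and parameters from a config."""
    g = cfg["grid"]
    grid = GridSpec(n=g["N"], lower=tuple(g["lower"]),
                    upper=tuple(g["upper"]))
    geom = sphere_geometry() if cfg["shape"] == "sphere" \
        else dumbbell_geometry()
    band = build_band(geom, grid, cfg["band"]["half_width_in_h"] * grid.h)
    p = cfg["params"]
    dt = p["dt"] if p["dt"] is not None else DT_PER_H * grid.h
    params = ModelParams(pe=p["Pe"], cn=p["Cn"], sigma=p["sigma"],
                         mobility_kind=p["mobility"],
                         mean_concentration=p["mean_concentration"],
                         perturbation_amplitude=p["perturbation_amplitude"],
                         dt=dt)
    s = cfg["solver"]
    options = SolverOptions(rtol=s["rtol"], restart=s["restart"],
                            maxiter=s["maxiter"], s_inverse=s["s_inverse"],
                            direct_threshold=s["direct_threshold"])
    return RunSetup(config=cfg, geom=geom, grid=grid, band=band,
                    params=params, options=options)


def realization_seed(master_seed: int, index: int) -> int:
    """Derived per-realization seed: counter-based, order-independent,
    kept below 2^31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
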
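"""Pre-defined study configurations.

Two tiers:

* ``reduced_*`` — desk-scale versions of the sphere coarsening ensembles
  and the flat-torus coarsening law, sized to run on a single CPU in
  minutes.  The sphere studies keep the full-scale ratio of interface
  width to grid spacing (Cn ~ 2.5 h / 3.1) and rescale the noise intensity
  as sigma ~ h^2 so the noise-magnitude-to-mobility ratio sqrt(sigma nu)/h
  — the quantity that governs whether conserved noise competes with
  degenerate-mobility transport — matches the full-scale configuration.
* ``full_scale_config`` — the reference configuration (N = 129, dt =
  5.12e-3 h, t_end = 10, 64 realizations per case); multi-day on one CPU,
  shipped for completeness and for cluster use.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import GridSpec, build_band, sphere_geometry
from .model import ModelParams
from .operators import BandOperators
from .solver import SolverOptions, make_s_inverse, run_simulation
from .statistics import fit_growth_rate

__all__ = ["ReducedSphereStudy", "REDUCED_CASES", "reduced_sphere_study",
           "run_reduced_ensemble", "FLAT_COARSENING", "full_scale_config"]

_H_FULL = 2.5 / 128   # reference grid spacing of the full-scale runs


@dataclass(frozen=True)
class ReducedSphereStudy:
    """One reduced-scale sphere ensemble case."""

    name: str
    n_grid: int = 33
    cn: float = 0.05          # keeps ~2.5 cells per interface at N = 33
    dt: float = 2e-3
    t_end: float = 2.0
    mobility: str = "constant"
    sigma: float = 0.0
    fit_window: tuple = (0.3, 2.0)
    rtol: float = 1e-6

    @property
    def grid(self) -> GridSpec:
        return GridSpec(n=self.n_grid)

    @property
    def params(self) -> ModelParams:
        return ModelParams(cn=self.cn, dt=self.dt,
                           mobility_kind=self.mobility, sigma=self.sigma)

    @property
    def options(self) -> SolverOptions:
        return SolverOptions(rtol=self.rtol)


def _scaled_sigma(sigma_full: float, h: float) -> float:
    """Noise intensity preserving sqrt(sigma)/h across grid resolutions."""
    return sigma_full * (h / _H_FULL) ** 2


def reduced_sphere_study(case: str) -> ReducedSphereStudy:
    h = GridSpec(n=33).h
    cases = {
        "ch_constant": ReducedSphereStudy("ch_constant",
                                          mobility="constant"),
        "ch_degenerate": ReducedSphereStudy("ch_degenerate",
                                            mobility="degenerate"),
        "chc_degenerate": ReducedSphereStudy(
            "chc_degenerate", mobility="degenerate",
            sigma=_scaled_sigma(1e-5, h)),
        "chc_constant": ReducedSphereStudy(
            "chc_constant", mobility="constant",
            sigma=_scaled_sigma(1e-5, h)),
    }
    return cases[case]


REDUCED_CASES = ("ch_constant", "ch_degenerate", "chc_degenerate")


def run_reduced_ensemble(case: str, seeds, ops: BandOperators | None = None,
                         record_stride: int = 25):
    """Run a reduced sphere ensemble; returns (alphas, series list)."""
    study = reduced_sphere_study(case)
    if ops is None:
        band = build_band(sphere_geometry(), study.grid, 4 * study.grid.h)
        ops = BandOperators.build(band)
    params = study.params
    options = study.options
    s_inv = make_s_inverse(ops, params, options,
                           c_bot=2.0 * params.dt / (3.0 * params.pe))
    alphas, series = [], []
    for seed in seeds:
        res = run_simulation(ops, params, t_end=study.t_end, seed=int(seed),
                             record_stride=record_stride, options=options,
                             s_inv=s_inv)
        series.append(res.series)
        alphas.append(fit_growth_rate(res.series, study.fit_window).alpha)
    return alphas, series


# Flat-torus coarsening-law study: 256^2, interfaces ~5 cells wide, fitted
# over the established regime [0.2, 2] (earlier times are still
# segregating, later times have too few droplets left).
FLAT_COARSENING = {
    "n": 256, "cn": 8e-3, "dt": 2e-3, "t_end": 2.0,
    "mean_concentration": 0.3, "perturbation_amplitude": 0.01,
    "fit_window": (0.2, 2.0), "n_seeds": 8,
}


def full_scale_config(case: str) -> dict:
    """Full-scale run configuration dicts (cli_io schema)."""
    mobility = "degenerate" if "degenerate" in case else "constant"
    sigma = {"ch": 0.0, "chc9": 1e-9, "chc7": 1e-7, "chc5": 1e-5}[
        case.split("_")[0]]
    window = [0.1, 0.8] if (mobility == "degenerate" and sigma >= 1e-5) \
        else [0.1, 10.0]
    return {
        "shape": "sphere",
        "grid": {"N": 129},
        "params": {"mobility": mobility, "sigma": sigma},
        "run": {"t_end": 10.0},
        "analysis": {"fit_window": window},
    }
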
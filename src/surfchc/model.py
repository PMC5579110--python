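"""Dimensionless Cahn-Hilliard / Cahn-Hilliard-Cook physics.

Double-well mixing energy g(f) = f^2 (1-f)^2 with equilibrium phases at
f = 0 and f = 1, chemical potential mu = g'(f) - Cn^2 Lap_s f, and either
constant (nu = 1) or degenerate (nu = 4 f (1-f)) dimensionless mobility.
All quantities are dimensionless; Pe scales diffusion, Cn the interface
width and sigma the conserved-noise intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ModelParams", "mixing_energy", "g_prime", "g_second", "mobility"]

SPINODAL_HALF_WIDTH = 1.0 / np.sqrt(12.0)   # g''(f) < 0 on 0.5 +- this


@dataclass(frozen=True)
class ModelParams:
    """Physical/run parameters of the dimensionless CH/CHC system.

    Defaults are the unit-sphere study conditions: mean concentration 0.3
    perturbed by +-0.01, Pe = 1, Cn = 0.015, noise off.  ``dt`` must be set
    explicitly per run (the reference choice is 5.12e-3 * h).
    """

    pe: float = 1.0
    cn: float = 0.015
    sigma: float = 0.0
    mobility_kind: str = "constant"          # "constant" | "degenerate"
    mean_concentration: float = 0.3
    perturbation_amplitude: float = 0.01
    dt: float = 1e-4

    def __post_init__(self):
        if self.pe <= 0:
            raise ValueError("Pe must be positive")
        if self.cn <= 0:
            raise ValueError("Cn must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 < self.mean_concentration < 1.0:
            raise ValueError("mean concentration must lie in (0, 1)")
        if self.perturbation_amplitude < 0:
            raise ValueError("perturbation amplitude must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mobility_kind not in ("constant", "degenerate"):
            raise ValueError("mobility_kind must be 'constant' or 'degenerate'")

    def with_dt(self, dt: float) -> "ModelParams":
        return replace(self, dt=dt)


def mixing_energy(f):
    """Double-well mixing energy g(f) = f^2 (1 - f)^2."""
    f = np.asarray(f, dtype=float)
    return f**2 * (1.0 - f) ** 2


def g_prime(f):
    """g'(f) = 2 f (1 - f)(1 - 2 f), the homogeneous chemical potential."""
    f = np.asarray(f, dtype=float)
    return 2.0 * f * (1.0 - f) * (1.0 - 2.0 * f)


def g_second(f):
    """g''(f) = 2 (1 - 6 f + 6 f^2); negative inside the spinodal region."""
    f = np.asarray(f, dtype=float)
    return 2.0 * (1.0 - 6.0 * f + 6.0 * f**2)


def mobility(f, kind: str = "constant"):
    """Dimensionless mobility nu(f).

    ``constant``: 1 everywhere.  ``degenerate``: 4 f (1-f), clamped at zero
    from below so small overshoots outside [0, 1] (routine for semi-implicit
    phase-field schemes) cannot make the transport operator ill-posed.
    """
    f = np.asarray(f, dtype=float)
    if kind == "constant":
        return np.ones_like(f)
    if kind == "degenerate":
        return np.maximum(4.0 * f * (1.0 - f), 0.0)
    raise ValueError("kind must be 'constant' or 'degenerate'")
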
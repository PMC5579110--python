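"""Surface integration and global mass correction.

Surface integrals are computed over the embedding band with a smoothed
one-dimensional Dirac delta of the signed distance,

    int_Gamma q dA  ~=  sum_nodes q * delta_eps(phi) * |grad phi| * h^3,

using the cosine kernel delta_eps(x) = (1 + cos(pi x / eps)) / (2 eps) on
|x| <= eps, eps = 1.5 h by default.  The per-step mass correction rescales
the concentration by beta = M0 / int f dA so the surface-integrated amount
is conserved for the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import NarrowBand
from .operators import SurfaceField

__all__ = ["QuadratureSpec", "surface_integral", "beta_correction"]


@dataclass(frozen=True)
class QuadratureSpec:
    """Smoothed-delta quadrature: kernel half-width in units of h."""

    width_in_h: float = 1.5
    kernel: str = "cosine"

    def __post_init__(self):
        if self.width_in_h < 1.5:
            raise ValueError("kernel half-width must be at least 1.5 h")
        if self.kernel != "cosine":
            raise ValueError("only the cosine kernel is implemented")


def _delta_eps(phi: np.ndarray, eps: float) -> np.ndarray:
    out = np.zeros_like(phi)
    m = np.abs(phi) <= eps
    out[m] = (1.0 + np.cos(np.pi * phi[m] / eps)) / (2.0 * eps)
    return out


def surface_integral(field: SurfaceField | np.ndarray, band: NarrowBand,
                     quad: QuadratureSpec = QuadratureSpec()) -> float:
    """Integral of a band field over the surface (second order in h)."""
    vals = field.values if isinstance(field, SurfaceField) else np.asarray(field)
    h = band.grid.h
    eps = quad.width_in_h * h
    if band.half_width < eps:
        raise ValueError("band thinner than the quadrature kernel support")
    w = _delta_eps(band.phi, eps)
    sel = w > 0
    gp = band.geom.grad_phi(band.coords[sel])
    gn = np.linalg.norm(gp, axis=-1)
    return float(np.sum(vals[sel] * w[sel] * gn) * h**3)


def beta_correction(f_h: SurfaceField, M0: float, band: NarrowBand,
                    quad: QuadratureSpec = QuadratureSpec()
                    ) -> tuple[SurfaceField, float]:
    """Rescale f by beta = M0 / int f dA; returns (beta*f, beta).

    Raises if the current surface mass is zero or negative (the correction
    is a pure rescaling and cannot recover from a sign change).
    """
    mass = surface_integral(f_h, band, quad)
    if mass <= 0:
        raise ValueError(f"current surface mass {mass:g} is not positive")
    beta = M0 / mass
    return SurfaceField(beta * f_h.values, extended=f_h.extended), beta
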
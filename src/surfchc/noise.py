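"""Conserved Gaussian noise for the Cahn-Hilliard-Cook system.

At each band node's closest point a random tangential vector
rho = rho1 t + rho2 b is drawn with independent standard normals; the
forcing is its surface divergence,

    xi = sqrt(sigma nu(f) / (h^2 dt)) * div_s(rho~),

computed with the closest point pattern: extend each Cartesian component,
take the centred Cartesian divergence, and re-extend.  Built from a
divergence, xi integrates to zero over the surface (conserved noise), and
the amplitude follows the discrete fluctuation-dissipation variance
(one surface Laplacian of a delta, variance proportional to
sigma nu / (dt h^2)).  Draws are counter-based in (seed, step): fresh and
uncorrelated every time step, bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import NarrowBand
from .model import ModelParams, mobility
from .operators import BandOperators, SurfaceField

__all__ = ["NoiseRealization", "sample_tangential_field", "conserved_noise"]


@dataclass
class NoiseRealization:
    """Tangential random field and (optionally) the resulting forcing."""

    rho: np.ndarray            # (nb, 3), tangent to the surface at cp
    seed: int
    step: int
    xi: SurfaceField | None = None


def _rng(seed: int, step: int) -> np.random.Generator:
    # Philox is counter-based: keyed by the realization seed, with the time
    # step in the counter, so (seed, step) -> stream is order-independent.
    return np.random.Generator(
        np.random.Philox(key=np.uint64(seed), counter=[0, 0, 0, step]))


def sample_tangential_field(band: NarrowBand, seed: int,
                            step: int = 0) -> NoiseRealization:
    """Draw rho = rho1 t + rho2 b at each band node's closest point."""
    g = _rng(seed, step)
    r = g.standard_normal((band.size, 2))
    rho = r[:, :1] * band.tangent + r[:, 1:2] * band.bitangent
    return NoiseRealization(rho=rho, seed=seed, step=step)


def conserved_noise(rho: NoiseRealization, f: SurfaceField,
                    params: ModelParams, ops: BandOperators
                    ) -> SurfaceField:
    """Scalar conserved forcing xi from a tangential realization.

    The mobility factor is evaluated pointwise at the current extended
    field (explicit, Ito-style placement), making the noise multiplicative
    for the degenerate mobility.
    """
    if params.sigma < 0:
        raise ValueError("sigma must be non-negative")
    nb = ops.band.size
    if params.sigma == 0.0:
        xi = SurfaceField(np.zeros(nb), extended=True)
        rho.xi = xi
        return xi
    if not f.extended:
        raise ValueError("f must be extended before computing the noise")
    h = ops.grid.h
    div = np.zeros(nb)
    for k in range(3):
        comp = ops.E3 @ rho.rho[:, k]
        div += ops.D[k] @ comp
    div = ops.E3 @ div
    nu = mobility(f.values, params.mobility_kind)
    amp = np.sqrt(params.sigma * nu / (h**2 * params.dt))
    xi = SurfaceField(amp * div, extended=True)
    rho.xi = xi
    return xi
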
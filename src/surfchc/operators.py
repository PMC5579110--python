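"""Discrete closest point operators on the narrow band.

The surface Laplacian is realized in the embedding space as

    M  = E1 L  + alpha (E3 - I),      alpha = 6 / h^2,

where E1/E3 interpolate a band field to each node's closest surface point
with tensor-product linear/cubic polynomials, L is the standard 7-point
Cartesian Laplacian and the alpha term is the side condition forcing
solutions to be constant along surface normals.  The variable-coefficient
version M^nu uses a conservative face-flux discretization of
div(nu grad .) in place of L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import GridSpec, NarrowBand

__all__ = [
    "SurfaceField",
    "interpolation_operator",
    "cartesian_laplacian",
    "variable_laplacian",
    "gradient_operator",
    "surface_laplacian_operator",
    "side_condition_alpha",
    "dump_operator",
]


def dump_operator(op: "sp.spmatrix", path) -> None:
    """Write an assembled operator to a Matrix Market file (debugging)."""
    from scipy.io import mmwrite
    mmwrite(str(path), op.tocoo())


@dataclass
class SurfaceField:
    """Scalar values on band nodes.

    ``extended`` is set once the values are constant along surface normals
    (i.e. after applying E3); several operations require extended inputs.
    """

    values: np.ndarray
    extended: bool = False

    def copy(self) -> "SurfaceField":
        return SurfaceField(self.values.copy(), self.extended)


def side_condition_alpha(grid: GridSpec) -> float:
    """The side-condition constant alpha = 6/h^2 (fixed, not tunable)."""
    return 6.0 / grid.h**2


class StencilError(RuntimeError):
    pass


def _lagrange_weights_1d(s: np.ndarray, degree: int) -> np.ndarray:
    """Weights of the 1D Lagrange interpolant on nodes 0..degree at s."""
    if degree == 1:
        return np.stack([1.0 - s, s], axis=-1)
    # degree 3, nodes 0,1,2,3
    w0 = -(s - 1.0) * (s - 2.0) * (s - 3.0) / 6.0
    w1 = s * (s - 2.0) * (s - 3.0) / 2.0
    w2 = -s * (s - 1.0) * (s - 3.0) / 2.0
    w3 = s * (s - 1.0) * (s - 2.0) / 6.0
    return np.stack([w0, w1, w2, w3], axis=-1)


def interpolation_operator(band: NarrowBand, grid: GridSpec,
                           degree: int) -> sp.csr_matrix:
    """Sparse operator whose i-th row interpolates a band field at cp(i).

    Tensor-product Lagrange polynomials of the given degree (1 or 3) on the
    2^3 or 4^3 grid cell stencil surrounding the closest point.  Rows sum to
    one (constants are reproduced); degree-3 weights may be negative.
    Raises ``StencilError`` if a stencil node is outside the band.
    """
    if degree not in (1, 3):
        raise ValueError("degree must be 1 or 3")
    h = grid.h
    n = grid.n
    npts = degree + 1
    lower = np.asarray(grid.lower)

    rel = (band.cp - lower) / h
    if degree == 1:
        base = np.floor(rel).astype(np.int64)
    else:
        base = np.floor(rel).astype(np.int64) - 1
    base = np.clip(base, 0, n - npts)
    s = rel - base  # in [0, npts-1]

    w = [_lagrange_weights_1d(s[:, d], degree) for d in range(3)]
    # tensor product over the stencil cube
    nb = band.size
    wx = w[0][:, :, None, None]
    wy = w[1][:, None, :, None]
    wz = w[2][:, None, None, :]
    weights = (wx * wy * wz).reshape(nb, npts**3)

    off = np.arange(npts)
    oi, oj, ok = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.column_stack([oi.ravel(), oj.ravel(), ok.ravel()])
    idx = base[:, None, :] + offsets[None, :, :]
    rav = (idx[..., 0] * n + idx[..., 1]) * n + idx[..., 2]
    cols = band.lookup(rav.reshape(-1)).reshape(nb, npts**3)

    bad = (cols < 0) & (np.abs(weights) > 1e-14)
    if np.any(bad):
        node = int(np.argwhere(np.any(bad, axis=1))[0, 0])
        raise StencilError(
            f"interpolation stencil of band node {node} "
            f"(grid index {tuple(band.indices[node])}) leaves the band; "
            f"increase the band half-width")
    cols = np.where(cols < 0, 0, cols)
    rows = np.repeat(np.arange(nb), npts**3)
    mat = sp.csr_matrix((weights.ravel(), (rows, cols.ravel())),
                        shape=(nb, nb))
    mat.eliminate_zeros()
    return mat


def cartesian_laplacian(band: NarrowBand, grid: GridSpec) -> sp.csr_matrix:
    """Second-order 7-point Laplacian, 1/h^2 scaling.

    Rows are assembled only at interior band nodes (all six neighbours
    present); remaining rows are zero and must not be consumed — the
    composite surface operator checks this at assembly time.
    """
    h2 = grid.h**2
    nb = band.size
    interior = np.flatnonzero(band.interior)
    rows = np.repeat(interior, 7)
    cols = np.column_stack([band.neighbors[interior], interior]).ravel()
    data = np.tile(np.array([1, 1, 1, 1, 1, 1, -6.0]) / h2,
                   interior.size)
    return sp.csr_matrix((data, (rows, cols)), shape=(nb, nb))


def variable_laplacian(band: NarrowBand, grid: GridSpec,
                       nu: SurfaceField) -> sp.csr_matrix:
    """Conservative face-flux discretization of div(nu grad .).

    Face mobilities are arithmetic means of the adjacent node values,
    so nu == 1 reproduces :func:`cartesian_laplacian` row for row.
    Raises if nu is negative anywhere (mobility must be >= 0) or not
    extended off the surface.
    """
    vals = np.asarray(nu.values, dtype=float)
    if not nu.extended:
        raise ValueError("nu must be extended off the surface")
    if np.any(vals < 0):
        raise ValueError("mobility must be non-negative")
    h2 = grid.h**2
    nb = band.size
    interior = np.flatnonzero(band.interior)
    neigh = band.neighbors[interior]                       # (m, 6)
    nu_face = 0.5 * (vals[interior][:, None] + vals[neigh])  # (m, 6)
    rows = np.repeat(interior, 7)
    cols = np.column_stack([neigh, interior]).ravel()
    data = np.column_stack([nu_face, -np.sum(nu_face, axis=1)]).ravel() / h2
    return sp.csr_matrix((data, (rows, cols)), shape=(nb, nb))


def gradient_operator(band: NarrowBand, grid: GridSpec,
                      axis: int) -> sp.csr_matrix:
    """Centred first difference along a Cartesian axis (interior rows)."""
    nb = band.size
    interior = np.flatnonzero(band.interior)
    plus = band.neighbors[interior, 2 * axis]
    minus = band.neighbors[interior, 2 * axis + 1]
    rows = np.concatenate([interior, interior])
    cols = np.concatenate([plus, minus])
    c = 1.0 / (2.0 * grid.h)
    data = np.concatenate([np.full(interior.size, c),
                           np.full(interior.size, -c)])
    return sp.csr_matrix((data, (rows, cols)), shape=(nb, nb))


def surface_laplacian_operator(E1: sp.csr_matrix, E3: sp.csr_matrix,
                               L: sp.csr_matrix, alpha: float,
                               band: NarrowBand | None = None
                               ) -> sp.csr_matrix:
    """Composite closest point surface Laplacian M = E1 L + alpha (E3 - I).

    With the variable-coefficient Laplacian in place of L this yields M^nu.
    If a band is supplied, verifies that every Laplacian row consumed
    through E1 was actually assembled (stencil completeness).
    """
    if band is not None:
        needed = np.unique(E1.indices)
        missing = needed[~band.interior[needed]]
        if missing.size:
            raise StencilError(
                f"Laplacian stencil incomplete at band node {int(missing[0])}; "
                f"increase the band half-width")
    nb = E1.shape[0]
    return (E1 @ L + alpha * (E3 - sp.identity(nb, format="csr"))).tocsr()


@dataclass
class BandOperators:
    """Pre-assembled constant operators on a band, shared by the solver,
    noise and observable computations."""

    band: NarrowBand
    grid: GridSpec
    alpha: float
    E1: sp.csr_matrix
    E3: sp.csr_matrix
    L: sp.csr_matrix
    M: sp.csr_matrix               # constant-coefficient surface Laplacian
    D: tuple = field(default=None)  # centred gradients (Dx, Dy, Dz)

    @classmethod
    def build(cls, band: NarrowBand) -> "BandOperators":
        grid = band.grid
        alpha = side_condition_alpha(grid)
        E1 = interpolation_operator(band, grid, 1)
        E3 = interpolation_operator(band, grid, 3)
        L = cartesian_laplacian(band, grid)
        M = surface_laplacian_operator(E1, E3, L, alpha, band=band)
        D = tuple(gradient_operator(band, grid, a) for a in range(3))
        return cls(band=band, grid=grid, alpha=alpha, E1=E1, E3=E3, L=L,
                   M=M, D=D)

    def variable_surface_laplacian(self, nu: SurfaceField) -> sp.csr_matrix:
        Lnu = variable_laplacian(self.band, self.grid, nu)
        return surface_laplacian_operator(self.E1, self.E3, Lnu, self.alpha)

    def extend(self, f: SurfaceField | np.ndarray) -> SurfaceField:
        """Make a field constant along normals by one application of E3."""
        vals = f.values if isinstance(f, SurfaceField) else np.asarray(f)
        return SurfaceField(self.E3 @ vals, extended=True)

    def surface_gradient(self, f: SurfaceField) -> np.ndarray:
        """Projected Cartesian gradient P grad f, P = I - n (x) n; (nb, 3).

        Valid at interior nodes; non-interior rows are zero.
        """
        if not f.extended:
            raise ValueError("field must be extended")
        g = np.stack([Dk @ f.values for Dk in self.D], axis=-1)
        n = self.band.normal
        return g - n * np.sum(g * n, axis=-1, keepdims=True)
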
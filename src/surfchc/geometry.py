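"""Implicit surface geometry for the closest point method.

A static surface is described by a signed distance function phi, its
gradient, and a closest-point map, all evaluated on (subsets of) a uniform
Cartesian grid.  The computation itself lives on a *narrow band* of grid
nodes within a prescribed distance of the zero level set; each band node
carries its closest surface point, signed distance, outward unit normal and
an orthonormal tangent pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "GridSpec",
    "LevelSetGeometry",
    "NarrowBand",
    "sphere_geometry",
    "dumbbell_geometry",
    "build_band",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform cubic Cartesian grid.

    The default domain is the cube [-1.25, 1.25]^3 used for the unit-sphere
    runs; ``n`` is the number of nodes per axis, so the spacing is
    ``h = extent / (n - 1)`` and is identical in all three axes.
    """

    n: int
    lower: tuple[float, float, float] = (-1.25, -1.25, -1.25)
    upper: tuple[float, float, float] = (1.25, 1.25, 1.25)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("grid needs at least two nodes per axis")
        ext = np.asarray(self.upper) - np.asarray(self.lower)
        if np.any(ext <= 0):
            raise ValueError("upper must exceed lower in every axis")
        h = ext / (self.n - 1)
        if not np.allclose(h, h[0], rtol=1e-12, atol=0.0):
            raise ValueError("grid spacing must be identical in all axes")

    @property
    def h(self) -> float:
        return (self.upper[0] - self.lower[0]) / (self.n - 1)

    def axis(self, d: int) -> np.ndarray:
        return self.lower[d] + self.h * np.arange(self.n)

    def node_coords(self, idx: np.ndarray) -> np.ndarray:
        """Physical coordinates of integer grid indices, shape (m, 3)."""
        return np.asarray(self.lower) + self.h * np.asarray(idx, dtype=float)


@dataclass(frozen=True)
class LevelSetGeometry:
    """Implicit surface: signed distance, gradient and closest-point map.

    ``phi`` maps (m, 3) points to (m,) signed distances (negative inside),
    ``grad_phi`` to (m, 3) gradients, and ``closest_point`` to (m, 3) surface
    points.  For the analytic shapes here phi is an exact signed distance
    away from the medial skeleton.
    """

    name: str
    phi: Callable[[np.ndarray], np.ndarray]
    grad_phi: Callable[[np.ndarray], np.ndarray]
    closest_point: Callable[[np.ndarray], np.ndarray]


@dataclass
class NarrowBand:
    """Band of grid nodes with |phi| <= half_width plus per-node frames.

    Nodes are ordered lexicographically by (i, j, k) so band construction is
    deterministic.  ``ravel`` holds ``i*n^2 + j*n + k`` for O(log n) lookup
    of neighbours via searchsorted.
    """

    grid: GridSpec
    geom: LevelSetGeometry
    half_width: float
    indices: np.ndarray        # (nb, 3) int
    ravel: np.ndarray          # (nb,) int, sorted ascending
    coords: np.ndarray         # (nb, 3) float
    phi: np.ndarray            # (nb,)
    cp: np.ndarray             # (nb, 3)
    normal: np.ndarray         # (nb, 3)
    tangent: np.ndarray        # (nb, 3)
    bitangent: np.ndarray      # (nb, 3)
    neighbors: np.ndarray = field(default=None)   # (nb, 6) band positions or -1
    interior: np.ndarray = field(default=None)    # (nb,) bool: all 6 neighbours present

    @property
    def size(self) -> int:
        return self.indices.shape[0]

    def lookup(self, ravel_ids: np.ndarray) -> np.ndarray:
        """Band positions of raveled grid ids; -1 where not in the band."""
        pos = np.searchsorted(self.ravel, ravel_ids)
        pos = np.clip(pos, 0, self.size - 1)
        ok = self.ravel[pos] == ravel_ids
        return np.where(ok, pos, -1)


def sphere_geometry(radius: float = 1.0,
                    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
                    ) -> LevelSetGeometry:
    """Exact signed distance geometry of a sphere.

    phi(x) = |x - c| - r.  The closest-point map is the radial projection;
    the center itself has no unique closest point and is sent to an arbitrary
    surface point (it can never lie in a narrow band of width < r).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = np.asarray(center, dtype=float)
    r = float(radius)

    def phi(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.linalg.norm(x - c, axis=-1) - r

    def grad(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = x - c
        nrm = np.linalg.norm(d, axis=-1, keepdims=True)
        safe = np.where(nrm > 0, nrm, 1.0)
        g = d / safe
        g[(nrm == 0).ravel()] = np.array([1.0, 0.0, 0.0])
        return g

    def cp(x):
        return c + r * grad(x)

    return LevelSetGeometry(f"sphere(r={r})", phi, grad, cp)


# Dumbbell dimensions: two spheres of radius 0.75 centred at (+-1.125, 0, 0)
# joined by a cylinder of radius 0.375 along the x axis.
_DB_SPHERE_R = 0.75
_DB_SPHERE_X = 1.125
_DB_CYL_R = 0.375
# Junction circles: sphere and cylinder intersect where sqrt(y^2+z^2) = 0.375
# on the sphere, i.e. at |x| = 1.125 - sqrt(0.75^2 - 0.375^2).
_DB_JUNCTION_X = _DB_SPHERE_X - np.sqrt(_DB_SPHERE_R**2 - _DB_CYL_R**2)


def _db_sphere_phi(x, sx):
    return np.linalg.norm(x - np.array([sx, 0.0, 0.0]), axis=-1) - _DB_SPHERE_R


def _db_cyl_phi(x):
    """Signed distance to the finite cylinder |x0| <= 1.125, rho = 0.375."""
    rho = np.hypot(x[..., 1], x[..., 2])
    dr = rho - _DB_CYL_R
    dx = np.abs(x[..., 0]) - _DB_SPHERE_X
    outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dx, 0.0))
    inside = np.minimum(np.maximum(dr, dx), 0.0)
    return outside + inside


def dumbbell_geometry() -> LevelSetGeometry:
    """Dumbbell: union of two spheres and a connecting cylinder.

    phi is the min of the three primitive signed distances — a true signed
    distance except near the interior skeleton of the union.  Closest points
    are found by projecting onto each primitive, discarding candidates that
    fall strictly inside the union, and adding the two junction circles as
    explicit candidates (the nearest boundary point of nodes facing the
    concave sphere/cylinder crease lies on those circles).
    """
    centers = np.array([[-_DB_SPHERE_X, 0.0, 0.0], [_DB_SPHERE_X, 0.0, 0.0]])

    def phi(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.minimum(
            np.minimum(_db_sphere_phi(x, -_DB_SPHERE_X),
                       _db_sphere_phi(x, _DB_SPHERE_X)),
            _db_cyl_phi(x))

    def grad(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = phi(x)
        cpx = cp(x)
        d = x - cpx
        nrm = np.linalg.norm(d, axis=-1, keepdims=True)
        g = np.where(nrm > 1e-13, d / np.where(nrm > 0, nrm, 1.0), 0.0)
        g = g * np.sign(p)[:, None]
        # on-surface points: fall back to the active primitive's gradient
        deg = nrm.ravel() <= 1e-13
        if np.any(deg):
            g[deg] = _db_primitive_grad(x[deg])
        return g

    def _db_primitive_grad(x):
        vals = np.stack([_db_sphere_phi(x, -_DB_SPHERE_X),
                         _db_sphere_phi(x, _DB_SPHERE_X),
                         _db_cyl_phi(x)], axis=-1)
        which = np.argmin(vals, axis=-1)
        g = np.empty_like(x)
        for w, cen in ((0, centers[0]), (1, centers[1])):
            m = which == w
            if np.any(m):
                d = x[m] - cen
                g[m] = d / np.linalg.norm(d, axis=-1, keepdims=True)
        m = which == 2
        if np.any(m):
            rho = np.hypot(x[m, 1], x[m, 2])
            safe = np.where(rho > 0, rho, 1.0)
            g[m, 0] = 0.0
            g[m, 1] = x[m, 1] / safe
            g[m, 2] = x[m, 2] / safe
        return g

    def cp(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        m = x.shape[0]
        cands = np.full((m, 5, 3), np.nan)
        valid = np.zeros((m, 5), dtype=bool)

        for s, cen in enumerate(centers):
            d = x - cen
            nrm = np.linalg.norm(d, axis=-1, keepdims=True)
            safe = np.where(nrm > 0, nrm, 1.0)
            proj = cen + _DB_SPHERE_R * d / safe
            cands[:, s] = proj
            # valid if on the union boundary: not strictly inside another
            # primitive (tolerance keeps the junction circle itself valid)
            others = np.minimum(_db_sphere_phi(proj, -np.sign(cen[0]) * _DB_SPHERE_X),
                                _db_cyl_phi(proj))
            valid[:, s] = (others >= -1e-12) & (nrm.ravel() > 0)

        # cylinder barrel projection (caps lie inside the spheres, never on
        # the union boundary)
        rho = np.hypot(x[:, 1], x[:, 2])
        safe = np.where(rho > 0, rho, 1.0)
        barrel = np.empty((m, 3))
        barrel[:, 0] = np.clip(x[:, 0], -_DB_SPHERE_X, _DB_SPHERE_X)
        barrel[:, 1] = _DB_CYL_R * x[:, 1] / safe
        barrel[:, 2] = _DB_CYL_R * x[:, 2] / safe
        cands[:, 2] = barrel
        others = np.minimum(_db_sphere_phi(barrel, -_DB_SPHERE_X),
                            _db_sphere_phi(barrel, _DB_SPHERE_X))
        valid[:, 2] = (others >= -1e-12) & (rho > 0)

        # junction circles at x = +-junction_x, radius = cylinder radius
        for j, jx in enumerate((-_DB_JUNCTION_X, _DB_JUNCTION_X)):
            circ = np.empty((m, 3))
            circ[:, 0] = jx
            circ[:, 1] = _DB_CYL_R * x[:, 1] / safe
            circ[:, 2] = _DB_CYL_R * x[:, 2] / safe
            # points on the axis have no unique circle point; pick +y
            axis = rho == 0
            circ[axis, 1] = _DB_CYL_R
            circ[axis, 2] = 0.0
            cands[:, 3 + j] = circ
            valid[:, 3 + j] = True

        d2 = np.sum((cands - x[:, None, :]) ** 2, axis=-1)
        d2[~valid] = np.inf
        best = np.argmin(d2, axis=1)
        return cands[np.arange(m), best]

    return LevelSetGeometry("dumbbell", phi, grad, cp)


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal (t, b) with t = normalize(n x e_k) where e_k
    is the coordinate axis least aligned with n, and b = n x t."""
    n = normal
    k = np.argmin(np.abs(n), axis=-1)
    e = np.zeros_like(n)
    e[np.arange(n.shape[0]), k] = 1.0
    t = np.cross(n, e)
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    b = np.cross(n, t)
    return t, b


def build_band(geom: LevelSetGeometry, grid: GridSpec,
               half_width: float | None = None) -> NarrowBand:
    """Collect grid nodes with |phi| <= half_width and attach frames.

    The default half-width, 6*sqrt(3)*h, conservatively contains every
    tricubic interpolation stencil with a guard layer; simulation configs
    typically use 4h, the tight bound for the composite closest point
    operators.  Raises if the band is empty (surface outside the domain).
    """
    h = grid.h
    if half_width is None:
        half_width = 6.0 * np.sqrt(3.0) * h
    if half_width <= 0:
        raise ValueError("half_width must be positive")

    ax = grid.axis(0)
    ay = grid.axis(1)
    az = grid.axis(2)
    # evaluate phi on the full grid in z-slabs to bound memory
    n = grid.n
    keep_idx = []
    keep_phi = []
    X, Y = np.meshgrid(ax, ay, indexing="ij")
    for kz in range(n):
        pts = np.column_stack([X.ravel(), Y.ravel(),
                               np.full(X.size, az[kz])])
        p = geom.phi(pts)
        sel = np.abs(p) <= half_width
        if np.any(sel):
            ij = np.argwhere(sel.reshape(n, n))
            ijk = np.column_stack([ij, np.full(ij.shape[0], kz)])
            keep_idx.append(ijk)
            keep_phi.append(p[sel])
    if not keep_idx:
        raise ValueError("narrow band is empty: surface does not intersect "
                         "the computational domain")
    indices = np.concatenate(keep_idx)
    phi = np.concatenate(keep_phi)
    # lexicographic (i, j, k) order == sorted ravel order
    ravel = (indices[:, 0] * n + indices[:, 1]) * n + indices[:, 2]
    order = np.argsort(ravel, kind="stable")
    indices = indices[order]
    ravel = ravel[order]
    phi = phi[order]

    coords = grid.node_coords(indices)
    cp = geom.closest_point(coords)
    # normal at the node's closest point; for |phi| ~ 0 fall back to grad phi
    d = coords - cp
    dn = np.linalg.norm(d, axis=-1, keepdims=True)
    sign = np.where(phi >= 0, 1.0, -1.0)
    normal = np.where(dn > 1e-12 * max(h, 1.0),
                      d / np.where(dn > 0, dn, 1.0) * sign[:, None],
                      geom.grad_phi(coords))
    normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
    tangent, bitangent = _tangent_frame(normal)

    band = NarrowBand(grid=grid, geom=geom, half_width=float(half_width),
                      indices=indices, ravel=ravel, coords=coords, phi=phi,
                      cp=cp, normal=normal, tangent=tangent,
                      bitangent=bitangent)
    _attach_neighbors(band)
    return band


def _attach_neighbors(band: NarrowBand) -> None:
    n = band.grid.n
    offs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    nb = band.size
    neigh = np.full((nb, 6), -1, dtype=np.int64)
    for a, off in enumerate(offs):
        idx = band.indices + off
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        rav = (idx[:, 0] * n + idx[:, 1]) * n + idx[:, 2]
        pos = band.lookup(np.where(ok, rav, 0))
        neigh[:, a] = np.where(ok, pos, -1)
    band.neighbors = neigh
    band.interior = np.all(neigh >= 0, axis=1)
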
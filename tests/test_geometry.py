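"""Geometry: signed distances, closest points, narrow band construction."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import surfchc as sc
from surfchc.geometry import _DB_JUNCTION_X, _DB_CYL_R, _DB_SPHERE_R, _DB_SPHERE_X


class TestSphere:
    def test_signed_distance_examples(self):
        g = sc.sphere_geometry()
        assert g.phi([[0, 0, 0]])[0] == pytest.approx(-1.0)
        assert g.phi([[1, 0, 0]])[0] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(g.closest_point([[0, 0, 2]])[0],
                                   [0, 0, 1], atol=1e-15)

    def test_gradient_is_unit_away_from_center(self):
        g = sc.sphere_geometry()
        rng = np.random.default_rng(0)
        x = rng.normal(size=(500, 3))
        r = np.linalg.norm(x, axis=1)
        x = x[(r > 0.2) & (r < 2.0)][:100]
        norms = np.linalg.norm(g.grad_phi(x), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_closest_point_exact(self):
        g = sc.sphere_geometry(radius=0.7, center=(0.1, -0.2, 0.3))
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, size=(200, 3))
        cp = g.closest_point(x)
        # on the surface, and |x - cp| = |phi|
        assert np.abs(g.phi(cp)).max() < 1e-14
        d = np.linalg.norm(x - cp, axis=1)
        np.testing.assert_allclose(d, np.abs(g.phi(x)), atol=1e-13)


def _dumbbell_surface_cloud(n_total=1_000_000):
    """Dense parametric sampling of the dumbbell surface (oracle)."""
    rng = np.random.default_rng(42)
    # spheres: keep points outside the cylinder region
    pts = []
    for sx in (-_DB_SPHERE_X, _DB_SPHERE_X):
        u = rng.normal(size=(n_total // 3, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p = np.array([sx, 0, 0]) + _DB_SPHERE_R * u
        keep = (np.hypot(p[:, 1], p[:, 2]) >= _DB_CYL_R) | \
               (np.abs(p[:, 0]) > _DB_SPHERE_X)
        pts.append(p[keep])
    theta = rng.uniform(0, 2 * np.pi, n_total // 3)
    x = rng.uniform(-_DB_JUNCTION_X, _DB_JUNCTION_X, n_total // 3)
    pts.append(np.column_stack([x, _DB_CYL_R * np.cos(theta),
                                _DB_CYL_R * np.sin(theta)]))
    return np.vstack(pts)


class TestDumbbell:
    def test_closest_point_examples(self):
        g = sc.dumbbell_geometry()
        np.testing.assert_allclose(g.closest_point([[2.5, 0, 0]])[0],
                                   [1.875, 0, 0], atol=1e-14)
        np.testing.assert_allclose(g.closest_point([[0, 1, 0]])[0],
                                   [0, 0.375, 0], atol=1e-14)

    def test_closest_point_matches_brute_force_near_junction(self):
        g = sc.dumbbell_geometry()
        cloud = _dumbbell_surface_cloud()
        tree = cKDTree(cloud)
        rng = np.random.default_rng(7)
        # points scattered around the right junction circle
        x = np.column_stack([
            rng.uniform(_DB_JUNCTION_X - 0.3, _DB_JUNCTION_X + 0.3, 50),
            rng.uniform(-0.8, 0.8, 50),
            rng.uniform(-0.8, 0.8, 50)])
        cp = g.closest_point(x)
        d_cp = np.linalg.norm(x - cp, axis=1)
        d_oracle, _ = tree.query(x)
        h = 2.5 / 32
        # our cp distance can only beat the sampled oracle slightly
        assert np.all(d_cp <= d_oracle + 1e-8)
        assert np.all(np.abs(d_cp - d_oracle) < 2 * h)

    def test_band_closest_points_on_surface(self, dumbbell_band_33):
        band = dumbbell_band_33
        assert np.abs(band.geom.phi(band.cp)).max() <= 1e-10


class TestBand:
    def test_node_set_matches_brute_force(self):
        grid = sc.GridSpec(n=33)
        g = sc.sphere_geometry()
        band = sc.build_band(g, grid, 4 * grid.h)
        ax = grid.axis(0)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        expect = int(np.sum(np.abs(g.phi(pts)) <= 4 * grid.h))
        assert band.size == expect

    def test_frames_orthonormal(self, sphere_band_21, dumbbell_band_33):
        for band in (sphere_band_21, dumbbell_band_33):
            n, t, b = band.normal, band.tangent, band.bitangent
            for u, v in ((n, t), (n, b), (t, b)):
                assert np.abs(np.sum(u * v, axis=1)).max() < 1e-12
            for u in (n, t, b):
                np.testing.assert_allclose(np.linalg.norm(u, axis=1), 1.0,
                                           atol=1e-12)
            # right-handed up to the sign convention of n
            cross = np.cross(t, b)
            err = np.minimum(np.linalg.norm(cross - n, axis=1),
                             np.linalg.norm(cross + n, axis=1))
            assert err.max() <= 1e-12

    def test_deterministic_ordering(self):
        grid = sc.GridSpec(n=21)
        g = sc.sphere_geometry()
        b1 = sc.build_band(g, grid, 4 * grid.h)
        b2 = sc.build_band(g, grid, 4 * grid.h)
        np.testing.assert_array_equal(b1.indices, b2.indices)
        np.testing.assert_array_equal(b1.cp, b2.cp)

    def test_origin_shift_preserves_invariants(self):
        # shifting the grid origin by < h/2 must not break any band contract
        grid = sc.GridSpec(n=21)
        d = 0.4 * grid.h
        shifted = sc.GridSpec(n=21, lower=(-1.25 + d,) * 3,
                              upper=(1.25 + d,) * 3)
        band = sc.build_band(sc.sphere_geometry(), shifted, 4 * shifted.h)
        assert band.size > 0
        assert np.abs(band.geom.phi(band.cp)).max() < 1e-12
        assert np.abs(np.sum(band.normal * band.tangent, axis=1)).max() < 1e-12

    def test_empty_band_is_an_error(self):
        grid = sc.GridSpec(n=9, lower=(5.0, 5.0, 5.0), upper=(6.0, 6.0, 6.0))
        with pytest.raises(ValueError, match="empty"):
            sc.build_band(sc.sphere_geometry(), grid, 2 * grid.h)
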
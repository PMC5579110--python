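"""Closest point operators: interpolation, Laplacians, surface Laplacian."""

import numpy as np
import pytest
import scipy.sparse as sp

import surfchc as sc
from surfchc.operators import StencilError, gradient_operator


class TestInterpolation:
    @pytest.mark.parametrize("degree", [1, 3])
    def test_rows_sum_to_one(self, sphere_band_21, degree):
        E = sc.interpolation_operator(sphere_band_21, sphere_band_21.grid,
                                      degree)
        np.testing.assert_allclose(np.asarray(E.sum(axis=1)).ravel(), 1.0,
                                   atol=1e-13)

    def test_linear_reproduction(self, sphere_band_21):
        band = sphere_band_21
        E1 = sc.interpolation_operator(band, band.grid, 1)
        f = band.coords @ np.array([1.0, 2.0, -1.0])
        expect = band.cp @ np.array([1.0, 2.0, -1.0])
        np.testing.assert_allclose(E1 @ f, expect, atol=1e-12)

    def test_cubic_reproduction_matches_direct_evaluation(self,
                                                          sphere_band_21):
        band = sphere_band_21
        E3 = sc.interpolation_operator(band, band.grid, 3)
        poly = lambda p: p[:, 0] ** 2 * p[:, 1]
        np.testing.assert_allclose(E3 @ poly(band.coords), poly(band.cp),
                                   atol=1e-12)

    def test_incomplete_stencil_raises(self):
        grid = sc.GridSpec(n=21)
        band = sc.build_band(sc.sphere_geometry(), grid, 1.2 * grid.h)
        with pytest.raises(StencilError, match="band node"):
            sc.interpolation_operator(band, grid, 3)


class TestCartesianLaplacian:
    def test_exact_on_quadratics_and_constants(self, sphere_band_21):
        band = sphere_band_21
        L = sc.cartesian_laplacian(band, band.grid)
        x2 = band.coords[:, 0] ** 2
        got = L @ x2
        np.testing.assert_allclose(got[band.interior], 2.0, atol=1e-10)
        np.testing.assert_allclose(L @ np.ones(band.size), 0.0, atol=1e-12)

    def test_matches_dense_stencil_oracle(self, sphere_band_21):
        band = sphere_band_21
        n, h = band.grid.n, band.grid.h
        L = sc.cartesian_laplacian(band, band.grid)
        rng = np.random.default_rng(3)
        f = rng.normal(size=band.size)
        # scatter to the full grid and convolve with the 7-point stencil
        full = np.zeros((n, n, n))
        i, j, k = band.indices.T
        full[i, j, k] = f
        lap = (np.roll(full, 1, 0) + np.roll(full, -1, 0)
               + np.roll(full, 1, 1) + np.roll(full, -1, 1)
               + np.roll(full, 1, 2) + np.roll(full, -1, 2)
               - 6 * full) / h**2
        got = L @ f
        sel = band.interior
        np.testing.assert_allclose(got[sel], lap[i[sel], j[sel], k[sel]],
                                   atol=1e-12 / h**2)


class TestVariableLaplacian:
    def test_unit_mobility_reduces_to_constant_laplacian(self,
                                                         sphere_band_21):
        band = sphere_band_21
        one = sc.SurfaceField(np.ones(band.size), extended=True)
        Lv = sc.variable_laplacian(band, band.grid, one)
        L = sc.cartesian_laplacian(band, band.grid)
        assert abs(Lv - L).max() < 1e-12

    def test_zero_mobility_gives_zero_operator(self, sphere_band_21):
        band = sphere_band_21
        zero = sc.SurfaceField(np.zeros(band.size), extended=True)
        Lv = sc.variable_laplacian(band, band.grid, zero)
        assert abs(Lv).max() == 0.0

    def test_negative_mobility_rejected(self, sphere_band_21):
        band = sphere_band_21
        bad = sc.SurfaceField(np.full(band.size, -0.1), extended=True)
        with pytest.raises(ValueError, match="non-negative"):
            sc.variable_laplacian(band, band.grid, bad)

    def test_divergence_form_is_self_adjoint(self, sphere_band_21):
        band = sphere_band_21
        rng = np.random.default_rng(5)
        nu = sc.SurfaceField(rng.uniform(0.1, 1.0, band.size), extended=True)
        Lv = sc.variable_laplacian(band, band.grid, nu)
        # restrict to nodes whose whole stencil has assembled rows
        deep = band.interior & np.all(
            np.where(band.neighbors >= 0,
                     band.interior[band.neighbors], False), axis=1)
        u = np.where(deep, rng.normal(size=band.size), 0.0)
        v = np.where(deep, rng.normal(size=band.size), 0.0)
        assert u @ (Lv @ v) == pytest.approx(v @ (Lv @ u), abs=1e-12 * band.size)


class TestSurfaceLaplacian:
    def test_annihilates_constants(self, sphere_ops_21):
        ops = sphere_ops_21
        out = ops.M @ np.ones(ops.band.size)
        assert np.abs(out).max() < 1e-10 * ops.alpha

    @pytest.mark.parametrize("l, harmonic", [
        (1, lambda p: p[:, 2]),
        (2, lambda p: p[:, 2] ** 2 - (p[:, 0] ** 2 + p[:, 1] ** 2) / 2),
    ])
    def test_spherical_harmonic_eigenvalues(self, sphere_ops_33, l, harmonic):
        # Laplace-Beltrami eigenvalue -l(l+1) on the unit sphere
        ops = sphere_ops_33
        y = harmonic(ops.band.cp)   # normal-extended by construction
        resid = ops.M @ y + l * (l + 1) * y
        rel = np.abs(resid).max() / np.abs(y).max()
        assert rel < 0.025   # second-order accurate at h = 2.5/32

    def test_extension_makes_fields_normal_constant(self, sphere_ops_21):
        ops = sphere_ops_21
        band = ops.band
        raw = np.sin(3 * band.coords[:, 0]) * band.coords[:, 1]
        ext = ops.extend(raw)
        # after extension, re-interpolating at the closest points is ~ a no-op
        again = ops.E3 @ ext.values
        assert np.abs(again - ext.values).max() < 5e-3 * np.abs(ext.values).max()


def test_gradient_operator_exact_on_linears(sphere_band_21):
    band = sphere_band_21
    Dx = gradient_operator(band, band.grid, 0)
    f = 2.0 * band.coords[:, 0] + band.coords[:, 1]
    got = Dx @ f
    np.testing.assert_allclose(got[band.interior], 2.0, atol=1e-11)
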
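"""BDF2 block solver: fixed points, accuracy, conservation, preconditioning."""

import numpy as np
import pytest

import surfchc as sc
from surfchc.solver import (make_s_inverse, schur_preconditioner,
                            solve_block_system)


@pytest.fixture(scope="module")
def small_setup():
    grid = sc.GridSpec(n=17)
    band = sc.build_band(sc.sphere_geometry(), grid, 4 * grid.h)
    ops = sc.BandOperators.build(band)
    return band, ops


def _uniform_state(ops, value, params):
    f = sc.SurfaceField(np.full(ops.band.size, float(value)), extended=True)
    m0 = sc.surface_integral(f, ops.band)
    mu = sc.SurfaceField(sc.g_prime(f.values), extended=True)
    return sc.SolverState(f=f, f_prev=f.copy(), mu=mu, t=0.0, step=1,
                          M0=m0, seed=0)


class TestFixedPoints:
    def test_pure_phase_zero(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-4)
        state = _uniform_state(ops, 0.0, p)
        xi = sc.SurfaceField(np.zeros(band.size), extended=True)
        system = sc.assemble_system(state, p, ops, xi)
        x, _ = solve_block_system(system, None, sc.SolverOptions())
        assert np.abs(system.matvec(x) - system.rhs).max() <= 1e-10
        nb = band.size
        assert np.abs(x[:nb]).max() <= 1e-10   # mu = 0
        assert np.abs(x[nb:]).max() <= 1e-10   # f = 0

    def test_uniform_state_is_stationary(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-4)
        state = _uniform_state(ops, 0.3, p)
        new = sc.bdf2_step(state, p, ops)
        np.testing.assert_allclose(new.f.values, 0.3, atol=1e-8)
        # mu = g'(0.3) = 2*0.3*0.7*0.4 = 0.168, uniform
        np.testing.assert_allclose(new.mu.values, 0.168, atol=1e-8)


class TestLinearSolve:
    def test_matches_dense_direct_solve(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-4, mobility_kind="degenerate")
        rng = np.random.default_rng(0)
        f = ops.extend(0.3 + 0.05 * np.sin(3 * band.coords[:, 0]))
        state = sc.SolverState(f=f, f_prev=f.copy(),
                               mu=ops.extend(sc.g_prime(f.values)),
                               t=0.0, step=2,
                               M0=sc.surface_integral(f, band), seed=0)
        xi = sc.SurfaceField(np.zeros(band.size), extended=True)
        system = sc.assemble_system(state, p, ops, xi)
        dense = system.matrix().toarray()
        expect = np.linalg.solve(dense, system.rhs)
        got, _ = solve_block_system(system, None,
                                    sc.SolverOptions(rtol=1e-12))
        assert np.abs(got - expect).max() <= 1e-8 * np.abs(expect).max()

    def test_rejects_unextended_history(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-4)
        f = sc.SurfaceField(np.full(band.size, 0.3), extended=False)
        state = sc.SolverState(f=f, f_prev=f, mu=f, t=0, step=1, M0=1.0)
        xi = sc.SurfaceField(np.zeros(band.size), extended=True)
        with pytest.raises(ValueError, match="extended"):
            sc.assemble_system(state, p, ops, xi)


class TestPreconditioner:
    def _random_system(self, ops, dt, seed):
        rng = np.random.default_rng(seed)
        p = sc.ModelParams(dt=dt, cn=0.1)
        f = ops.extend(0.3 + 0.1 * rng.normal(size=ops.band.size))
        state = sc.SolverState(f=f, f_prev=f.copy(),
                               mu=ops.extend(sc.g_prime(f.values)),
                               t=0.0, step=2,
                               M0=sc.surface_integral(f, ops.band), seed=0)
        xi = sc.SurfaceField(np.zeros(ops.band.size), extended=True)
        return p, sc.assemble_system(state, p, ops, xi)

    def test_small_dt_limit_converges_immediately(self, small_setup):
        band, ops = small_setup
        _, system = self._random_system(ops, dt=1e-12, seed=1)
        pre = schur_preconditioner(system)       # S ~ I
        _, iters = solve_block_system(system, None, sc.SolverOptions(),
                                      precond=pre)
        assert iters <= 3

    def test_preconditioned_solution_agrees(self, small_setup):
        band, ops = small_setup
        p, system = self._random_system(ops, dt=2e-3, seed=2)
        opts = sc.SolverOptions(rtol=1e-10)
        s_inv = make_s_inverse(ops, p, opts, c_bot=2 * p.dt / 3)
        x_pre, _ = solve_block_system(system, None, opts,
                                      schur_preconditioner(system, s_inv))
        x_raw, _ = solve_block_system(system, None, opts)
        assert np.abs(x_pre - x_raw).max() <= 1e-8 * np.abs(x_raw).max()

    def test_preconditioner_reduces_iterations(self, small_setup):
        band, ops = small_setup
        for seed in range(5):
            p, system = self._random_system(ops, dt=2e-3, seed=seed)
            opts = sc.SolverOptions(rtol=1e-8)
            s_inv = make_s_inverse(ops, p, opts, c_bot=2 * p.dt / 3)
            _, it_pre = solve_block_system(
                system, None, opts, schur_preconditioner(system, s_inv))
            _, it_raw = solve_block_system(system, None, opts)
            assert it_pre <= it_raw


class TestStepContracts:
    def test_mass_conserved_each_step(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=5.12e-3 * band.grid.h, cn=0.1)
        state = sc.initial_condition(p, band, ops, seed=3)
        m0 = state.M0
        for _ in range(5):
            state = sc.bdf2_step(state, p, ops)
            mass = sc.surface_integral(state.f, band)
            assert mass == pytest.approx(m0, rel=1e-12)

    def test_second_order_in_time(self, sphere_ops_33):
        # temporal self-convergence on a smooth state; the grid is fine
        # enough that the O(h^4) re-extension floor stays subdominant
        ops = sphere_ops_33
        band = ops.band
        T = 0.16

        def final(dt):
            p = sc.ModelParams(dt=dt, cn=0.1,
                               perturbation_amplitude=0.0)
            f = ops.extend(0.3 + 0.05 * band.cp[:, 2])
            state = sc.SolverState(f=f, f_prev=f.copy(),
                                   mu=ops.extend(sc.g_prime(f.values)),
                                   t=0.0, step=0,
                                   M0=sc.surface_integral(f, band), seed=0)
            opts = sc.SolverOptions(rtol=1e-10, s_inverse="identity",
                                    maxiter=500)
            for _ in range(int(round(T / dt))):
                state = sc.bdf2_step(state, p, ops, options=opts)
            return state.f.values

        f1, f2, f4 = final(T / 4), final(T / 8), final(T / 16)
        e1 = np.abs(f1 - f2).max()
        e2 = np.abs(f2 - f4).max()
        assert 2.5 < e1 / e2 < 6.5   # ~4 for a second-order scheme

    def test_deterministic_rerun_is_bitwise(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-3, cn=0.1, sigma=1e-5)
        r1 = sc.run_simulation(ops, p, t_end=5e-3, seed=9)
        r2 = sc.run_simulation(ops, p, t_end=5e-3, seed=9)
        np.testing.assert_array_equal(r1.state.f.values, r2.state.f.values)
        assert r1.series.r_bar == r2.series.r_bar

    def test_t_end_zero_records_initial_only(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-3)
        res = sc.run_simulation(ops, p, t_end=0.0, seed=1)
        assert len(res.series.t) == 1
        assert res.series.t[0] == 0.0

    def test_initial_condition_contracts(self, small_setup):
        band, ops = small_setup
        p = sc.ModelParams(dt=1e-3)
        s1 = sc.initial_condition(p, band, ops, seed=1)
        s2 = sc.initial_condition(p, band, ops, seed=1)
        s3 = sc.initial_condition(p, band, ops, seed=2)
        np.testing.assert_array_equal(s1.f.values, s2.f.values)
        assert not np.array_equal(s1.f.values, s3.f.values)
        assert np.all(np.abs(s1.f.values - 0.3) <= 0.0100001)
        flat = sc.initial_condition(
            sc.ModelParams(dt=1e-3, perturbation_amplitude=0.0),
            band, ops, seed=1)
        np.testing.assert_allclose(flat.f.values, 0.3, atol=1e-13)
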
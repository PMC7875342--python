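"""Time-stepping: conservation, positivity, kernel reductions, determinism."""

import numpy as np
import pytest

from gliofront import (
    Grid1D,
    ModelParams,
    SolverConfig,
    State,
    check_stability,
    divergence,
    simulate,
    step_mmp,
    step_others,
    step_tumor,
)
from gliofront.errors import SolverError
from gliofront.scenarios import ScenarioSpec, baseline_initial
from gliofront.solver import _step_mmp_kernel

NO_REACTIONS = dict(a3=0, a4=0, a5=0, a6=0, a7=0, a8=0, a9=0, v_Int=0)


def plateau_state(grid, params, t=0.0):
    return baseline_initial(ScenarioSpec(), params, grid)


class TestDivergence:
    def test_constant_interior_flux_zero_divergence(self, small_grid):
        J = np.zeros(small_grid.n_nodes + 1)
        J[1:-1] = 0.7
        rate = divergence(J, small_grid)
        assert np.allclose(rate[1:-1], 0.0)

    def test_telescoping_sum_is_zero(self, small_grid, rng):
        J = np.zeros(small_grid.n_nodes + 1)
        J[1:-1] = rng.normal(size=small_grid.n_nodes - 1)
        assert abs(divergence(J, small_grid).sum()) < 1e-10

    def test_linear_flux_gives_constant_divergence(self, small_grid):
        J = np.zeros(small_grid.n_nodes + 1)
        J[1:-1] = np.linspace(0, 1, small_grid.n_nodes - 1)
        rate = divergence(J, small_grid)
        assert np.allclose(rate[2:-2], rate[2])

    def test_nonzero_boundary_flux_rejected(self, small_grid):
        J = np.ones(small_grid.n_nodes + 1)
        with pytest.raises(SolverError):
            divergence(J, small_grid)


class TestStepTumor:
    def test_flat_state_is_fixed_point(self, small_grid):
        params = ModelParams(a3=0)
        n = small_grid.n_nodes
        state = State(
            t=0, grid=small_grid, N=np.full(n, 0.4), P=np.zeros(n),
            E=np.ones(n), A=np.zeros(n), I=np.zeros(n),
        )
        N_new = step_tumor(state, params, SolverConfig())
        assert np.allclose(N_new, 0.4, atol=1e-13)

    def test_reduces_to_reference_backward_euler_heat_step(self, small_grid):
        # with taxis disabled and m_N huge the mobility is (nu/m)*u: one step
        # must match an independently assembled dense backward-Euler solve
        params = ModelParams(a1=0, a2=0, a3=0, m_N=1e8, nu_N=1e6, v_N=50.0)
        cfg = SolverConfig(dt=1e-4)
        g = small_grid
        n = g.n_nodes
        N = np.exp(-0.5 * ((g.x - 0.4) / 0.1) ** 2)
        state = State(t=0, grid=g, N=N, P=np.zeros(n), E=np.ones(n),
                      A=np.zeros(n), I=np.zeros(n))
        got = step_tumor(state, params, cfg)

        D = params.nu_N * 0.5 * (N[1:] + N[:-1]) / params.m_N  # saturation negligible
        L = np.zeros((n, n))
        for f in range(n - 1):
            L[f, f] += D[f]
            L[f, f + 1] -= D[f]
            L[f + 1, f + 1] += D[f]
            L[f + 1, f] -= D[f]
        M = np.eye(n) + cfg.dt / g.dx**2 * L
        ref = np.linalg.solve(M, N)
        assert np.max(np.abs(got - ref)) < 1e-8

    def test_mass_conserved_without_growth(self, small_grid):
        params = ModelParams(a3=0)
        state = plateau_state(small_grid, params)
        cfg = SolverConfig()
        mass0 = state.N.sum() * small_grid.dx
        N = state.N
        for _ in range(50):
            state = State(t=0, grid=small_grid, N=N, P=state.P, E=state.E,
                          A=state.A, I=state.I)
            N = step_tumor(state, params, cfg)
        assert abs(N.sum() * small_grid.dx - mass0) / mass0 < 1e-10


class TestStepMmp:
    def test_empty_tumor_keeps_P_zero(self, small_grid):
        params = ModelParams()
        n = small_grid.n_nodes
        state = State(t=0, grid=small_grid, N=np.zeros(n), P=np.zeros(n),
                      E=np.ones(n), A=np.zeros(n), I=np.zeros(n))
        assert np.all(step_mmp(state, params, SolverConfig()) == 0)

    def test_local_ode_fixed_point_inside_band(self, small_grid):
        # nu_P = 0, frozen E, F, N: P -> a4*E*F/(a5*N) on the band
        params = ModelParams(nu_P=0, a4=0.5, a5=0.4)
        n = small_grid.n_nodes
        E = np.full(n, 0.8)
        F = np.full(n, 2.0)
        N = np.full(n, 0.5)
        chi = np.zeros(n)
        chi[20:30] = 1.0
        P = np.zeros(n)
        cfg = SolverConfig(dt=5e-3)
        for _ in range(20000):
            P = _step_mmp_kernel(P, N, E, F, chi, params, cfg, cfg.dt, small_grid.dx)
        expected = 0.5 * 0.8 * 2.0 / (0.4 * 0.5)
        assert np.allclose(P[20:30], expected, rtol=1e-6)
        assert np.allclose(P[chi == 0], 0.0)

    def test_pure_degradation_decays_exponentially(self, small_grid):
        params = ModelParams(a4=0, a5=0.4, nu_P=0)
        n = small_grid.n_nodes
        N = np.full(n, 0.8)
        state0 = State(t=0, grid=small_grid, N=N, P=np.full(n, 1.0),
                       E=np.ones(n), A=np.zeros(n), I=np.zeros(n))
        cfg = SolverConfig(dt=1e-3)
        P = state0.P
        steps = 500
        for _ in range(steps):
            state = State(t=0, grid=small_grid, N=N, P=P, E=state0.E,
                          A=state0.A, I=state0.I)
            P = step_mmp(state, params, cfg)
        t = steps * cfg.dt
        exact = np.exp(-0.4 * 0.8 * t)
        # implicit Euler error is O(dt) per unit time
        assert np.allclose(P, exact, rtol=0.4 * 0.8 * cfg.dt * 2)


class TestStepOthers:
    def test_zero_rhs_keeps_fields(self, small_grid):
        params = ModelParams(**NO_REACTIONS)
        n = small_grid.n_nodes
        state = State(t=0, grid=small_grid, N=np.zeros(n), P=np.zeros(n),
                      E=np.ones(n), A=np.full(n, 0.2), I=np.full(n, 0.3))
        E, A, I = step_others(state, params, SolverConfig())
        assert np.array_equal(E, state.E)
        assert np.array_equal(A, state.A)
        assert np.array_equal(I, state.I)

    def test_rk4_order_on_linear_decay(self, small_grid):
        # E' = -a6*P*E with constant P: single-step error is O(dt^5)
        params = ModelParams(a6=0.5, E_basal=0.0, a7=0, a8=0, a9=0, v_Int=0)
        n = small_grid.n_nodes
        dt = 0.01
        state = State(t=0, grid=small_grid, N=np.zeros(n), P=np.full(n, 1.0),
                      E=np.ones(n), A=np.zeros(n), I=np.zeros(n))
        E, _, _ = step_others(state, params, SolverConfig(dt=dt))
        k = 0.5 * 1.0
        assert np.allclose(E, np.exp(-k * dt), rtol=1e-11)

    def test_integrin_total_invariant_at_saturation(self, small_grid):
        params = ModelParams(v_Int=0)
        n = small_grid.n_nodes
        A = np.linspace(0.1, 0.6, n)
        I = params.K_I - A
        state = State(t=0, grid=small_grid, N=np.where(small_grid.x < 0.4, 1.0, 0.0),
                      P=np.zeros(n), E=np.ones(n), A=A, I=I)
        _, A2, I2 = step_others(state, params, SolverConfig(dt=1e-3))
        assert np.allclose(A2 + I2, params.K_I, atol=1e-12)

    def test_cfl_violation_raises_before_stepping(self, small_grid):
        params = ModelParams(v_Int=50.0)
        n = small_grid.n_nodes
        state = State(t=0, grid=small_grid, N=np.zeros(n), P=np.zeros(n),
                      E=np.ones(n), A=np.zeros(n), I=np.zeros(n))
        with pytest.raises(SolverError):
            step_others(state, params, SolverConfig(dt=0.1))


class TestSimulate:
    def test_empty_initial_state_is_static(self, small_grid):
        params = ModelParams()
        n = small_grid.n_nodes
        initial = State(t=0, grid=small_grid, N=np.zeros(n), P=np.zeros(n),
                        E=np.full(n, params.E0), A=np.zeros(n), I=np.zeros(n))
        traj = simulate(initial, params, SolverConfig(t_end=0.05, output_times=[0.0, 0.05]))
        final = traj.states[-1]
        assert np.array_equal(final.N, initial.N)
        assert np.array_equal(final.P, initial.P)
        assert np.array_equal(final.E, initial.E)

    def test_homogeneous_tumor_stays_at_capacity(self, small_grid):
        # taxis off: the boundary-truncated activity functional induces mild
        # integrin gradients near the walls that would otherwise nudge N
        params = ModelParams(a1=0, a2=0)
        n = small_grid.n_nodes
        initial = State(t=0, grid=small_grid, N=np.full(n, params.K_N),
                        P=np.full(n, 0.2), E=np.full(n, params.E_basal),
                        A=np.full(n, 0.2), I=np.full(n, 0.8))
        traj = simulate(initial, params, SolverConfig(t_end=0.05, output_times=[0.05]))
        final = traj.states[-1]
        assert np.allclose(final.N, params.K_N, atol=1e-10)
        # full-domain support leaves a zero-width TM band: no production, P decays
        assert np.all(final.P < 0.2)

    def test_bit_identical_reruns(self, small_grid):
        params = ModelParams()
        initial = plateau_state(small_grid, params)
        cfg = SolverConfig(t_end=0.03, output_times=[0.0, 0.03])
        t1 = simulate(initial, params, cfg)
        t2 = simulate(initial, params, cfg)
        for s1, s2 in zip(t1.states, t2.states):
            for name in "NPEAI":
                assert np.array_equal(getattr(s1, name), getattr(s2, name))

    def test_positivity_and_no_flooring_at_defaults(self, grid):
        params = ModelParams()
        initial = plateau_state(grid, params)
        traj = simulate(initial, params, SolverConfig(t_end=0.1, output_times=[0.1]))
        assert traj.diagnostics["floor_events"] == 0
        for name in "NPEAI":
            assert np.all(getattr(traj.states[-1], name) >= 0)


class TestCheckStability:
    def test_zero_transport_speed_unbounded(self, small_grid):
        rep = check_stability(ModelParams(v_Int=0), SolverConfig(), small_grid)
        assert rep.limits["v_Int"] == np.inf
        assert rep.passed

    def test_cfl_ratio_two_fails(self, small_grid):
        cfg = SolverConfig(dt=2 * small_grid.dx / 0.02)
        rep = check_stability(ModelParams(v_Int=0.02), cfg, small_grid)
        assert not rep.passed

    def test_halving_dx_halves_the_limit(self):
        cfg = SolverConfig()
        p = ModelParams(v_Int=0.05)
        lim1 = check_stability(p, cfg, Grid1D.regular(n_nodes=250)).limits["v_Int"]
        lim2 = check_stability(p, cfg, Grid1D.regular(n_nodes=499)).limits["v_Int"]
        assert lim2 == pytest.approx(lim1 / 2, rel=0.01)
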
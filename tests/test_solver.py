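"""1D finite-volume solver: stability limits, well-balancedness, mass
conservation and the local-time-step schedule."""

import numpy as np
import pytest

import hemonet.solver as slv
from hemonet import mechanics as mech

from conftest import make_artery_grid, make_vein_grid


class TestTimeStep:
    def test_dt_capped_at_dt_max(self):
        g = make_vein_grid()
        st = slv.quiescent_state(g)
        cfg = slv.SolverConfig()
        assert slv.max_stable_dt(st, g, cfg) <= cfg.dt_max

    def test_dt_scales_with_dx(self):
        cfg = slv.SolverConfig(dt_max=10.0)   # uncap to test the CFL branch
        g1 = make_vein_grid(L=10.0, n=10)
        g2 = make_vein_grid(L=20.0, n=10)     # doubled dx
        dt1 = slv.max_stable_dt(slv.quiescent_state(g1), g1, cfg)
        dt2 = slv.max_stable_dt(slv.quiescent_state(g2), g2, cfg)
        assert dt2 == pytest.approx(2.0 * dt1, rel=1e-12)

    def test_nonfinite_state_detected(self):
        g = make_vein_grid()
        st = slv.quiescent_state(g)
        st.q[0] = np.inf
        with pytest.raises(ValueError):
            slv.max_wave_speed(st, g)


class TestSteadyStates:
    def test_uniform_quiescent_state_is_fixed_point(self):
        g = make_artery_grid()
        st = slv.quiescent_state(g)
        cfg = slv.SolverConfig()
        dt = slv.max_stable_dt(st, g, cfg)
        for _ in range(50):
            st = slv.advance(st, g, dt, slv.reflective_bc(st, "left"),
                             slv.reflective_bc(st, "right"), cfg)
        assert np.max(np.abs(st.A - g.wall.A0)) == 0.0
        assert np.max(np.abs(st.q)) == 0.0

    def test_deadman_state_with_varying_properties(self):
        """Quiescent vessel with strongly varying A0 and K at uniform
        pressure stays put (well-balancedness, short version)."""
        from hemonet.scenarios import deadman_steady_state_error
        assert deadman_steady_state_error(n_steps=200) < 1e-13


class TestConservation:
    def test_closed_vessel_conserves_volume(self):
        g = make_artery_grid(mu=0.0)
        st = slv.quiescent_state(g)
        st.A = st.A * (1.0 + 0.05 * np.exp(
            -((np.arange(g.n_cells) - 4.0) / 1.5) ** 2))
        V0 = slv.total_volume(st, g)
        cfg = slv.SolverConfig()
        for _ in range(1000):
            dt = slv.max_stable_dt(st, g, cfg)
            st = slv.advance(st, g, dt, slv.reflective_bc(st, "left"),
                             slv.reflective_bc(st, "right"), cfg)
        assert abs(slv.total_volume(st, g) - V0) / V0 < 1e-12

    def test_boundary_flux_is_star_flow(self):
        """With a prescribed boundary star state, the volume change equals
        the star flow exactly (1D/0D bookkeeping closes)."""
        g = make_vein_grid()
        st = slv.quiescent_state(g)
        cfg = slv.SolverConfig()
        dt = 1e-4
        q_in = 2.5
        V0 = slv.total_volume(st, g)
        for _ in range(100):
            st = slv.advance(st, g, dt, (float(st.A[0]), q_in),
                             slv.reflective_bc(st, "right"), cfg)
        assert slv.total_volume(st, g) - V0 == pytest.approx(
            q_in * dt * 100, rel=1e-12)


class TestRelaxationVariable:
    def test_zero_viscoelasticity_reproduces_elastic_solution(self):
        """With Km = 0 the auxiliary field is inert: (A, q) match a run with
        a very different relaxation stiffness bit-for-bit."""
        runs = []
        for tau_scale in (1.0, 0.01):
            g = make_artery_grid(Km_scale=0.0, mu=0.0)
            st = slv.quiescent_state(g)
            st.A = st.A * (1.0 + 0.03 * np.exp(
                -((np.arange(g.n_cells) - 5.0) / 1.5) ** 2))
            cfg = slv.SolverConfig(tau_scale=tau_scale)
            for _ in range(200):
                dt = 2e-4
                st = slv.advance(st, g, dt, slv.reflective_bc(st, "left"),
                                 slv.reflective_bc(st, "right"), cfg)
            runs.append(st)
        assert np.array_equal(runs[0].A, runs[1].A)
        assert np.array_equal(runs[0].q, runs[1].q)

    def test_viscoelasticity_damps_pulse(self):
        """A pulse in a viscoelastic vessel loses more energy than in the
        elastic one (the relaxation field feeds the rate term)."""
        amps = []
        for km_scale in (0.0, 1.0):
            g = make_vein_grid()
            if km_scale == 0.0:
                g.wall.Km = g.wall.Km * 0.0
            st = slv.quiescent_state(g)
            st.A = st.A * (1.0 + 0.08 * np.exp(
                -((np.arange(g.n_cells) - 5.0) / 1.5) ** 2))
            cfg = slv.SolverConfig()
            for _ in range(300):
                dt = slv.max_stable_dt(st, g, cfg)
                st = slv.advance(st, g, dt, slv.reflective_bc(st, "left"),
                                 slv.reflective_bc(st, "right"), cfg)
            amps.append(float(np.max(np.abs(st.A / g.wall.A0 - 1.0))))
        assert amps[1] < amps[0]


class TestSchedule:
    def test_integer_ratio_binning(self):
        macro, sched = slv.local_time_step_schedule(
            {1: 1.0e-3, 2: 0.4e-3}, pairs=[], dt_max=1.0e-3)
        assert macro == 1.0e-3
        assert sched[1] == (1, 1.0e-3)
        assert sched[2][0] == 3
        assert sched[2][1] == pytest.approx(macro / 3)

    def test_uniform_dts_pass_through(self):
        macro, sched = slv.local_time_step_schedule(
            {1: 0.7e-3, 2: 0.7e-3}, pairs=[])
        assert all(s == (1, 0.7e-3) for s in sched.values())

    def test_valve_pair_forced_equal(self):
        macro, sched = slv.local_time_step_schedule(
            {1: 1.0e-3, 2: 0.5e-3}, pairs=[(1, 2)])
        assert sched[1] == sched[2]
        assert sched[1][1] == pytest.approx(0.5e-3)


class TestGridConstruction:
    def test_short_vessel_single_cell(self):
        assert slv.n_cells_for(0.4) == 1
        assert slv.n_cells_for(7.6) == 8

    def test_cell_helpers_match_wall_field(self):
        g = make_vein_grid()
        A = 0.9 * g.wall.A0[3]
        assert float(slv.cell_pressure(g, 3, A)[0]) == pytest.approx(
            float(g.wall.p_elastic(np.full(g.n_cells, A))[3]), rel=1e-14)
        c = float(slv.cell_celerity(g, 3, A)[0])
        assert c == pytest.approx(
            float(g.celerity(np.full(g.n_cells, A))[3]), rel=1e-14)

    def test_area_floor_guard_logs_not_raises(self):
        g = make_vein_grid(n=4)
        st = slv.quiescent_state(g)
        cfg = slv.SolverConfig()
        # drain hard from the right boundary; area must floor, not go negative
        for _ in range(30):
            dt = slv.max_stable_dt(st, g, cfg)
            st = slv.advance(st, g, dt, slv.reflective_bc(st, "left"),
                             (float(st.A[-1]), 50.0), cfg)
        assert np.all(st.A > 0)
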
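"""Junction and 1D-0D coupling solves against closed forms and an
independent dense root-finder."""

import numpy as np
import pytest
from scipy.optimize import root

import hemonet.coupling as cpl
import hemonet.solver as slv

from conftest import make_artery_grid, make_vein_grid


def artery_end(g=+1, q=0.0, A_scale=1.0, **kw):
    grid = make_artery_grid(**kw)
    st = slv.quiescent_state(grid)
    st.q[:] = q
    st.A[:] *= A_scale
    return cpl.BoundaryEnd(grid, st, g)


class TestJunctions:
    def test_transparent_junction(self):
        """Two identical collinear vessels with identical states couple to
        their interior states."""
        e1 = artery_end(+1, q=5.0, A_scale=1.02)
        e2 = artery_end(-1, q=5.0, A_scale=1.02)
        res = cpl.solve_junction([e1, e2])
        assert res.A[0] == pytest.approx(e1.A_in, rel=1e-12)
        assert res.q[0] == pytest.approx(5.0, rel=1e-12)
        assert res.q[1] == pytest.approx(5.0, rel=1e-12)

    def test_symmetric_bifurcation_splits_flow_evenly(self):
        mother = artery_end(+1, q=10.0, R0=0.6)
        d1 = artery_end(-1, R0=0.45)
        d2 = artery_end(-1, R0=0.45)
        res = cpl.solve_junction([mother, d1, d2])
        assert res.q[1] == pytest.approx(res.q[2], rel=1e-12)
        assert res.q[0] == pytest.approx(res.q[1] + res.q[2], abs=1e-10)

    def test_venous_confluence_matches_dense_root_finder(self):
        g1, g2, g3 = (make_vein_grid(R0=r) for r in (0.3, 0.4, 0.55))
        states = []
        for g, q, s in ((g1, 2.0, 1.05), (g2, 3.0, 0.97), (g3, 4.0, 1.0)):
            st = slv.quiescent_state(g)
            st.q[:] = q
            st.A[:] *= s
            states.append(st)
        ends = [cpl.BoundaryEnd(g1, states[0], +1),
                cpl.BoundaryEnd(g2, states[1], +1),
                cpl.BoundaryEnd(g3, states[2], -1)]
        res = cpl.solve_junction(ends)
        rho = g1.rho

        def resid(A):
            u = [e.u_star(A[k]) for k, e in enumerate(ends)]
            pt = [ends[k].pressure(A[k]) + 0.5 * rho * u[k] ** 2
                  for k in range(3)]
            return [sum(e.g * A[k] * u[k] for k, e in enumerate(ends)),
                    pt[0] - pt[1], pt[0] - pt[2]]

        sol = root(resid, [e.A_in for e in ends], tol=1e-13)
        assert sol.success
        assert np.max(np.abs(np.array(res.A) - sol.x) / sol.x) < 1e-9
        assert abs(res.mass_residual) < 1e-12 * max(abs(x) for x in res.q)
        assert res.pressure_spread < 1e-9

    def test_conservation_over_random_states(self, rng):
        """Mass is exact and total-pressure spread tiny for arbitrary
        admissible member states."""
        for _ in range(25):
            ends = []
            for k in range(3):
                g = make_vein_grid(R0=float(rng.uniform(0.25, 0.6)))
                st = slv.quiescent_state(g)
                st.q[:] = float(rng.uniform(-5, 5))
                st.A[:] *= float(rng.uniform(0.9, 1.1))
                ends.append(cpl.BoundaryEnd(g, st, +1 if k < 2 else -1))
            res = cpl.solve_junction(ends)
            assert abs(res.mass_residual) < 1e-12 * max(abs(x) for x in res.q)
            assert res.pressure_spread < 1e-9


class TestTerminalCouplings:
    def test_matched_pressure_gives_zero_flow(self):
        end = artery_end(+1, q=0.0)
        p_match = end.total_pressure(end.A_in)
        A, q = cpl.couple_terminal_artery(end, p_match, R_a=500.0)
        assert abs(q) < 1e-10

    def test_steady_flow_matches_direct_algebra(self):
        end = artery_end(+1, q=3.0, R0=0.4)
        p_bed, R_a = 0.9e5, 2000.0
        A, q = cpl.couple_terminal_artery(end, p_bed, R_a)
        u = q / A
        p_tot = end.pressure(A) + 0.5 * end.grid.rho * u * u
        assert q == pytest.approx((p_tot - p_bed) / R_a, rel=1e-9)

    def test_infinite_resistance_reflects_fully(self):
        end = artery_end(+1, q=3.0)
        _, q = cpl.couple_terminal_artery(end, 0.9e5, R_a=1e12)
        assert abs(q) < 1e-6

    def test_vein_mirror_cases(self):
        grid = make_vein_grid()
        st = slv.quiescent_state(grid)
        end = cpl.BoundaryEnd(grid, st, -1)
        p_match = end.total_pressure(end.A_in)
        _, q = cpl.couple_terminal_vein(end, p_match, R_v=300.0)
        assert abs(q) < 1e-10
        A, q = cpl.couple_terminal_vein(end, p_match + 4000.0, R_v=300.0)
        u = q / A
        lhs = p_match + 4000.0 - 300.0 * q
        assert lhs == pytest.approx(end.pressure(A) + 0.5 * grid.rho * u * u,
                                    rel=1e-9)
        _, q_inf = cpl.couple_terminal_vein(end, p_match + 4000.0, R_v=1e12)
        assert abs(q_inf) < 1e-6


class TestAtrialAndPrescribedFlow:
    def test_outlet_pressure_pinned(self):
        grid = make_vein_grid()
        st = slv.quiescent_state(grid)
        end = cpl.BoundaryEnd(grid, st, +1)
        p_RA = 8000.0
        A, q = cpl.couple_pressure_outlet(end, p_RA)
        u = q / A
        assert end.pressure(A) + 0.5 * grid.rho * u * u == pytest.approx(
            p_RA, rel=1e-9)

    def test_equilibrium_at_atrial_pressure(self):
        grid = make_vein_grid()
        st = slv.quiescent_state(grid)
        end = cpl.BoundaryEnd(grid, st, +1)
        p_eq = end.total_pressure(end.A_in)
        _, q = cpl.couple_pressure_outlet(end, p_eq)
        assert abs(q) < 1e-10

    def test_raising_atrial_pressure_reduces_outflow(self):
        grid = make_vein_grid()
        st = slv.quiescent_state(grid)
        st.q[:] = 4.0
        end = cpl.BoundaryEnd(grid, st, +1)
        _, q_lo = cpl.couple_pressure_outlet(end, 7000.0)
        _, q_hi = cpl.couple_pressure_outlet(end, 9000.0)
        assert q_hi < q_lo

    def test_prescribed_flow_keeps_invariant(self):
        end = artery_end(-1, q=2.0)
        q_set = 15.0
        A, q = cpl.couple_prescribed_flow(end, q_set)
        assert q == q_set
        assert q_set / A == pytest.approx(end.u_star(A), rel=1e-9)
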
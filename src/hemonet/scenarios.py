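"""Validation scenarios: self-contained numerical experiments exercising
specific model properties. Used by the test suite and the reproduction
script; each returns plain numbers.

* dead-man steady state: a quiescent vessel with strongly varying reference
  area and stiffness must hold uniform pressure and zero flow exactly
  (well-balancedness of the scheme);
* grid-refinement study: empirical L1 convergence order on a smooth pulse
  in a uniform elastic vessel;
* Starling waterfall rig: an open vein fed by a pressure reservoir and
  drained through a Starling resistor, measuring how the steady outflow
  responds to changes in downstream pressure above/below the external
  (intracranial) pressure.
"""

from __future__ import annotations

import math

import numpy as np

from . import coupling as cpl
from . import lumped
from . import mechanics as mech
from . import solver as slv
from .mechanics import MMHG


def deadman_steady_state_error(n_cells: int = 30, n_steps: int = 1000,
                               p_tm: float = 9000.0, seed: int = 0) -> float:
    """Max relative area drift after n_steps on a quiescent venous vessel
    with strongly varying A0(x) and K(x) at uniform transmural pressure."""
    rng = np.random.default_rng(seed)
    fluid = mech.FluidParams()
    vr = mech.VenousParamRules()
    radii = 0.3 + 0.15 * np.sin(np.linspace(0, 3 * np.pi, n_cells)) \
        + 0.05 * rng.standard_normal(n_cells)
    radii = np.clip(radii, 0.1, 0.6)
    walls = [mech.make_venous_wall(float(r), 0.3, vr, fluid.rho) for r in radii]
    # impose additional stiffness variation on top of the radius profile
    from dataclasses import replace
    walls = [replace(w, K=w.K * (1.0 + 0.5 * math.sin(float(i))))
             for i, w in enumerate(walls)]
    grid = slv.VesselGrid(slv.VenousWallField(walls), length=float(n_cells),
                          rho=fluid.rho, mu=fluid.mu)
    A = np.array([slv.area_at_pressure(grid, p_tm, i) for i in range(n_cells)])
    st = slv.VesselState(A=A.copy(), q=np.zeros(n_cells), w=np.zeros(n_cells))
    cfg = slv.SolverConfig()
    dt = slv.max_stable_dt(st, grid, cfg)
    for _ in range(n_steps):
        st = slv.advance(st, grid, dt, slv.reflective_bc(st, "left"),
                         slv.reflective_bc(st, "right"), cfg)
    return float(np.max(np.abs(st.A - A) / A))


def _elastic_pulse_run(n: int, T: float, cfg: slv.SolverConfig,
                       length: float = 20.0, R0: float = 0.5):
    fluid = mech.FluidParams()
    w = mech.with_km_scaled(mech.make_arterial_wall(R0), 0.0)
    grid = slv.VesselGrid(slv.ArterialWallField([w] * n), length=length,
                          rho=fluid.rho, mu=0.0)
    x = (np.arange(n) + 0.5) * grid.dx
    A = w.A0 * (1.0 + 0.05 * np.exp(-((x - 8.0) / 2.0) ** 2))
    st = slv.VesselState(A=A, q=np.zeros(n), w=np.zeros(n))
    t = 0.0
    while t < T - 1e-15:
        dt = min(slv.max_stable_dt(st, grid, cfg), T - t)
        st = slv.advance(st, grid, dt, slv.transmissive_bc(st, "left"),
                         slv.transmissive_bc(st, "right"), cfg)
        t += dt
    return grid, st


def convergence_orders(grids=(100, 200, 400), ref: int = 1600,
                       T: float = 0.008,
                       cfg: slv.SolverConfig | None = None) -> list:
    """Empirical L1 orders of accuracy for a smooth pulse on successive
    refinements (reference = cell-averaged fine-grid solution)."""
    cfg = cfg or slv.SolverConfig(CFL=0.45)
    _, st_ref = _elastic_pulse_run(ref, T, cfg)
    errs = []
    for n in grids:
        g, st = _elastic_pulse_run(n, T, cfg)
        ratio = ref // n
        A_ref = st_ref.A.reshape(n, ratio).mean(axis=1)
        errs.append(float(np.sum(np.abs(st.A - A_ref)) * g.dx))
    return [math.log2(errs[i] / errs[i + 1]) for i in range(len(errs) - 1)]


def waterfall_outflow(p_in_mmhg: float, p_down_mmhg: float, p_icp_mmhg: float,
                      T: float = 2.5, R0: float = 0.35,
                      length: float = 5.0) -> float:
    """Steady outflow of an intracranial vein through a Starling resistor.

    The vein inlet is held at reservoir total pressure ``p_in``; the
    resistor's downstream pressure is prescribed at ``p_down``; the vein's
    external pressure and the resistor's collapse reference are the
    intracranial pressure ``p_icp``. Returns the mean flow over the final
    fifth of the run (cm^3/s).
    """
    fluid = mech.FluidParams()
    vr = mech.VenousParamRules()
    n = slv.n_cells_for(length)
    walls = [mech.make_venous_wall(R0, R0, vr, fluid.rho)] * n
    grid = slv.VesselGrid(slv.VenousWallField(walls), length=length,
                          rho=fluid.rho, mu=fluid.mu,
                          p_ext=p_icp_mmhg * MMHG)
    st = slv.quiescent_state(grid)
    A0_end = float(grid.wall.A0[-1])
    sr = lumped.StarlingParams(l_eff=2.0 * math.sqrt(A0_end / math.pi),
                               A_eff=A0_end)
    state = lumped.ValveState(zeta=1.0, q=0.0)
    cfg = slv.SolverConfig()
    p_in = p_in_mmhg * MMHG
    p_down = p_down_mmhg * MMHG
    p_icp = p_icp_mmhg * MMHG
    t, qs, ts = 0.0, [], []
    while t < T:
        dt = slv.max_stable_dt(st, grid, cfg)
        last = grid.n_cells - 1
        p_up = float(slv.cell_pressure(grid, last, st.A[last], st.w[last])[0])
        Z = grid.rho * float(slv.cell_celerity(grid, last, st.A[last])[0]) \
            / float(st.A[last])
        state = lumped.starling_step(state, p_up, p_down, p_icp, dt, sr,
                                     fluid.rho, Z_wave=Z)
        bc_in = cpl.couple_pressure_outlet(
            cpl.BoundaryEnd(grid, st, -1), p_in)
        bc_out = cpl.couple_prescribed_flow(
            cpl.BoundaryEnd(grid, st, +1), state.q)
        st = slv.advance(st, grid, dt, bc_in, bc_out, cfg)
        t += dt
        ts.append(t)
        qs.append(state.q)
    qs = np.array(qs)
    ts = np.array(ts)
    return float(qs[ts > 0.8 * T].mean())


def waterfall_sensitivities(p_icp_high: float = 11.0, p_icp_low: float = 2.0,
                            p_in: float = 14.0, p_down: float = 8.0) -> dict:
    """Relative change (%) of cerebral venous outflow when the downstream
    pressure is lowered by 10%, with the sinus pressure below vs above the
    intracranial pressure."""
    out = {}
    q1 = waterfall_outflow(p_in, p_down, p_icp_high)
    q2 = waterfall_outflow(p_in, 0.9 * p_down, p_icp_high)
    out["collapsed_change_pct"] = 100.0 * abs(q2 - q1) / abs(q1)
    q3 = waterfall_outflow(p_in, p_down, p_icp_low)
    q4 = waterfall_outflow(p_in, 0.9 * p_down, p_icp_low)
    out["open_change_pct"] = 100.0 * abs(q4 - q3) / abs(q3)
    out["q_collapsed"] = q1
    out["q_open"] = q3
    return out
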
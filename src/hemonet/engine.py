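"""Closed-loop simulation engine: assembles all model components, advances
them on a synchronized local-time-step schedule, enforces the total
stretched-volume set point, and records waveforms.

Stepping order within one macro step (the common synchronization interval):

1. chamber pressures (pairwise contralateral solves) and pericardium;
2. pulmonary chain and cardiac-valve ODEs (explicit Euler, semi-implicit
   quadratic drag); the aortic valve sees the 1D aortic-root boundary
   pressure from the previous step;
3. venous-valve / Starling-resistor ODEs using current 1D boundary
   pressures (Starling external pressure = intracranial pressure);
4. all 1D boundary couplings (junctions, terminals, caval inlets, aortic
   root, element-adjacent ends) solved for star states;
5. every vessel advanced through its substeps with frozen star states, so
   the mass exchanged with 0D elements is exactly q* dt;
6. peripheral/coronary bed and chamber-volume updates (explicit Euler);
7. intracranial pressure stepped on its own (dt_max) clock from the
   accumulated cerebral blood-volume rate.

The total *stretched* (stressed) volume — the blood volume in excess of the
zero-transmural-pressure volume, which sets the operating pressure of the
closed loop — is measured at assembly and driven to the configured set
point by a constant-rate source at the right atrium during the first
three seconds of the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import beds as bedmod
from . import coupling as cpl
from . import lumped
from . import mechanics as mech
from . import solver as slv
from .network import ElementKind, NetworkTopology

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    period: float = 0.9                  # s, cardiac period
    n_cycles: int = 10
    periodicity_tol: float = 1e-3        # relative L2 between consecutive cycles
    solver: slv.SolverConfig = field(default_factory=slv.SolverConfig)
    dx_c: float = slv.DX_CHARACTERISTIC  # cm
    fluid: mech.FluidParams = field(default_factory=mech.FluidParams)
    arterial_rules: mech.ArterialParamRules = field(default_factory=mech.ArterialParamRules)
    venous_rules: mech.VenousParamRules = field(default_factory=mech.VenousParamRules)
    V_set: float | None = 2273.643       # cm^3 stretched-volume set point;
    #                                      None keeps the assembled volume
    enforcement_window: float = 3.0      # s
    C_v_data: float = bedmod.C_V_DATA_DEFAULT
    k_ICP: float = bedmod.K_ICP_DEFAULT
    p_ICP_init: float = bedmod.P_ICP_INITIAL
    output_every: int = 1                # record every k-th macro step
    schedule_margin: float = 1.5         # sizing factor on reference celerity
    audit: bool = True                   # track junction residuals / volumes


@dataclass
class Monitor:
    vessel: int
    pos: float = 0.5                     # fractional axial position
    name: str = ""


@dataclass
class WaveformRecord:
    """Uniformly sampled time series at monitored 1D sites and 0D elements."""

    t: np.ndarray = None
    monitors: dict = field(default_factory=dict)   # name -> {"p","q","A"}
    lumped: dict = field(default_factory=dict)     # name -> array
    cycle_starts: list = field(default_factory=list)
    audit: dict = field(default_factory=dict)
    period: float = 0.9

    def cycle_indices(self, k: int):
        """Sample index range of cycle k (0-based)."""
        i0 = self.cycle_starts[k]
        i1 = self.cycle_starts[k + 1] if k + 1 < len(self.cycle_starts) else len(self.t)
        return i0, i1

    def n_complete_cycles(self):
        return max(0, len(self.cycle_starts) - 1)

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=self.t)
            f.attrs["period"] = self.period
            f.create_dataset("cycle_starts", data=np.array(self.cycle_starts, dtype=int))
            g = f.create_group("monitors")
            for name, d in self.monitors.items():
                gg = g.create_group(str(name))
                for k, v in d.items():
                    gg.create_dataset(k, data=v)
            g = f.create_group("lumped")
            for name, v in self.lumped.items():
                g.create_dataset(str(name), data=v)
            g = f.create_group("audit")
            for name, v in self.audit.items():
                g.create_dataset(str(name), data=np.asarray(v))

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        rec = cls()
        with h5py.File(path, "r") as f:
            rec.t = f["t"][:]
            rec.period = float(f.attrs["period"])
            rec.cycle_starts = list(f["cycle_starts"][:])
            for name, gg in f["monitors"].items():
                rec.monitors[name] = {k: gg[k][:] for k in gg}
            for name, v in f["lumped"].items():
                rec.lumped[name] = v[:]
            for name, v in f["audit"].items():
                rec.audit[name] = v[:]
        return rec


def periodicity_check(record: WaveformRecord, k: int | None = None) -> float:
    """Max over monitors of the relative L2 distance between the pressure
    traces of cycle k and cycle k-1 (defaults to the last complete pair)."""
    nc = record.n_complete_cycles()
    if nc < 2:
        raise ValueError("need at least two complete cycles")
    k = nc - 1 if k is None else k
    i0, i1 = record.cycle_indices(k)
    j0, j1 = record.cycle_indices(k - 1)
    m = min(i1 - i0, j1 - j0)
    worst = 0.0
    for d in record.monitors.values():
        a, b = d["p"][i0:i0 + m], d["p"][j0:j0 + m]
        denom = float(np.linalg.norm(b))
        worst = max(worst, float(np.linalg.norm(a - b)) / max(denom, 1e-30))
    return worst


# ---------------------------------------------------------------------------
# Simulation assembly
# ---------------------------------------------------------------------------

class Simulation:
    """Assembled closed-loop model ready to run."""

    def __init__(self, net: NetworkTopology, config: SimulationConfig,
                 monitors: list[Monitor] | None = None,
                 heart_params: lumped.HeartParams | None = None,
                 cardiac_valves: dict | None = None,
                 pulmonary_params: lumped.PulmonaryParams | None = None):
        self.net = net
        self.cfg = config
        self.heart_params = heart_params or lumped.default_heart_params(config.period)
        self.valve_params = cardiac_valves or lumped.default_cardiac_valves()
        self.pulm_params = pulmonary_params or lumped.default_pulmonary_params()
        self._build_grids()
        self._build_beds()
        self._build_elements()
        self._build_lumped_states()
        self._classify_ends()
        self._build_schedule()
        self._build_monitors(monitors)
        self._prepare_stretched_volume()
        self.t = 0.0
        self.injection_rate = 0.0
        self.injection_until = 0.0
        self._icp_accum_dV = 0.0
        self._icp_accum_t = 0.0
        self.max_junction_mass_residual = 0.0
        self.max_junction_pressure_spread = 0.0

    # -- construction -------------------------------------------------------

    def _build_grids(self):
        cfg = self.cfg
        self.grids, self.states = {}, {}
        for vid, v in self.net.vessels.items():
            n = slv.n_cells_for(v.length, cfg.dx_c)
            g = slv.build_grid(v, cfg.fluid, cfg.arterial_rules,
                               cfg.venous_rules, n_cells=n)
            self.grids[vid] = g
            self.states[vid] = slv.quiescent_state(g)
        self.intracranial = {vid for vid, v in self.net.vessels.items() if v.intracranial}

    def _venous_1d_compliance(self):
        tot = 0.0
        for vid, v in self.net.vessels.items():
            if v.is_arterial:
                continue
            g = self.grids[vid]
            tot += float(np.sum(1.0 / g.wall.dpdA(g.wall.A0)) * g.dx)
        return tot

    def _build_beds(self):
        cfg = self.cfg
        coronary_territories = {self.net.terminals[a].territory
                                for a in self.net.coronary_walls}
        ic_veins = {v for v in self.net.terminal_veins() if v in self.intracranial}
        self.beds = bedmod.derive_peripheral_parameters(
            self.net, cfg.venous_rules, cfg.fluid.rho,
            C_v_data=cfg.C_v_data, C_v_1D=self._venous_1d_compliance(),
            coronary_territories=coronary_territories,
            intracranial_veins=ic_veins)
        # coronary intramyocardial beds on top of the coronary territories
        R_av_all = {}
        for bed in self.beds.values():
            R_av_all.update(bed.R_av)
        self.coronary = {}
        if self.net.coronary_walls:
            self.coronary = bedmod.derive_coronary_parameters(self.net, R_av_all)
            for t, bed in self.beds.items():
                conns = [(a, v) for (a, v) in bed.R_av if (a, v) in self.coronary]
                if not conns:
                    continue
                bed.coronary = {k: self.coronary[k] for k in conns}
                for a in bed.arteries:
                    mine = [self.coronary[k] for k in conns if k[0] == a]
                    if mine:
                        bed.proximal[a].C = bedmod.coronary_arteriolar_compliance(mine)
                for v in bed.veins:
                    mine = [self.coronary[k] for k in conns if k[1] == v]
                    if mine:
                        bed.distal[v].C = bedmod.coronary_venular_compliance(mine)
        # cerebral compartments feel the intracranial pressure as external
        self._icp_compartments = []
        for bed in self.beds.values():
            for a in bed.arteries:
                if a in self.intracranial:
                    bed.proximal[a].p_ext = self.cfg.p_ICP_init
                    self._icp_compartments.append(bed.proximal[a])
            for v in bed.veins:
                if v in self.intracranial:
                    bed.distal[v].p_ext = self.cfg.p_ICP_init
                    self._icp_compartments.append(bed.distal[v])
        # initialize compartments at the class reference transmural pressures
        # (luminal = p_tm + p_ext, so cerebral compartments start consistent
        # with the intracranial pressure instead of half-empty)
        p_art0 = self.cfg.arterial_rules.p0
        p_ven0 = self.cfg.venous_rules.p0
        for bed in self.beds.values():
            for c in bed.proximal.values():
                c.V = c.C * 0.8 * p_art0
            for c in bed.distal.values():
                c.V = c.C * p_ven0
        self._bed_of_artery = {}
        self._bed_of_vein = {}
        for t, bed in self.beds.items():
            for a in bed.arteries:
                self._bed_of_artery[a] = bed
            for v in bed.veins:
                self._bed_of_vein[v] = bed

    def _build_elements(self):
        """Venous valves and Starling resistors between 1D segments."""
        self.elements = []
        for spec in self.net.elements:
            gu, gd = self.grids[spec.vessel_up], self.grids[spec.vessel_down]
            A_eff = 0.5 * (float(gu.wall.A0[-1]) + float(gd.wall.A0[0]))
            l_eff = 0.5 * (2.0 * np.sqrt(float(gu.wall.A0[-1]) / np.pi)
                           + 2.0 * np.sqrt(float(gd.wall.A0[0]) / np.pi))
            if spec.kind is ElementKind.VENOUS_VALVE:
                params = lumped.ValveParams(
                    l_eff=l_eff, A_eff_max=A_eff,
                    K_vo=lumped.VENOUS_VALVE_KVO, K_vc=lumped.VENOUS_VALVE_KVC)
            else:
                params = lumped.StarlingParams(
                    l_eff=l_eff, A_eff=A_eff,
                    K_so=lumped.STARLING_KSO, K_sc=lumped.STARLING_KSC)
            self.elements.append({
                "spec": spec, "params": params,
                "state": lumped.ValveState(zeta=1.0, q=0.0),
            })

    def _build_lumped_states(self):
        self.heart = lumped.HeartState(
            volumes={"RA": 60.0, "RV": 120.0, "LA": 60.0, "LV": 120.0})
        self.valves = {name: lumped.ValveState() for name in self.valve_params}
        self.pulm = lumped.PulmonaryState(V={"pua": 60.0, "puc": 98.0, "puv": 108.0},
                                          q={"pua": 0.0, "puc": 0.0, "puv": 0.0})
        self.icp = bedmod.ICPState(p=self.cfg.p_ICP_init, k=self.cfg.k_ICP)
        self.p_ao = self.cfg.arterial_rules.p0
        # intracranial 1D vessels feel the ICP as external pressure; dural
        # sinuses are deliberately untagged (extracranial-rigid partition)
        for vid in self.intracranial:
            self.grids[vid].p_ext = self.icp.p
        self._V_cbv_prev = self._compute_V_cbv()

    def _classify_ends(self):
        """Assign exactly one coupling role to every vessel end."""
        roles = {}
        for j in self.net.junctions:
            for vid, g in j.members:
                roles[(vid, g)] = ("junction", j)
        for i, el in enumerate(self.elements):
            spec = el["spec"]
            roles[(spec.vessel_up, +1)] = ("element_up", i)
            roles[(spec.vessel_down, -1)] = ("element_down", i)
        for a in self.net.terminals:
            roles.setdefault((a, +1), ("terminal_artery", a))
        for v in self.net.terminal_veins():
            roles.setdefault((v, -1), ("terminal_vein", v))
        root = self.net.heart.aortic_root_vessel
        roles[(root, -1)] = ("aortic_root", root)
        for v in self.net.heart.atrial_inlet_vessels:
            roles[(v, +1)] = ("atrial_inlet", v)
        if self.net.heart.coronary_sinus_vessel is not None:
            roles[(self.net.heart.coronary_sinus_vessel, +1)] = \
                ("atrial_inlet", self.net.heart.coronary_sinus_vessel)
        for vid in self.net.vessels:
            for g in (-1, +1):
                if (vid, g) not in roles:
                    raise ValueError(f"vessel {vid} end g={g}: no coupling role")
        self.roles = roles
        self.junction_list = self.net.junctions

    def _build_schedule(self):
        cfg = self.cfg
        stable = {}
        for vid, g in self.grids.items():
            st = self.states[vid]
            lam = slv.max_wave_speed(st, g) * cfg.schedule_margin
            stable[vid] = min(cfg.solver.dt_max, cfg.solver.CFL * g.dx / lam)
        pairs = [(el["spec"].vessel_up, el["spec"].vessel_down)
                 for el in self.elements]
        self.macro_dt, self.schedule = slv.local_time_step_schedule(
            stable, pairs, cfg.solver.dt_max)

    def _build_monitors(self, monitors):
        if monitors is None:
            monitors = [Monitor(vessel=vid, pos=0.5,
                                name=f"v{vid}:{self.net.vessels[vid].name}")
                        for vid in sorted(self.net.vessels)]
        self.monitor_defs = monitors
        self._mon_cells = {}
        for m in monitors:
            g = self.grids[m.vessel]
            cell = min(g.n_cells - 1, int(m.pos * g.n_cells))
            self._mon_cells[m.name or str(m.vessel)] = (m.vessel, cell)
        self._rec_t = []
        self._rec_mon = {k: {"p": [], "q": [], "A": []} for k in self._mon_cells}
        self._rec_lumped = {}
        self._rec_audit = {"volume": [], "junction_mass": [], "junction_spread": []}
        self._cycle_starts = [0]

    def _prepare_stretched_volume(self):
        """Per-cell zero-transmural-pressure areas and the initial audit."""
        self.A_zero = {}
        for vid, g in self.grids.items():
            self.A_zero[vid] = np.array([
                slv.area_at_pressure(g, 0.0, i) for i in range(g.n_cells)])
        self.V_stretched0 = self.stretched_volume()

    # -- audits -------------------------------------------------------------

    def stretched_volume(self) -> float:
        """Total stressed blood volume over 1D cells, linear compartments,
        chambers, pulmonary and coronary compartments."""
        tot = 0.0
        for vid, g in self.grids.items():
            tot += float(np.sum(self.states[vid].A - self.A_zero[vid]) * g.dx)
        for bed in self.beds.values():
            tot += sum(c.V for c in bed.proximal.values())
            tot += sum(c.V for c in bed.distal.values())
            if bed.coronary:
                for cb in bed.coronary.values():
                    tot += sum(cb.V[k] - cb.V0[k] for k in cb.V)
        for c in lumped.CHAMBERS:
            tot += self.heart.volumes[c] - self.heart_params.chambers[c].V0
        tot += sum(self.pulm.V.values())
        return tot

    def total_blood_volume(self) -> float:
        tot = 0.0
        for vid, g in self.grids.items():
            tot += slv.total_volume(self.states[vid], g)
        for bed in self.beds.values():
            tot += sum(c.V for c in bed.proximal.values())
            tot += sum(c.V for c in bed.distal.values())
            if bed.coronary:
                for cb in bed.coronary.values():
                    tot += sum(cb.V.values())
        tot += sum(self.heart.volumes.values())
        tot += sum(self.pulm.V.values())
        return tot

    def enforce_stretched_volume(self):
        """Schedule the constant-rate volume source over the first window."""
        if self.cfg.V_set is None:
            return
        comps = [c for bed in self.beds.values() for c in bed.distal.values()]
        self._injection_compartment = max(comps, key=lambda c: c.C)
        dv = self.cfg.V_set - self.V_stretched0
        self.injection_rate = dv / self.cfg.enforcement_window
        self.injection_until = self.cfg.enforcement_window
        log.info("stretched volume %.3f cm^3, set point %.3f cm^3: "
                 "source %.3f cm^3/s for %.1f s", self.V_stretched0,
                 self.cfg.V_set, self.injection_rate, self.cfg.enforcement_window)

    # -- boundary pressure helpers ------------------------------------------

    def _end_pressure(self, vid: int, g: int) -> float:
        grid, st = self.grids[vid], self.states[vid]
        cell = grid.n_cells - 1 if g == +1 else 0
        return float(slv.cell_pressure(grid, cell, st.A[cell], st.w[cell])[0])

    def _end_impedance(self, vid: int, g: int) -> float:
        """Characteristic impedance rho c / A at a vessel end."""
        grid, st = self.grids[vid], self.states[vid]
        cell = grid.n_cells - 1 if g == +1 else 0
        c = float(slv.cell_celerity(grid, cell, st.A[cell])[0])
        return grid.rho * c / float(st.A[cell])

    # -- one macro step -----------------------------------------------------

    def step(self):
        cfg = self.cfg
        dt = self.macro_dt
        t_cycle = self.t % self.heart_params.period

        # 1. chamber + pericardial pressures
        q_out = {"RA": self.valves["tv"].q, "RV": self.valves["pv"].q,
                 "LA": self.valves["mv"].q, "LV": self.valves["av"].q}
        q_V = {"RA": self.valves["tv"].q, "RV": 0.0,
               "LA": self.valves["mv"].q, "LV": 0.0}
        pres, p_pc = lumped.chamber_pressures(
            self.heart_params, t_cycle, self.heart.volumes, q_out, q_V)
        self.heart.pressures = pres
        self.heart.p_pc = p_pc

        # 2. pulmonary + cardiac valves
        self.pulm, p_pulm = lumped.pulmonary_step(
            self.pulm, pres["LA"], self.valves["pv"].q, dt, self.pulm_params)
        rho = cfg.fluid.rho
        vp = self.valve_params
        self.valves["tv"] = lumped.valve_step(self.valves["tv"], pres["RA"],
                                              pres["RV"], dt, vp["tv"], rho)
        self.valves["pv"] = lumped.valve_step(self.valves["pv"], pres["RV"],
                                              p_pulm["pua"], dt, vp["pv"], rho)
        self.valves["mv"] = lumped.valve_step(self.valves["mv"], pres["LA"],
                                              pres["LV"], dt, vp["mv"], rho)
        root = self.net.heart.aortic_root_vessel
        self.valves["av"] = lumped.valve_step(
            self.valves["av"], pres["LV"], self.p_ao, dt, vp["av"], rho,
            Z_wave=self._end_impedance(root, -1))

        # 3. venous valves / Starling resistors
        for el in self.elements:
            spec = el["spec"]
            p_up = self._end_pressure(spec.vessel_up, +1)
            p_down = self._end_pressure(spec.vessel_down, -1)
            Z = self._end_impedance(spec.vessel_up, +1) \
                + self._end_impedance(spec.vessel_down, -1)
            if spec.kind is ElementKind.STARLING_RESISTOR:
                el["state"] = lumped.starling_step(
                    el["state"], p_up, p_down, self.icp.p, dt, el["params"],
                    rho, Z_wave=Z)
            else:
                el["state"] = lumped.valve_step(
                    el["state"], p_up, p_down, dt, el["params"], rho, Z_wave=Z)

        # 4. boundary couplings -> star states
        stars = {}
        handled = set()
        step_mass_res, step_spread = 0.0, 0.0
        for j in self.junction_list:
            ends = [cpl.BoundaryEnd(self.grids[vid], self.states[vid], g)
                    for vid, g in j.members]
            res = cpl.solve_junction(ends, label=f"junction@{j.node}")
            qs = [abs(x) for x in res.q]
            scale = max(max(qs), 1e-12)
            step_mass_res = max(step_mass_res, abs(res.mass_residual) / scale)
            step_spread = max(step_spread, res.pressure_spread)
            for (vid, g), A, q in zip(j.members, res.A, res.q):
                stars[(vid, g)] = (A, q)
                handled.add((vid, g))
        for (vid, g), (kind, ref) in self.roles.items():
            if (vid, g) in handled:
                continue
            end = cpl.BoundaryEnd(self.grids[vid], self.states[vid], g)
            if kind == "terminal_artery":
                bed = self._bed_of_artery[vid]
                stars[(vid, g)] = cpl.couple_terminal_artery(
                    end, bed.proximal[vid].pressure(), bed.R_a[vid])
            elif kind == "terminal_vein":
                bed = self._bed_of_vein[vid]
                stars[(vid, g)] = cpl.couple_terminal_vein(
                    end, bed.distal[vid].pressure(), bed.R_v[vid])
            elif kind == "atrial_inlet":
                stars[(vid, g)] = cpl.couple_pressure_outlet(end, pres["RA"])
            elif kind == "aortic_root":
                stars[(vid, g)] = cpl.couple_prescribed_flow(end, self.valves["av"].q)
                A_star = stars[(vid, g)][0]
                self.p_ao = float(slv.cell_pressure(
                    self.grids[vid], 0, A_star, self.states[vid].w[0])[0])
            elif kind == "element_up":
                stars[(vid, g)] = cpl.couple_prescribed_flow(
                    end, self.elements[ref]["state"].q)
            elif kind == "element_down":
                stars[(vid, g)] = cpl.couple_prescribed_flow(
                    end, self.elements[ref]["state"].q)
            else:
                raise RuntimeError(kind)
        self.max_junction_mass_residual = max(self.max_junction_mass_residual,
                                              step_mass_res)
        self.max_junction_pressure_spread = max(self.max_junction_pressure_spread,
                                                step_spread)
        self._last_mass_res, self._last_spread = step_mass_res, step_spread

        # 5. advance 1D vessels through their substeps; the frozen schedule
        # is refined (never coarsened) when the current state's wave speeds
        # exceed what it was sized for
        for vid, grid in self.grids.items():
            nk, dtk = self.schedule[vid]
            st = self.states[vid]
            lam = slv.max_wave_speed(st, grid)
            n_needed = int(np.ceil(lam * dt / (cfg.solver.CFL * grid.dx) - 1e-12))
            if n_needed > nk:
                nk = n_needed
                dtk = dt / nk
            bc_l = stars[(vid, -1)]
            bc_r = stars[(vid, +1)]
            st0 = st
            for attempt in range(5):
                try:
                    st = st0
                    for _ in range(nk):
                        st = slv.advance(st, grid, dtk, bc_l, bc_r, cfg.solver)
                    break
                except ValueError:
                    # wave speeds grew inside the macro step: halve and redo
                    if attempt == 4:
                        raise
                    nk *= 2
                    dtk = dt / nk
            self.states[vid] = st

        # 6. bed + chamber volume updates
        for t_key, bed in self.beds.items():
            q_in_art = {a: stars[(a, +1)][1] for a in bed.arteries}
            q_out_ven = {v: stars[(v, -1)][1] for v in bed.veins}
            if bed.coronary:
                self._step_coronary_bed(bed, q_in_art, q_out_ven, pres, p_pc, dt)
            else:
                bedmod.step_peripheral(bed, q_in_art, q_out_ven, dt)

        # stretched-volume source: fed into the most compliant venular
        # compartment (a neutral low-pressure site that absorbs the rate
        # smoothly; the right atrium cannot take hundreds of mL/s)
        src = self.injection_rate if self.t < self.injection_until else 0.0
        if src != 0.0:
            self._injection_compartment.V += dt * src

        q_atrial_in = sum(stars[(v, +1)][1] for v in self.net.heart.atrial_inlet_vessels)
        if self.net.heart.coronary_sinus_vessel is not None:
            q_atrial_in += stars[(self.net.heart.coronary_sinus_vessel, +1)][1]
        vol = self.heart.volumes
        vol["RA"] += dt * (q_atrial_in - self.valves["tv"].q)
        vol["RV"] += dt * (self.valves["tv"].q - self.valves["pv"].q)
        vol["LA"] += dt * (self.pulm.q["puv"] - self.valves["mv"].q)
        vol["LV"] += dt * (self.valves["mv"].q - self.valves["av"].q)

        # 7. intracranial pressure on the dt_max clock
        if self.intracranial:
            V_cbv = self._compute_V_cbv()
            self._icp_accum_dV += V_cbv - self._V_cbv_prev
            self._V_cbv_prev = V_cbv
            self._icp_accum_t += dt
            if self._icp_accum_t >= cfg.solver.dt_max - 1e-12:
                self.icp = bedmod.icp_step(
                    self.icp, self._icp_accum_dV / self._icp_accum_t,
                    self._icp_accum_t)
                self._icp_accum_dV = 0.0
                self._icp_accum_t = 0.0
                for vid in self.intracranial:
                    self.grids[vid].p_ext = self.icp.p
                for comp in self._icp_compartments:
                    comp.p_ext = self.icp.p

        self.t += dt

    def _compute_V_cbv(self) -> float:
        """Cerebral blood volume: intracranial 1D vessels plus the cerebral
        bed compartments."""
        tot = 0.0
        for vid in self.intracranial:
            tot += slv.total_volume(self.states[vid], self.grids[vid])
        tot += sum(c.V for c in self._icp_compartments)
        return tot

    def _step_coronary_bed(self, bed, q_in_art, q_out_ven, pres, p_pc, dt):
        """Coronary territory: three-layer intramyocardial beds between the
        arteriolar and venular compartments."""
        chamber_V0 = {c: self.heart_params.chambers[c].V0 for c in lumped.CHAMBERS}
        inflow_a = {a: 0.0 for a in bed.arteries}
        outflow_v = {v: 0.0 for v in bed.veins}
        for (a, v), cb in bed.coronary.items():
            p_im = {lam: bedmod.intramyocardial_pressure(
                cb.wall, lam, pres, self.heart.volumes, chamber_V0, p_pc)
                for lam in bedmod.LAYERS}
            q1, q2 = bedmod.step_coronary(
                cb, bed.proximal[a].pressure(), bed.distal[v].pressure(), p_im, dt)
            inflow_a[a] += q1
            outflow_v[v] += q2
        for a in bed.arteries:
            bed.proximal[a].V += dt * (q_in_art.get(a, 0.0) - inflow_a[a])
        for v in bed.veins:
            bed.distal[v].V += dt * (outflow_v[v] - q_out_ven.get(v, 0.0))

    # -- recording and run loop ---------------------------------------------

    def _record(self):
        self._rec_t.append(self.t)
        for name, (vid, cell) in self._mon_cells.items():
            g, st = self.grids[vid], self.states[vid]
            self._rec_mon[name]["p"].append(
                float(slv.cell_pressure(g, cell, st.A[cell], st.w[cell])[0]))
            self._rec_mon[name]["q"].append(float(st.q[cell]))
            self._rec_mon[name]["A"].append(float(st.A[cell]))
        lum = self._rec_lumped
        scalars = {
            "p_LV": self.heart.pressures["LV"], "p_RA": self.heart.pressures["RA"],
            "p_LA": self.heart.pressures["LA"], "p_RV": self.heart.pressures["RV"],
            "V_LV": self.heart.volumes["LV"], "V_RV": self.heart.volumes["RV"],
            "V_LA": self.heart.volumes["LA"], "V_RA": self.heart.volumes["RA"],
            "q_av": self.valves["av"].q, "q_mv": self.valves["mv"].q,
            "q_tv": self.valves["tv"].q, "q_pv": self.valves["pv"].q,
            "p_pc": self.heart.p_pc, "p_ao": self.p_ao, "p_icp": self.icp.p,
            "V_pua": self.pulm.V["pua"], "q_puv": self.pulm.q["puv"],
            "p_pua": lumped.pulmonary_pressure("pua", self.pulm, self.pulm_params, 0.0),
        }
        for i, el in enumerate(self.elements):
            scalars[f"el{i}_q"] = el["state"].q
            scalars[f"el{i}_zeta"] = el["state"].zeta
        for k, v in scalars.items():
            lum.setdefault(k, []).append(v)
        if self.cfg.audit:
            self._rec_audit["volume"].append(self.total_blood_volume())
            self._rec_audit["junction_mass"].append(
                getattr(self, "_last_mass_res", 0.0))
            self._rec_audit["junction_spread"].append(
                getattr(self, "_last_spread", 0.0))

    def run(self, n_cycles: int | None = None,
            stop_on_periodic: bool = True) -> WaveformRecord:
        """Advance until n_cycles or the periodicity criterion is met."""
        cfg = self.cfg
        n_cycles = n_cycles or cfg.n_cycles
        self.enforce_stretched_volume()
        self._record()
        T = self.heart_params.period
        steps_per_record = cfg.output_every
        k = 0
        cycle = 0
        while cycle < n_cycles:
            next_cycle_t = (cycle + 1) * T
            while self.t < next_cycle_t - 1e-12:
                self.step()
                k += 1
                if k % steps_per_record == 0:
                    self._record()
            cycle += 1
            self._cycle_starts.append(len(self._rec_t) - 1)
            rec = self._snapshot()
            if (stop_on_periodic and rec.n_complete_cycles() >= 2
                    and self.t > self.injection_until + T):
                if periodicity_check(rec) < cfg.periodicity_tol:
                    log.info("periodic after %d cycles", cycle)
                    break
        return self._snapshot()

    def _snapshot(self) -> WaveformRecord:
        rec = WaveformRecord(
            t=np.array(self._rec_t),
            monitors={k: {q: np.array(v) for q, v in d.items()}
                      for k, d in self._rec_mon.items()},
            lumped={k: np.array(v) for k, v in self._rec_lumped.items()},
            cycle_starts=list(self._cycle_starts),
            audit={k: np.array(v) for k, v in self._rec_audit.items()},
            period=self.heart_params.period)
        return rec


def assemble(net: NetworkTopology, config: SimulationConfig | None = None,
             **kw) -> Simulation:
    """Build a ready-to-run closed-loop simulation from a validated network."""
    return Simulation(net, config or SimulationConfig(), **kw)


def config_from_yaml(path) -> SimulationConfig:
    """Run configuration from a YAML file.

    Top-level keys map to SimulationConfig fields; the nested blocks
    ``solver``, ``fluid``, ``arterial`` and ``venous`` override fields of
    the corresponding parameter sets (all CGS units). Unknown keys raise.
    """
    import dataclasses

    import yaml

    with open(path) as f:
        data = yaml.safe_load(f) or {}
    cfg = SimulationConfig()
    nested = {"solver": (cfg.solver, slv.SolverConfig),
              "fluid": (cfg.fluid, mech.FluidParams),
              "arterial": (cfg.arterial_rules, mech.ArterialParamRules),
              "venous": (cfg.venous_rules, mech.VenousParamRules)}
    for key, val in data.items():
        if key in nested:
            base, _ = nested[key]
            bad = set(val) - {f.name for f in dataclasses.fields(base)}
            if bad:
                raise ValueError(f"unknown {key} config key(s): {sorted(bad)}")
            repl = dataclasses.replace(base, **val)
            attr = {"solver": "solver", "fluid": "fluid",
                    "arterial": "arterial_rules", "venous": "venous_rules"}[key]
            setattr(cfg, attr, repl)
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg
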
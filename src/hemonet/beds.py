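"""Peripheral microcirculation beds, coronary intramyocardial beds and the
intracranial-pressure (ICP) compliance model.

Generic territories: each terminal artery feeds a proximal (arteriolar/
capillary) RC compartment; each terminal vein drains a distal (venular)
compartment; the two layers are wired many-to-many through purely resistive
arterio-venous connections (the capillary resistances). Compartment pressure
is linear in volume, p = V/C + p_ext.

Coronary territories replace the single arterio-venous resistance by a
three-layer (sub-epicardial / midwall / sub-endocardial) intramyocardial
pump: each layer holds two volume compartments whose resistances stiffen as
the compartments are squeezed by intramyocardial pressure (cavity-induced
extracellular pressure + shortening-induced intracellular pressure).

The ICP model is a nonlinear cranio-spinal compliance C_ICP = 1/(k_ICP p):
dp/dt = k_ICP p (dV_cbv/dt + q_gen - q_abs), which integrates in closed form
to p(t) = p(0) exp(k_ICP dV_cbv) when generation and absorption balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import MMHG, VenousParamRules, venous_celerity_and_stiffness
from .network import NetworkTopology

# ---------------------------------------------------------------------------
# Generic peripheral beds
# ---------------------------------------------------------------------------

R_PROXIMAL_FRACTION = 0.15     # R_ai = 0.15 R_t
R_AV_FRACTION = 0.85           # equivalent AV resistance = 0.85 R_t
C_V_DATA_DEFAULT = 146.0 / MMHG  # cm^5/dyn, total systemic venous compliance


@dataclass
class Compartment:
    C: float                   # cm^5/dyn
    V: float = 0.0             # cm^3 (stressed volume)
    p_ext: float = 0.0         # dyn/cm^2

    def pressure(self) -> float:
        return self.V / self.C + self.p_ext


@dataclass
class PeripheralBed:
    """One territory: proximal compartments (by terminal artery), distal
    compartments (by terminal vein) and the AV resistance matrix."""

    arteries: list                      # terminal artery ids
    veins: list                         # terminal vein ids
    proximal: dict = field(default_factory=dict)   # artery id -> Compartment
    distal: dict = field(default_factory=dict)     # vein id -> Compartment
    R_a: dict = field(default_factory=dict)        # artery id -> R_ai
    R_v: dict = field(default_factory=dict)        # vein id -> R_vj
    R_av: dict = field(default_factory=dict)       # (artery, vein) -> R_{ai,vj}
    coronary: object = None             # CoronaryBedGroup for coronary beds

    def av_flows(self):
        """q through each AV resistance, positive artery -> vein."""
        return {(a, v): (self.proximal[a].pressure() - self.distal[v].pressure()) / R
                for (a, v), R in self.R_av.items()}

    def q_out_arterial(self, a):
        return sum(q for (ai, _), q in self.av_flows().items() if ai == a)

    def q_in_venous(self, v):
        return sum(q for (_, vj), q in self.av_flows().items() if vj == v)


def cube_rule_split(R_equiv: float, radii: dict) -> dict:
    """Split an equivalent resistance among parallel branches with
    conductances proportional to the cubed radii (sum of conductances is
    exactly 1/R_equiv)."""
    total = sum(r ** 3 for r in radii.values())
    return {k: R_equiv * total / r ** 3 for k, r in radii.items()}


C_V_INTRACRANIAL_DEFAULT = 1.0 / MMHG   # cm^5/dyn per intracranial venular bed


def derive_peripheral_parameters(net: NetworkTopology,
                                 venous_rules: VenousParamRules,
                                 rho: float,
                                 C_v_data: float = C_V_DATA_DEFAULT,
                                 C_v_1D: float = 0.0,
                                 coronary_territories: set | None = None,
                                 intracranial_veins: set | None = None,
                                 C_v_intracranial: float = C_V_INTRACRANIAL_DEFAULT) -> dict:
    """All bed parameters from the terminal specs and the derivation rules.

    * R_ai = 0.15 R_t; the remaining 0.85 R_t is the equivalent resistance of
      that artery's AV connections, split by the cube rule over the radii of
      the draining terminal veins (radius at the vein's terminal point, i.e.
      its proximal end).
    * R_vj = rho c(A_hat)/A_hat: the characteristic impedance of the terminal
      vein at its terminal cross-section.
    * C_vj: the residual systemic venous compliance C_v,data - C_v,1D is
      distributed over the (non-coronary) venular compartments with weights
      given by the conductance-apportioned compliances of the feeding
      proximal compartments (C_ai shares of C_tot).

    Intracranial venular compartments are excluded from the residual
    distribution and receive the small fixed compliance ``C_v_intracranial``
    instead: they live inside the rigid cranio-spinal cavity, where the
    flow-share rule would place tens of mL/mmHg of compliance into the
    intracranial-pressure feedback loop and destabilize it.

    Returns {territory key: PeripheralBed}; one bed per connected component
    of the AV graph. Raises if the 1D venous network is already more
    compliant than C_v_data.
    """
    coronary_territories = coronary_territories or set()
    intracranial_veins = intracranial_veins or set()
    C_v_res = C_v_data - C_v_1D
    if C_v_res <= 0:
        raise ValueError(
            f"residual venous compliance non-positive (C_v,data={C_v_data:g}, "
            f"C_v,1D={C_v_1D:g}): 1D network over-compliant")

    # connected components of the bipartite AV graph -> one bed each
    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        parent[find(x)] = find(y)

    for (a, v) in net.av.edges:
        union(("a", a), ("v", v))

    groups: dict = {}
    for (a, v) in net.av.edges:
        groups.setdefault(find(("a", a)), set()).add((a, v))

    # per-artery AV resistances (cube rule) and proximal values
    R_a, R_av, C_a = {}, {}, {}
    for a, spec in net.terminals.items():
        R_a[a] = R_PROXIMAL_FRACTION * spec.R_t
        C_a[a] = spec.C_a
        radii = {v: net.vessels[v].radius_prox for v in spec.draining_veins}
        split = cube_rule_split(R_AV_FRACTION * spec.R_t, radii)
        for v, R in split.items():
            R_av[(a, v)] = R

    # venous proximal resistances (characteristic impedance at the terminal
    # point = the vein's proximal end, where it meets its venular compartment)
    R_v = {}
    for v_id in net.terminal_veins():
        ves = net.vessels[v_id]
        r_hat = ves.radius_prox
        A_hat = math.pi * r_hat ** 2
        r_mid = ves.radius_at(0.5)
        dural = ves.vessel_class.value == "dural_sinus"
        from .mechanics import DURAL_SINUS_EXPONENTS, VEIN_EXPONENTS
        m, n = DURAL_SINUS_EXPONENTS if dural else VEIN_EXPONENTS
        c, _ = venous_celerity_and_stiffness(r_mid, venous_rules, rho, m, n)
        R_v[v_id] = rho * c / A_hat

    # venular compliances: conductance-weighted C_ai shares of the residual
    def excluded(a, v):
        return (net.terminals[a].territory in coronary_territories
                or v in intracranial_veins)

    C_tot = 0.0
    for (a, v), R in R_av.items():
        if not excluded(a, v):
            g_frac = (1.0 / R) / sum(1.0 / R_av[(a, vv)]
                                     for vv in net.terminals[a].draining_veins)
            C_tot += C_a[a] * g_frac
    weights = {}
    for (a, v), R in R_av.items():
        if excluded(a, v):
            continue
        g_frac = (1.0 / R) / sum(1.0 / R_av[(a, vv)]
                                 for vv in net.terminals[a].draining_veins)
        weights[v] = weights.get(v, 0.0) + C_a[a] * g_frac / C_tot
    C_v = {v: w * C_v_res for v, w in weights.items()}
    for v in intracranial_veins:
        C_v[v] = C_v_intracranial

    beds = {}
    for key, edges in groups.items():
        arteries = sorted({a for a, _ in edges})
        veins = sorted({v for _, v in edges})
        bed = PeripheralBed(arteries=arteries, veins=veins)
        for a in arteries:
            bed.proximal[a] = Compartment(C=C_a[a])
            bed.R_a[a] = R_a[a]
        for v in veins:
            # coronary venular compliance is set by the coronary derivation
            bed.distal[v] = Compartment(C=C_v.get(v, 1e-6))
            bed.R_v[v] = R_v[v]
        for (a, v) in edges:
            bed.R_av[(a, v)] = R_av[(a, v)]
        territory = net.terminals[arteries[0]].territory or f"bed{len(beds)}"
        beds[territory] = bed
    return beds


def step_peripheral(bed: PeripheralBed, q_in_art: dict, q_out_ven: dict,
                    dt: float) -> None:
    """Explicit-Euler volume update of all compartments (in place).

    q_in_art: inflow from each terminal artery (1D coupling);
    q_out_ven: outflow into each terminal vein (1D coupling).
    """
    flows = bed.av_flows()
    for a in bed.arteries:
        out = sum(q for (ai, _), q in flows.items() if ai == a)
        bed.proximal[a].V += dt * (q_in_art.get(a, 0.0) - out)
    for v in bed.veins:
        inn = sum(q for (_, vj), q in flows.items() if vj == v)
        bed.distal[v].V += dt * (inn - q_out_ven.get(v, 0.0))


# ---------------------------------------------------------------------------
# Coronary beds
# ---------------------------------------------------------------------------

LAYERS = ("sub-epi", "midwall", "sub-endo")
LAYER_WEIGHTS = {"sub-epi": 1.0 / 6.0, "midwall": 0.5, "sub-endo": 5.0 / 6.0}
ALPHA_SIP = 8.2                 # 1/cm^3 (pressure-consistent units)
ETA = {1: 2.5, 2: 8.0}          # cm^3/100 g, perfusion volume rates
KAPPA = {1: 9.7501e-6, 2: 1.905019e-4}   # cm^5/dyn/100 g
RHO_MYO = 1.05                  # g/cm^3
V_MID_OVER_ENDO = 0.93
V_EPI_OVER_ENDO = 0.87
R_MID_OVER_EPI = 0.6
R_ENDO_OVER_EPI = 0.2
R1_OVER_RM = 1.2
R2_OVER_RM = 0.5

MYOCARDIAL_VOLUMES = {          # cm^3, per perfused wall
    "LV-fw": 111.43, "RV-fw": 47.62, "IVS": 58.09, "LA": 15.48, "RA": 13.76,
}
WALL_CHAMBER = {"LV-fw": "LV", "RV-fw": "RV", "IVS": "LV", "LA": "LA", "RA": "RA"}

VOLUME_FLOOR_FRACTION = 1e-3    # guard against vanishing compartment volume


def layer_split(total: float) -> dict:
    """Split a total over the three layers with the fixed endo ratios."""
    endo = total / (1.0 + V_MID_OVER_ENDO + V_EPI_OVER_ENDO)
    return {"sub-endo": endo, "midwall": V_MID_OVER_ENDO * endo,
            "sub-epi": V_EPI_OVER_ENDO * endo}


def parallel_layer_resistances(R_tot: float) -> dict:
    """Layer totals from the parallel arrangement with the fixed ratios."""
    R_epi = R_tot * (1.0 + 1.0 / R_MID_OVER_EPI + 1.0 / R_ENDO_OVER_EPI)
    return {"sub-epi": R_epi, "midwall": R_MID_OVER_EPI * R_epi,
            "sub-endo": R_ENDO_OVER_EPI * R_epi}


def series_split(R_layer: float) -> dict:
    """(R1, Rm, R2) with R1 = 1.2 Rm, R2 = 0.5 Rm, summing to R_layer."""
    Rm = R_layer / (R1_OVER_RM + 1.0 + R2_OVER_RM)
    return {1: R1_OVER_RM * Rm, "m": Rm, 2: R2_OVER_RM * Rm}


@dataclass
class CoronaryBed:
    """One arterio-venous coronary connection (all three layers)."""

    wall: str
    V0: dict                   # (i, layer) -> reference volume, i in {1, 2}
    C: dict                    # (i, layer) -> compliance
    R0: dict                   # (j, layer) -> nominal resistance, j in {1, m, 2}
    V: dict = None             # (i, layer) -> current volume

    def __post_init__(self):
        if self.V is None:
            self.V = dict(self.V0)

    def resistances(self) -> dict:
        """The nine volume-dependent resistances R^j_lambda."""
        R = {}
        for lam in LAYERS:
            for j in (1, 2):
                V = max(self.V[(j, lam)],
                        VOLUME_FLOOR_FRACTION * self.V0[(j, lam)])
                R[(j, lam)] = self.R0[(j, lam)] * (self.V0[(j, lam)] / V) ** 2
            V1 = max(self.V[(1, lam)], VOLUME_FLOOR_FRACTION * self.V0[(1, lam)])
            V2 = max(self.V[(2, lam)], VOLUME_FLOOR_FRACTION * self.V0[(2, lam)])
            R[("m", lam)] = self.R0[("m", lam)] * (
                0.75 * (self.V0[(1, lam)] / V1) ** 2
                + 0.25 * (self.V0[(2, lam)] / V2) ** 2)
        return R


def shortening_induced_pressure(p_ch: float, V_ch: float, V_ch0: float,
                                alpha: float = ALPHA_SIP) -> float:
    """SIP = alpha p_ch (V_ch - V_ch0); alpha carries 1/cm^3."""
    return alpha * p_ch * (V_ch - V_ch0)


def cavity_induced_pressure(layer: str, p_ch: float, p_out: float) -> float:
    """CEP: linear blend between the outer pressure and the chamber pressure
    with the layer depth weight (sub-endo feels 5/6 of the cavity load)."""
    return p_out + LAYER_WEIGHTS[layer] * (p_ch - p_out)


SIP_CAP_DEFAULT = 0.5   # |SIP| <= cap * |p_ch|; None disables the clamp


def intramyocardial_pressure(wall: str, layer: str, chamber_pressures: dict,
                             chamber_volumes: dict, chamber_V0: dict,
                             p_pc: float, alpha: float = ALPHA_SIP,
                             sip_cap: float | None = SIP_CAP_DEFAULT) -> float:
    """p_im = CEP + SIP for one wall/layer.

    Free walls see the pericardial pressure outside; the interventricular
    septum sees the right ventricle outside and the left ventricle as its
    driving chamber.

    The SIP term is clamped to ``sip_cap * |p_ch|`` by default: the stated
    pressure-times-volume form with alpha in 1/cm^3 is dimensionally
    inconsistent and produces intramyocardial pressures orders of magnitude
    beyond tissue pressures, which no closed-loop state survives. With the clamp, systolic sub-endocardial p_im ~ 1.3 p_LV,
    consistent with intramyocardial-pump physiology.
    """
    ch = WALL_CHAMBER[wall]
    p_out = chamber_pressures["RV"] if wall == "IVS" else p_pc
    cep = cavity_induced_pressure(layer, chamber_pressures[ch], p_out)
    sip = shortening_induced_pressure(chamber_pressures[ch],
                                      chamber_volumes[ch], chamber_V0[ch], alpha)
    if sip_cap is not None:
        bound = sip_cap * abs(chamber_pressures[ch])
        sip = min(max(sip, -bound), bound)
    return cep + sip


def derive_coronary_parameters(net: NetworkTopology, R_av: dict,
                               wall_volumes: dict | None = None) -> dict:
    """Coronary bed parameters for every coronary AV connection.

    The myocardial wall volumes are partitioned among the terminal coronary
    arteries perfusing each wall proportionally to the cubed terminal radii,
    then among each artery's venous connections the same way. Reference
    volumes and compliances follow the perfusion-rate constants (eta, kappa)
    per 100 g of tissue; nominal resistances are anchored to the connection's
    AV resistance R_{ai,vl} with the fixed parallel/series ratios.

    R_av maps (artery id, vein id) -> capillary resistance for coronary
    connections (from the generic derivation). Returns
    {(artery, vein): CoronaryBed}.
    """
    wall_volumes = wall_volumes or MYOCARDIAL_VOLUMES
    by_wall: dict = {}
    for a, wall in net.coronary_walls.items():
        by_wall.setdefault(wall, []).append(a)
    for wall in by_wall:
        if wall not in wall_volumes:
            raise ValueError(f"unknown myocardial wall {wall!r}")

    V_perf_art = {}
    for wall, arts in by_wall.items():
        radii = {a: net.vessels[a].radius_dist for a in arts}
        total = sum(r ** 3 for r in radii.values())
        if total <= 0:
            raise ValueError(f"wall {wall}: no perfusing terminal")
        for a, r in radii.items():
            V_perf_art[a] = wall_volumes[wall] * r ** 3 / total

    out = {}
    for a, wall in net.coronary_walls.items():
        veins = net.terminals[a].draining_veins
        radii = {v: net.vessels[v].radius_prox for v in veins}
        r3tot = sum(r ** 3 for r in radii.values())
        for v in veins:
            V_perf = V_perf_art[a] * radii[v] ** 3 / r3tot
            V0, C, R0 = {}, {}, {}
            for i in (1, 2):
                V_tot = V_perf * RHO_MYO * ETA[i] / 100.0
                C_tot = V_perf * RHO_MYO * KAPPA[i] / 100.0
                for lam, Vl in layer_split(V_tot).items():
                    V0[(i, lam)] = Vl
                for lam, Cl in layer_split(C_tot).items():
                    C[(i, lam)] = Cl
            R_tot0 = R_av[(a, v)]
            for lam, R_layer in parallel_layer_resistances(R_tot0).items():
                for j, Rj in series_split(R_layer).items():
                    R0[(j, lam)] = Rj
            out[(a, v)] = CoronaryBed(wall=wall, V0=V0, C=C, R0=R0)
    return out


def coronary_arteriolar_compliance(beds_of_artery: list) -> float:
    """0.1 * sum of the region-1 total compliances over the artery's beds."""
    return 0.1 * sum(sum(b.C[(1, lam)] for lam in LAYERS) for b in beds_of_artery)


def coronary_venular_compliance(beds_of_vein: list) -> float:
    """0.1 * sum of the region-2 total compliances over the vein's beds."""
    return 0.1 * sum(sum(b.C[(2, lam)] for lam in LAYERS) for b in beds_of_vein)


def step_coronary(bed: CoronaryBed, p_a: float, p_v: float, p_im: dict,
                  dt: float) -> tuple[float, float]:
    """Advance one coronary connection by dt (explicit Euler, in place).

    p_a / p_v: arteriolar and venular compartment blood pressures;
    p_im: layer -> intramyocardial pressure. Returns (inflow drawn from the
    arteriolar compartment, outflow delivered to the venular compartment).
    """
    R = bed.resistances()
    q_in_tot = q_out_tot = 0.0
    newV = {}
    for lam in LAYERS:
        p1 = p_im[lam] + (bed.V[(1, lam)] - bed.V0[(1, lam)]) / bed.C[(1, lam)]
        p2 = p_im[lam] + (bed.V[(2, lam)] - bed.V0[(2, lam)]) / bed.C[(2, lam)]
        q1 = (p_a - p1) / R[(1, lam)]
        qm = (p1 - p2) / R[("m", lam)]
        q2 = (p2 - p_v) / R[(2, lam)]
        newV[(1, lam)] = bed.V[(1, lam)] + dt * (q1 - qm)
        newV[(2, lam)] = bed.V[(2, lam)] + dt * (qm - q2)
        q_in_tot += q1
        q_out_tot += q2
    for k, val in newV.items():
        bed.V[k] = max(val, VOLUME_FLOOR_FRACTION * bed.V0[k])
    return q_in_tot, q_out_tot


# ---------------------------------------------------------------------------
# Intracranial pressure
# ---------------------------------------------------------------------------

K_ICP_DEFAULT = 0.15           # 1/cm^3
P_ICP_INITIAL = 14665.42       # dyn/cm^2 (11.0 mmHg)


@dataclass
class ICPState:
    p: float = P_ICP_INITIAL   # dyn/cm^2
    k: float = K_ICP_DEFAULT   # 1/cm^3
    q_gen: float = 0.0         # cm^3/s, CSF generation
    q_abs: float = 0.0         # cm^3/s, CSF absorption

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError("p_ICP must be positive")


def icp_step(state: ICPState, dV_cbv_dt: float, dt: float) -> ICPState:
    """Explicit-Euler update dp/dt = k p (dV_cbv/dt + q_gen - q_abs)."""
    dp = state.k * state.p * (dV_cbv_dt + state.q_gen - state.q_abs)
    p_new = state.p + dt * dp
    if p_new <= 0:
        raise ValueError("p_ICP driven non-positive")
    return ICPState(p=p_new, k=state.k, q_gen=state.q_gen, q_abs=state.q_abs)
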
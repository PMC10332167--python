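"""Lumped (0D) model elements: heart chambers, valves, Starling resistors
and the pulmonary circulation.

Chamber pressure couples a prescribed time-varying free-wall elastance with
septal interaction (each chamber feels its contralateral partner through the
shared septum), a pericardial constraint (exponential pressure-volume law on
the total cardiac volume) and a flow-dependent source resistance.

Valves and Starling resistors share one ODE structure: an inertance/
quadratic-resistance flow equation driven by the pressure difference across
the element, with an opening-state variable in [0, 1] that scales the
effective orifice area. The Starling resistor additionally blends the
downstream pressure with the external (intracranial) pressure according to
its state, which produces the vascular-waterfall behaviour: once collapsed,
flow is driven by upstream-minus-external pressure and becomes independent
of the downstream (central venous) side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import MMHG

CHAMBERS = ("RA", "RV", "LA", "LV")


# ---------------------------------------------------------------------------
# Chambers and pericardium
# ---------------------------------------------------------------------------

@dataclass
class ChamberParams:
    V0: float                # cm^3, reference (unstressed) volume
    E_min: float             # dyn/cm^2/cm^3, minimum free-wall elastance
    E_max: float             # dyn/cm^2/cm^3, maximum free-wall elastance
    tau1: float              # s, contraction time offset
    tau2: float              # s, relaxation time offset
    m1: float                # contraction rate constant
    m2: float                # relaxation rate constant
    t_onset: float           # s, activation onset within the cycle
    K_S: float = 5e-5        # s/cm^3, source-resistance constant
    mu_AV: float = 0.0       # dyn s/cm^8, atrio-ventricular plane constant

    def __post_init__(self):
        if not (self.E_max >= self.E_min > 0):
            raise ValueError("require E_max >= E_min > 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1, tau2 must be positive")


@dataclass
class PericardiumParams:
    K_pc: float = 400.0      # dyn/cm^2
    Phi_pc: float = 50.0     # cm^3
    V0_pc: float = 520.0     # cm^3
    V_mio: float = 220.0     # cm^3, myocardial volume (constant)
    V_pcf: float = 20.0      # cm^3, pericardial fluid volume (constant)

    def __post_init__(self):
        if self.Phi_pc <= 0:
            raise ValueError("Phi_pc must be positive")


def _shape(tau, p: ChamberParams):
    """Normalized activation shape g1/(1+g1) * 1/(1+g2) at cycle time tau."""
    tau = np.asarray(tau, dtype=float)
    g1 = (tau / p.tau1) ** p.m1
    g2 = (tau / p.tau2) ** p.m2
    return g1 / (1.0 + g1) / (1.0 + g2)


def elastance_normalization(p: ChamberParams, period: float, n_samples: int = 10000):
    """k such that max_t E_fw = E_max (dense sampling over one period)."""
    tau = np.linspace(0.0, period, n_samples, endpoint=False)
    peak = float(np.max(_shape(tau, p)))
    if peak <= 0:
        raise ValueError("degenerate elastance shape")
    return (p.E_max - p.E_min) / peak


def free_wall_elastance(t, p: ChamberParams, period: float, k: float | None = None):
    """E_fw at time t (t may be outside [0, T); onset-relative and periodic)."""
    if k is None:
        k = elastance_normalization(p, period)
    tau = np.mod(np.asarray(t, dtype=float) - p.t_onset, period)
    return k * _shape(tau, p) + p.E_min


@dataclass
class HeartParams:
    chambers: dict                     # name -> ChamberParams
    pericardium: PericardiumParams
    K_C_atria: float = 10.0            # septal elastance constant (atria)
    K_C_ventricles: float = 10.0       # septal elastance constant (ventricles)
    period: float = 0.9                # s, cardiac period

    def __post_init__(self):
        self._k = {name: elastance_normalization(cp, self.period)
                   for name, cp in self.chambers.items()}

    def E_fw(self, name, t):
        return free_wall_elastance(t, self.chambers[name], self.period, self._k[name])


@dataclass
class HeartState:
    volumes: dict = field(default_factory=lambda: {c: 0.0 for c in CHAMBERS})
    pressures: dict = field(default_factory=lambda: {c: 0.0 for c in CHAMBERS})
    p_pc: float = 0.0


def pericardial_pressure(total_chamber_volume: float, p: PericardiumParams) -> float:
    V_pc = p.V_mio + p.V_pcf + total_chamber_volume
    return p.K_pc * math.exp((V_pc - p.V0_pc) / p.Phi_pc)


def septal_elastance(E_fw_L: float, E_fw_R: float, K_C: float) -> float:
    """E_sep = K_C (E_fw,L + E_fw,R); identical for both members of a pair."""
    return K_C * (E_fw_L + E_fw_R)


def native_elastance(E_fw: float, E_sep: float, mu_AV: float, q_V: float) -> float:
    return E_fw * E_sep / (E_fw + E_sep) - mu_AV * q_V


def chamber_pressures(params: HeartParams, t: float, volumes: dict,
                      q_out: dict, q_V: dict | None = None) -> tuple[dict, float]:
    """All four chamber pressures at time t, solved pairwise.

    Each chamber's pressure depends linearly on its contralateral partner's
    (septal coupling), so the (LA, RA) and (LV, RV) pairs are each an exact
    2x2 linear solve:  p_a = c_a + r_a p_b,  p_b = c_b + r_b p_a.
    q_out maps chamber -> outflow; q_V maps chamber -> trans-AV-plane flow
    (used only when mu_AV != 0).
    """
    q_V = q_V or {c: 0.0 for c in CHAMBERS}
    p_pc = pericardial_pressure(sum(volumes[c] for c in CHAMBERS), params.pericardium)
    pressures = {}
    for pair, K_C in ((("LA", "RA"), params.K_C_atria),
                      (("LV", "RV"), params.K_C_ventricles)):
        a, b = pair
        E_fw = {c: params.E_fw(c, t) for c in pair}
        E_sep = septal_elastance(E_fw[a], E_fw[b], K_C)
        coef = {}
        for c in pair:
            cp = params.chambers[c]
            E_nat = native_elastance(E_fw[c], E_sep, cp.mu_AV, q_V[c])
            R_S = cp.K_S * E_nat * (volumes[c] - cp.V0)
            const = p_pc + E_nat * (volumes[c] - cp.V0) - R_S * q_out[c]
            coef[c] = (const, E_nat / E_sep)
        ca, ra = coef[a]
        cb, rb = coef[b]
        det = 1.0 - ra * rb
        if abs(det) < 1e-12:
            raise ValueError(f"singular contralateral solve for pair {pair}")
        pressures[a] = (ca + ra * cb) / det
        pressures[b] = (cb + rb * ca) / det
    return pressures, p_pc


# ---------------------------------------------------------------------------
# Valves and Starling resistors
# ---------------------------------------------------------------------------

@dataclass
class ValveParams:
    l_eff: float             # cm, effective length
    A_eff_max: float         # cm^2
    A_eff_min: float = 0.0   # cm^2
    K_vo: float = 0.03       # cm^2/(dyn s), opening rate constant
    K_vc: float = 0.04       # cm^2/(dyn s), closing rate constant
    dp_open: float = 0.0     # dyn/cm^2
    dp_close: float = 0.0    # dyn/cm^2

    def __post_init__(self):
        if not (self.A_eff_max >= self.A_eff_min >= 0):
            raise ValueError("require A_eff_max >= A_eff_min >= 0")


@dataclass
class ValveState:
    zeta: float = 0.0        # opening state in [0, 1]
    q: float = 0.0           # cm^3/s


AEFF_FLOOR_FRACTION = 1e-6   # keeps B, L finite for a sealed valve


def effective_area(zeta: float, p: ValveParams) -> float:
    A = (p.A_eff_max - p.A_eff_min) * zeta + p.A_eff_min
    return max(A, AEFF_FLOOR_FRACTION * p.A_eff_max)


def _bernoulli_coeffs(zeta: float, p: ValveParams, rho: float):
    A_eff = effective_area(zeta, p)
    L = rho * p.l_eff / A_eff
    B = rho / (2.0 * A_eff ** 2)
    return B, L


def valve_flow_step(state: ValveState, p_up: float, p_down_eff: float,
                    dt: float, p: ValveParams, rho: float,
                    Z_wave: float = 0.0) -> float:
    """One step of dq/dt = (dp - B q|q|)/L.

    The driving term is explicit; the quadratic drag is integrated
    semi-implicitly, which is unconditionally stable when the orifice is
    nearly sealed (B ~ 1/A_eff^2 becomes enormous). ``Z_wave`` is the summed
    characteristic impedance (rho c / A) of adjacent 1D vessel ends: the
    upstream/downstream pressures are linearized about the current flow,
    p_up(q) = p_up - Z_up (q - q_n), which is exactly the feedback the
    vessels' outgoing characteristics would apply, and removes the flow
    overshoot of a purely explicit coupling. It introduces no steady-state
    bias (the correction vanishes at q = q_n).
    """
    B, L = _bernoulli_coeffs(state.zeta, p, rho)
    q = state.q
    return (q + dt * (p_up - p_down_eff + Z_wave * q) / L) \
        / (1.0 + dt * (B * abs(q) + Z_wave) / L)


def valve_state_step(zeta: float, dp: float, dt: float, p: ValveParams) -> float:
    """Opening-state update with hysteresis band [dp_close, dp_open]."""
    if dp >= p.dp_open:
        dzeta = p.K_vo * (1.0 - zeta) * dp
    elif dp < p.dp_close:
        dzeta = p.K_vc * zeta * dp
    else:
        dzeta = 0.0
    return min(1.0, max(0.0, zeta + dt * dzeta))


def valve_step(state: ValveState, p_up: float, p_down: float, dt: float,
               p: ValveParams, rho: float, Z_wave: float = 0.0) -> ValveState:
    """Advance flow and opening state of a cardiac or venous valve."""
    q_new = valve_flow_step(state, p_up, p_down, dt, p, rho, Z_wave)
    zeta_new = valve_state_step(state.zeta, p_up - p_down, dt, p)
    return ValveState(zeta=zeta_new, q=q_new)


@dataclass
class StarlingParams:
    """A Starling resistor's orifice is fixed (averaged from the adjacent
    segments); its state only blends the downstream pressure with the
    external one, which is what produces the vascular waterfall (flow
    persists through a collapsed segment, driven by p_up - p_ext)."""

    l_eff: float
    A_eff: float             # cm^2, fixed effective area
    K_so: float = 0.01       # opening constant
    K_sc: float = 0.01       # closing constant

    def as_valve(self) -> ValveParams:
        # A_eff_min = A_eff_max: the orifice does not track the state
        return ValveParams(l_eff=self.l_eff, A_eff_max=self.A_eff,
                           A_eff_min=self.A_eff, K_vo=self.K_so,
                           K_vc=self.K_sc, dp_open=0.0, dp_close=0.0)


def starling_effective_downstream(p_down: float, p_ext: float, zeta: float) -> float:
    """p*_down = (p_down - p_ext) zeta + p_ext.

    Fully open (zeta=1): the true downstream pressure drives the flow.
    Collapsed (zeta=0): the external pressure replaces it (waterfall).
    """
    return (p_down - p_ext) * zeta + p_ext


def starling_step(state: ValveState, p_up: float, p_down: float, p_ext: float,
                  dt: float, p: StarlingParams, rho: float,
                  Z_wave: float = 0.0) -> ValveState:
    """Advance a Starling resistor; state dynamics driven by p_down - p_ext."""
    vp = p.as_valve()
    p_down_eff = starling_effective_downstream(p_down, p_ext, state.zeta)
    q_new = valve_flow_step(state, p_up, p_down_eff, dt, vp, rho, Z_wave)
    zeta_new = valve_state_step(state.zeta, p_down - p_ext, dt, vp)
    return ValveState(zeta=zeta_new, q=q_new)


# ---------------------------------------------------------------------------
# Pulmonary circulation
# ---------------------------------------------------------------------------

PULMONARY_COMPARTMENTS = ("pua", "puc", "puv")


@dataclass
class PulmonaryCompartment:
    E0: float                # dyn/cm^2/cm^3, reference-volume elastance
    V0: float                # cm^3, reference volume
    Omega: float             # dyn s/cm^5, viscoelastance
    L: float                 # dyn s^2/cm^5, inertance
    R: float                 # dyn s/cm^5, resistance

    def __post_init__(self):
        if min(self.E0, self.V0, self.L, self.R) <= 0 or self.Omega < 0:
            raise ValueError("pulmonary parameters must be positive")


@dataclass
class PulmonaryParams:
    compartments: dict       # name -> PulmonaryCompartment


@dataclass
class PulmonaryState:
    V: dict = field(default_factory=lambda: {c: 0.0 for c in PULMONARY_COMPARTMENTS})
    q: dict = field(default_factory=lambda: {c: 0.0 for c in PULMONARY_COMPARTMENTS})


def pulmonary_pressure(name: str, state: PulmonaryState, params: PulmonaryParams,
                       dVdt: float) -> float:
    c = params.compartments[name]
    return c.E0 * c.V0 * math.exp(state.V[name] / c.V0) + c.Omega * dVdt


def pulmonary_step(state: PulmonaryState, p_LA: float, q_pv: float, dt: float,
                   params: PulmonaryParams) -> tuple[PulmonaryState, dict]:
    """Explicit-Euler advance of the pua -> puc -> puv chain.

    q_pv is the pulmonary-valve inflow; the puv compartment discharges into
    the left atrium. Returns the new state and the compartment pressures
    used in the step.
    """
    inflow = {"pua": q_pv, "puc": state.q["pua"], "puv": state.q["puc"]}
    dVdt = {n: inflow[n] - state.q[n] for n in PULMONARY_COMPARTMENTS}
    p = {n: pulmonary_pressure(n, state, params, dVdt[n])
         for n in PULMONARY_COMPARTMENTS}
    p_down = {"pua": p["puc"], "puc": p["puv"], "puv": p_LA}
    new = PulmonaryState(V=dict(state.V), q=dict(state.q))
    for n in PULMONARY_COMPARTMENTS:
        c = params.compartments[n]
        new.V[n] = state.V[n] + dt * dVdt[n]
        new.q[n] = state.q[n] + dt * (p[n] - p_down[n] - c.R * state.q[n]) / c.L
    return new, p


# ---------------------------------------------------------------------------
# Default presets: plausible adult values in the lineage of established
# time-varying-elastance heart models; not fitted to any dataset
# ---------------------------------------------------------------------------

def default_heart_params(period: float = 0.9) -> HeartParams:
    E = MMHG  # mmHg/mL -> dyn/cm^2/cm^3 is the same numeric factor
    chambers = {
        "LV": ChamberParams(V0=10.0, E_min=0.08 * E, E_max=2.6 * E,
                            tau1=0.269 * period / 0.9, tau2=0.452 * period / 0.9,
                            m1=1.32, m2=27.4, t_onset=0.0),
        "RV": ChamberParams(V0=10.0, E_min=0.045 * E, E_max=0.52 * E,
                            tau1=0.269 * period / 0.9, tau2=0.452 * period / 0.9,
                            m1=1.32, m2=27.4, t_onset=0.0),
        "LA": ChamberParams(V0=3.0, E_min=0.08 * E, E_max=0.17 * E,
                            tau1=0.110 * period / 0.9, tau2=0.180 * period / 0.9,
                            m1=1.99, m2=11.2, t_onset=0.85 * period),
        "RA": ChamberParams(V0=3.0, E_min=0.07 * E, E_max=0.15 * E,
                            tau1=0.110 * period / 0.9, tau2=0.180 * period / 0.9,
                            m1=1.99, m2=11.2, t_onset=0.85 * period),
    }
    return HeartParams(chambers=chambers, pericardium=PericardiumParams(),
                       period=period)


def default_cardiac_valves() -> dict:
    return {
        "av": ValveParams(l_eff=1.0, A_eff_max=4.8),
        "mv": ValveParams(l_eff=1.2, A_eff_max=6.5),
        "pv": ValveParams(l_eff=1.0, A_eff_max=5.0),
        "tv": ValveParams(l_eff=1.2, A_eff_max=7.5),
    }


VENOUS_VALVE_KVO = 0.1
VENOUS_VALVE_KVC = 0.03
STARLING_KSO = 0.01
STARLING_KSC = 0.01


def default_pulmonary_params() -> PulmonaryParams:
    return PulmonaryParams(compartments={
        "pua": PulmonaryCompartment(E0=120.0, V0=50.0, Omega=10.0, L=0.3, R=30.0),
        "puc": PulmonaryCompartment(E0=50.0, V0=100.0, Omega=10.0, L=0.3, R=40.0),
        "puv": PulmonaryCompartment(E0=36.0, V0=120.0, Omega=10.0, L=0.3, R=13.0),
    })
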
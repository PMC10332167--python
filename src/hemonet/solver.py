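"""Second-order well-balanced path-conservative finite-volume solver for the
1D blood-flow equations on a single vessel.

Equations (per cell, CGS): conservation of mass and balance of momentum

    dA/dt + dq/dx = 0
    dq/dt + d(q^2/A)/dx + (A/rho) dp/dx = -8 pi mu q / (rho A)

closed by a tube law p = p_ext + p_elastic(A; x) + Gamma(A; x) dA/dt whose
rate term makes the system advection-diffusion. The diffusive term is
removed by a hyperbolic relaxation: an auxiliary per-cell field w obeys

    dw/dt + (1/tau) dq/dx = -w/tau

so w -> -dq/dx = dA/dt as tau -> 0, and the pressure used everywhere is
p = p_ext + p_elastic(A) + Gamma(A) w. The stiff source is integrated
implicitly (the update recovers the equilibrium w = -dq/dx exactly in the
stiff limit), so any relaxation time is stable.

Scheme structure per step:
1. slope-limited reconstruction in (p, q, w) -- reconstructing the pressure
   rather than the area is what makes the scheme well-balanced for varying
   mechanical/geometric properties: a quiescent state with uniform total
   pressure has zero slopes and zero interface jumps regardless of how
   A0(x) or the stiffness vary;
2. cell-local predictor evolving edge-extrapolated states to the half time
   (an ADER-type generalized-Riemann-problem evolution, with the relaxation
   source handled semi-implicitly);
3. path-conservative fluctuations at interfaces: the non-conservative
   pressure term enters as (A_avg/rho)(p_R - p_L) and the dissipation acts
   on the steady-state-preserving jump variables (dp, dq, dw).

Vessel-boundary interfaces take externally solved star states (from the
junction/terminal couplings) and apply the full fluctuation to the interior
cell, so the mass exchanged with the coupled 0D elements is exactly q*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import mechanics as mech
from .network import Vessel, VesselClass

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-cell wall-parameter fields (vectorized tube laws)
# ---------------------------------------------------------------------------

class ArterialWallField:
    """Vectorized arterial tube law over the cells of one vessel."""

    is_arterial = True

    def __init__(self, walls: list):
        self.A0 = np.array([w.A0 for w in walls])
        self.piR0h0 = np.array([math.pi * w.R0 * w.h0 for w in walls])
        self.Ee = np.array([w.Ee_eff for w in walls])
        self.Ec = np.array([w.Ec_eff for w in walls])
        self.Km = np.array([w.Km for w in walls])
        self.p0 = np.array([w.p0 for w in walls])
        self.eps0 = np.array([w.eps0 for w in walls])
        self.eps_r = np.array([w.eps_r for w in walls])

    def p_elastic(self, A):
        eps = A / self.A0 - 1.0
        chi = (eps - self.eps0) / self.eps_r
        wall = self.Ee * eps + self.Ec * self.eps_r * np.logaddexp(0.0, chi)
        return self.piR0h0 / A * wall + self.p0

    def dpdA(self, A):
        eps = A / self.A0 - 1.0
        chi = (eps - self.eps0) / self.eps_r
        sig = 1.0 / (1.0 + np.exp(-chi))
        wall = self.Ee * eps + self.Ec * self.eps_r * np.logaddexp(0.0, chi)
        dwall = (self.Ee + self.Ec * sig) / self.A0
        return self.piR0h0 * (dwall / A - wall / A ** 2)

    def gamma(self, A):
        return 0.5 * self.Km * np.sqrt(A) / self.A0

    def dgamma(self, A):
        return 0.25 * self.Km / (self.A0 * np.sqrt(A))


class VenousWallField:
    """Vectorized collapsible-tube law over the cells of one vessel."""

    is_arterial = False

    def __init__(self, walls: list):
        self.A0 = np.array([w.A0 for w in walls])
        self.K = np.array([w.K for w in walls])
        self.m = np.array([w.m for w in walls])
        self.n = np.array([w.n for w in walls])
        self.Km = np.array([w.Km for w in walls])
        self.p0 = np.array([w.p0 for w in walls])

    def p_elastic(self, A):
        r = A / self.A0
        return self.K * (r ** self.m - r ** self.n) + self.p0

    def dpdA(self, A):
        r = A / self.A0
        return self.K * (self.m * r ** (self.m - 1.0)
                         - self.n * r ** (self.n - 1.0)) / self.A0

    def gamma(self, A):
        return self.Km * self.A0 / A

    def dgamma(self, A):
        return -self.Km * self.A0 / A ** 2


# ---------------------------------------------------------------------------
# Grid, state, configuration
# ---------------------------------------------------------------------------

DX_CHARACTERISTIC = 1.0       # cm; shorter vessels get a single cell

LIMITERS = ("minmod", "mc", "central", "zero")


@dataclass
class SolverConfig:
    CFL: float = 0.9
    dt_max: float = 1.0e-3    # s
    order: int = 2
    limiter: str = "mc"
    tau_scale: float = 1.0    # multiplies the per-vessel relaxation time
    area_floor: float = 1e-10  # fraction of A0 below which A is floored

    def __post_init__(self):
        if not (0.0 < self.CFL < 1.0):
            raise ValueError("require 0 < CFL < 1")
        if self.limiter not in LIMITERS:
            raise ValueError(f"unknown limiter {self.limiter!r}")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


class VesselGrid:
    """Discretization of one vessel: cells, wall field, fluid properties."""

    def __init__(self, wall, length: float, rho: float, mu: float,
                 tau: float | None = None, p_ext: float = 0.0,
                 vessel_id: int = -1):
        self.wall = wall
        self.n_cells = len(wall.A0)
        self.dx = length / self.n_cells
        self.length = length
        self.rho = rho
        self.mu = mu
        self.p_ext = p_ext
        self.vessel_id = vessel_id
        if tau is None:
            # relaxation time making the relaxation-wave speed comparable to
            # the elastic celerity: tau = nu / c^2 at the reference state
            A0 = self.wall.A0
            c2 = np.maximum(A0 / rho * self.wall.dpdA(A0), 1e-12)
            nu = self.wall.gamma(A0) * A0 / rho
            self.tau = float(np.max(np.maximum(nu / c2, 1e-6)))
        else:
            self.tau = tau

    def celerity(self, A):
        """Elastic wave speed; ``A`` must be the full per-cell array."""
        return np.sqrt(np.maximum(A / self.rho * self.wall.dpdA(A), 0.0))

    def p_total(self, A, w):
        """Full luminal pressure (external + elastic + viscoelastic).

        ``A``/``w`` must be full per-cell arrays (the wall parameters are
        per-cell); for a single cell use :func:`cell_pressure`.
        """
        return self.p_ext + self.wall.p_elastic(A) + self.wall.gamma(A) * w


def n_cells_for(length: float, dx_c: float = DX_CHARACTERISTIC) -> int:
    """Number of cells at characteristic spacing; never fewer than one."""
    return max(1, round(length / dx_c))


def build_grid(vessel: Vessel, fluid: mech.FluidParams,
               arterial_rules: mech.ArterialParamRules | None = None,
               venous_rules: mech.VenousParamRules | None = None,
               n_cells: int | None = None) -> VesselGrid:
    """Grid for a network vessel: per-cell wall parameters at the cell-centre
    radius of the linear taper; venous stiffness from the midpoint radius."""
    arterial_rules = arterial_rules or mech.ArterialParamRules()
    venous_rules = venous_rules or mech.VenousParamRules()
    n = n_cells or n_cells_for(vessel.length)
    s = (np.arange(n) + 0.5) / n
    radii = vessel.radius_at(s)
    if vessel.is_arterial:
        walls = [mech.make_arterial_wall(float(r), arterial_rules) for r in radii]
        wall = ArterialWallField(walls)
    else:
        r_mid = float(vessel.radius_at(0.5))
        dural = vessel.vessel_class is VesselClass.DURAL_SINUS
        walls = [mech.make_venous_wall(float(r), r_mid, venous_rules, fluid.rho,
                                       dural_sinus=dural) for r in radii]
        wall = VenousWallField(walls)
    mu = fluid.mu_perforator if vessel.vessel_class is VesselClass.PERFORATOR else fluid.mu
    return VesselGrid(wall, vessel.length, fluid.rho, mu, vessel_id=vessel.id)


@dataclass
class VesselState:
    A: np.ndarray
    q: np.ndarray
    w: np.ndarray
    t: float = 0.0

    def copy(self):
        return VesselState(self.A.copy(), self.q.copy(), self.w.copy(), self.t)


def quiescent_state(grid: VesselGrid, p_tm: float | None = None) -> VesselState:
    """State at rest: q = 0, w = 0, A at the reference (or given) pressure."""
    if p_tm is None:
        A = grid.wall.A0.copy()
    else:
        A = np.array([area_at_pressure(grid, p_tm, i)
                      for i in range(grid.n_cells)])
    z = np.zeros(grid.n_cells)
    return VesselState(A=A, q=z.copy(), w=z.copy())


def area_at_pressure(grid: VesselGrid, p_tm: float, cell: int) -> float:
    """Invert the cell's elastic tube law (bisection; both laws monotone)."""
    A0 = grid.wall.A0[cell]
    lo, hi = 1e-8 * A0, 4.0 * A0

    def f(a):
        arr = np.full(grid.n_cells, np.nan)
        arr[cell] = a
        return float(grid.wall.p_elastic(np.where(np.isnan(arr), A0, arr))[cell])

    while f(hi) < p_tm:
        hi *= 2.0
        if hi > 1e6 * A0:
            raise ValueError("pressure outside tube-law range")
    while f(lo) > p_tm:
        lo *= 0.5
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if f(mid) < p_tm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def total_volume(state: VesselState, grid: VesselGrid) -> float:
    return float(np.sum(state.A) * grid.dx)


# ---------------------------------------------------------------------------
# Time-step control
# ---------------------------------------------------------------------------

def max_wave_speed(state: VesselState, grid: VesselGrid) -> float:
    """Largest |eigenvalue| of the hyperbolized system over the cells."""
    A = state.A
    u = state.q / A
    c2 = A / grid.rho * grid.wall.dpdA(A)
    nu = grid.wall.gamma(A) * A / grid.rho
    lam = np.abs(u) + np.sqrt(np.maximum(c2 + nu / grid.tau, 0.0))
    m = float(np.max(lam))
    if not np.isfinite(m):
        raise ValueError(f"non-finite wave speed in vessel {grid.vessel_id}")
    return m


def max_stable_dt(state: VesselState, grid: VesselGrid,
                  cfg: SolverConfig) -> float:
    return min(cfg.dt_max, cfg.CFL * grid.dx / max_wave_speed(state, grid))


def local_time_step_schedule(stable_dt: dict, pairs: list,
                             dt_max: float = 1.0e-3) -> tuple[float, dict]:
    """Per-vessel substep schedule synchronizing at a common macro step.

    ``stable_dt`` maps vessel id -> its CFL-stable dt; ``pairs`` lists
    (up, down) vessel ids joined by a valve or Starling resistor, whose time
    steps are forced equal. The macro step is the largest stable dt (capped
    at dt_max); each vessel takes n_k = ceil(macro/stable_k) equal substeps,
    so all vessels meet at every macro synchronization time with an integer
    substep ratio.

    Returns (macro_dt, {vessel id: (n_substeps, dt)}).
    """
    macro = min(dt_max, max(stable_dt.values()))
    n = {vid: max(1, math.ceil(macro / dt - 1e-12))
         for vid, dt in stable_dt.items()}
    for up, down in pairs:
        m = max(n[up], n[down])
        n[up] = n[down] = m
    return macro, {vid: (nk, macro / nk) for vid, nk in n.items()}


# ---------------------------------------------------------------------------
# Reconstruction and advance
# ---------------------------------------------------------------------------

def _limited_slope(dl, dr, limiter: str):
    if limiter == "zero":
        return np.zeros_like(dl)
    if limiter == "central":
        return 0.5 * (dl + dr)
    if limiter == "minmod":
        s = np.where((dl > 0) & (dr > 0), np.minimum(dl, dr), 0.0)
        return np.where((dl < 0) & (dr < 0), np.maximum(dl, dr), s)
    if limiter == "mc":
        central = 0.5 * (dl + dr)
        lim = np.minimum(np.abs(central),
                         np.minimum(2 * np.abs(dl), 2 * np.abs(dr)))
        return np.where(dl * dr > 0, np.sign(central) * lim, 0.0)
    raise ValueError(limiter)


def advance(state: VesselState, grid: VesselGrid, dt: float,
            bc_left: tuple, bc_right: tuple,
            cfg: SolverConfig = SolverConfig()) -> VesselState:
    """One step of the well-balanced second-order scheme.

    ``bc_left``/``bc_right`` are boundary star states (A*, q*) solved by the
    coupling layer (or reflective walls). Raises on negative area beyond the
    guard and on blatant CFL violation.
    """
    A, q, w = state.A, state.q, state.w
    wall, rho, dx, tau = grid.wall, grid.rho, grid.dx, grid.tau * cfg.tau_scale
    n = grid.n_cells

    gam = wall.gamma(A)
    dgam = wall.dgamma(A)
    p = wall.p_elastic(A) + gam * w     # transmural (p_ext uniform in x)
    dpdA = wall.dpdA(A)
    u = q / A

    AL, qL = bc_left
    AR, qR = bc_right
    # ghost values carry the adjacent cell's wall parameters and w
    pL = float(wall.p_elastic(np.concatenate(([AL], A[1:])))[0] + gam[0] * w[0])
    pR = float(wall.p_elastic(np.concatenate((A[:-1], [AR])))[-1] + gam[-1] * w[-1])

    # --- slopes in (p, q, w), converted to A ---
    if cfg.order == 2 and n > 1:
        pe = np.concatenate(([pL], p, [pR]))
        qe = np.concatenate(([qL], q, [qR]))
        we = np.concatenate(([w[0]], w, [w[-1]]))
        sp = _limited_slope(pe[1:-1] - pe[:-2], pe[2:] - pe[1:-1], cfg.limiter) / dx
        sq = _limited_slope(qe[1:-1] - qe[:-2], qe[2:] - qe[1:-1], cfg.limiter) / dx
        sw = _limited_slope(we[1:-1] - we[:-2], we[2:] - we[1:-1], cfg.limiter) / dx
        denom = dpdA + dgam * w
        sA = np.where(denom > 1e-30, (sp - gam * sw) / np.where(denom > 1e-30, denom, 1.0), 0.0)
    else:
        sp = sq = sw = sA = np.zeros(n)

    # --- cell-local half-time evolution (predictor) ---
    fric = 8.0 * math.pi * grid.mu * q / (rho * A)
    dq_dt = -(2.0 * u * sq - u * u * sA) - (A / rho) * sp - fric
    dA_dt = -sq
    h = 0.5 * dt
    rel = 1.0 / (1.0 + h / tau)

    def half(X, sX, dX_dt):
        lo = (X - 0.5 * dx * sX) + h * dX_dt
        hi = (X + 0.5 * dx * sX) + h * dX_dt
        return lo, hi

    A_lo, A_hi = half(A, sA, dA_dt)
    q_lo, q_hi = half(q, sq, dq_dt)
    w_lo = ((w - 0.5 * dx * sw) - h * sq / tau) * rel
    w_hi = ((w + 0.5 * dx * sw) - h * sq / tau) * rel
    A_lo = np.maximum(A_lo, cfg.area_floor * wall.A0)
    A_hi = np.maximum(A_hi, cfg.area_floor * wall.A0)
    A_mid = np.maximum(A + h * dA_dt, cfg.area_floor * wall.A0)
    q_mid = q + h * dq_dt
    w_mid = (w - h * sq / tau) * rel

    # CFL sanity (the schedule is frozen; a gross violation means the state
    # left the regime the schedule was sized for)
    lam_cells = np.abs(u) + np.sqrt(np.maximum(
        A / rho * dpdA + gam * A / (rho * tau), 0.0))
    if float(np.max(lam_cells)) * dt / dx > 1.2:
        raise ValueError(
            f"vessel {grid.vessel_id}: CFL violation "
            f"(lambda dt/dx = {float(np.max(lam_cells)) * dt / dx:.2f})")

    # --- interface fluctuations (interior) ---
    # left side of interface i+1/2 is cell i's high edge, right side is
    # cell i+1's low edge; each side evaluated with its own cell parameters
    aL, aR = A_hi[:-1], A_lo[1:]
    qLl, qRr = q_hi[:-1], q_lo[1:]
    wLl, wRr = w_hi[:-1], w_lo[1:]
    pL_side = _p_side(wall, aL, wLl, np.arange(n - 1))
    pR_side = _p_side(wall, aR, wRr, np.arange(1, n))

    dF_A = qRr - qLl
    dF_q = qRr ** 2 / aR - qLl ** 2 / aL
    dF_w = (qRr - qLl) / tau
    Abar = 0.5 * (aL + aR)
    noncons_q = Abar / rho * (pR_side - pL_side)

    cL2 = _dpdA_side(wall, aL, np.arange(n - 1))
    cR2 = _dpdA_side(wall, aR, np.arange(1, n))
    pbarA = 0.5 * (cL2 + cR2)
    gbar = 0.5 * (_gamma_side(wall, aL, np.arange(n - 1))
                  + _gamma_side(wall, aR, np.arange(1, n)))
    dA_eff = (pR_side - pL_side - gbar * (wRr - wLl)) / np.maximum(pbarA, 1e-30)
    dq_j = qRr - qLl
    dw_j = wRr - wLl

    lamL = np.abs(qLl / aL) + np.sqrt(np.maximum(
        aL / rho * cL2 + _gamma_side(wall, aL, np.arange(n - 1)) * aL / (rho * tau), 0))
    lamR = np.abs(qRr / aR) + np.sqrt(np.maximum(
        aR / rho * cR2 + _gamma_side(wall, aR, np.arange(1, n)) * aR / (rho * tau), 0))
    s = np.maximum(lamL, lamR)

    Dtot_A, Dtot_q, Dtot_w = dF_A, dF_q + noncons_q, dF_w
    Dm_A = 0.5 * Dtot_A - 0.5 * s * dA_eff
    Dm_q = 0.5 * Dtot_q - 0.5 * s * dq_j
    Dm_w = 0.5 * Dtot_w - 0.5 * s * dw_j
    Dp_A = Dtot_A - Dm_A
    Dp_q = Dtot_q - Dm_q
    Dp_w = Dtot_w - Dm_w

    # --- boundary fluctuations: full fluctuation to the interior cell ---
    # left boundary: (A*, q*, w_0) -> cell 0 low edge
    p_star_L = _p_side(wall, np.array([AL]), np.array([w[0]]), np.array([0]))[0]
    p_edge_L = _p_side(wall, np.array([A_lo[0]]), np.array([w_lo[0]]), np.array([0]))[0]
    BL_A = q_lo[0] - qL
    BL_q = q_lo[0] ** 2 / A_lo[0] - qL ** 2 / AL \
        + 0.5 * (AL + A_lo[0]) / rho * (p_edge_L - p_star_L)
    BL_w = (q_lo[0] - qL) / tau
    # right boundary: cell n-1 high edge -> (A*, q*, w_{n-1})
    idx_last = np.array([n - 1])
    p_star_R = _p_side(wall, np.array([AR]), np.array([w[-1]]), idx_last)[0]
    p_edge_R = _p_side(wall, np.array([A_hi[-1]]), np.array([w_hi[-1]]), idx_last)[0]
    BR_A = qR - q_hi[-1]
    BR_q = qR ** 2 / AR - q_hi[-1] ** 2 / A_hi[-1] \
        + 0.5 * (AR + A_hi[-1]) / rho * (p_star_R - p_edge_R)
    BR_w = (qR - q_hi[-1]) / tau

    # --- assemble update ---
    upd_A = np.zeros(n)
    upd_q = np.zeros(n)
    upd_w = np.zeros(n)
    upd_A[0] += BL_A
    upd_q[0] += BL_q
    upd_w[0] += BL_w
    upd_A[-1] += BR_A
    upd_q[-1] += BR_q
    upd_w[-1] += BR_w
    if n > 1:
        upd_A[:-1] += Dm_A
        upd_q[:-1] += Dm_q
        upd_w[:-1] += Dm_w
        upd_A[1:] += Dp_A
        upd_q[1:] += Dp_q
        upd_w[1:] += Dp_w

    # in-cell smooth terms (flux difference between the cell's own half-time
    # edge states plus the midpoint-rule non-conservative pressure integral)
    cells = np.arange(n)
    p_lo_c = _p_side(wall, A_lo, w_lo, cells)
    p_hi_c = _p_side(wall, A_hi, w_hi, cells)
    upd_A += q_hi - q_lo
    upd_q += (q_hi ** 2 / A_hi - q_lo ** 2 / A_lo) \
        + A_mid / rho * (p_hi_c - p_lo_c)
    upd_w += (q_hi - q_lo) / tau

    fric_mid = 8.0 * math.pi * grid.mu * q_mid / (rho * A_mid)

    A_new = A - dt / dx * upd_A
    q_new = q - dt / dx * upd_q - dt * fric_mid
    w_star = w - dt / dx * upd_w
    w_new = w_star / (1.0 + dt / tau)

    bad = A_new <= cfg.area_floor * wall.A0
    if np.any(bad):
        idx = np.where(bad)[0]
        log.warning("vessel %s: area floored in cells %s",
                    grid.vessel_id, idx.tolist())
        A_new = np.maximum(A_new, cfg.area_floor * wall.A0)
    if not (np.all(np.isfinite(A_new)) and np.all(np.isfinite(q_new))):
        raise FloatingPointError(
            f"vessel {grid.vessel_id}: non-finite state after update")
    return VesselState(A=A_new, q=q_new, w=w_new, t=state.t + dt)


def _p_side(wall, A_vals, w_vals, idx):
    """Elastic+viscoelastic pressure of edge states using cell idx params."""
    if wall.is_arterial:
        A0 = wall.A0[idx]
        eps = A_vals / A0 - 1.0
        chi = (eps - wall.eps0[idx]) / wall.eps_r[idx]
        val = wall.Ee[idx] * eps + wall.Ec[idx] * wall.eps_r[idx] * np.logaddexp(0.0, chi)
        pe = wall.piR0h0[idx] / A_vals * val + wall.p0[idx]
        gam = 0.5 * wall.Km[idx] * np.sqrt(A_vals) / A0
    else:
        A0 = wall.A0[idx]
        r = A_vals / A0
        pe = wall.K[idx] * (r ** wall.m[idx] - r ** wall.n[idx]) + wall.p0[idx]
        gam = wall.Km[idx] * A0 / A_vals
    return pe + gam * w_vals


def _dpdA_side(wall, A_vals, idx):
    if wall.is_arterial:
        A0 = wall.A0[idx]
        eps = A_vals / A0 - 1.0
        chi = (eps - wall.eps0[idx]) / wall.eps_r[idx]
        sig = 1.0 / (1.0 + np.exp(-chi))
        val = wall.Ee[idx] * eps + wall.Ec[idx] * wall.eps_r[idx] * np.logaddexp(0.0, chi)
        dval = (wall.Ee[idx] + wall.Ec[idx] * sig) / A0
        return wall.piR0h0[idx] * (dval / A_vals - val / A_vals ** 2)
    A0 = wall.A0[idx]
    r = A_vals / A0
    return wall.K[idx] * (wall.m[idx] * r ** (wall.m[idx] - 1.0)
                          - wall.n[idx] * r ** (wall.n[idx] - 1.0)) / A0


def _gamma_side(wall, A_vals, idx):
    if wall.is_arterial:
        return 0.5 * wall.Km[idx] * np.sqrt(A_vals) / wall.A0[idx]
    return wall.Km[idx] * wall.A0[idx] / A_vals


def cell_pressure(grid: VesselGrid, cell: int, A, w=0.0) -> np.ndarray:
    """Full pressure of trial state(s) A using cell's wall params and p_ext."""
    A = np.atleast_1d(np.asarray(A, dtype=float))
    wv = np.full_like(A, float(w))
    idx = np.full(A.shape, cell, dtype=int)
    return _p_side(grid.wall, A, wv, idx) + grid.p_ext


def cell_dpdA(grid: VesselGrid, cell: int, A) -> np.ndarray:
    A = np.atleast_1d(np.asarray(A, dtype=float))
    idx = np.full(A.shape, cell, dtype=int)
    return _dpdA_side(grid.wall, A, idx)


def cell_dgamma(grid: VesselGrid, cell: int, A) -> np.ndarray:
    A = np.atleast_1d(np.asarray(A, dtype=float))
    w = grid.wall
    if w.is_arterial:
        return 0.25 * w.Km[cell] / (w.A0[cell] * np.sqrt(A))
    return -w.Km[cell] * w.A0[cell] / A ** 2


def cell_celerity(grid: VesselGrid, cell: int, A) -> np.ndarray:
    A = np.atleast_1d(np.asarray(A, dtype=float))
    return np.sqrt(np.maximum(A / grid.rho * cell_dpdA(grid, cell, A), 0.0))


def reflective_bc(state: VesselState, side: str) -> tuple:
    """Closed-end boundary: mirror area, zero flow."""
    if side == "left":
        return (float(state.A[0]), 0.0)
    return (float(state.A[-1]), 0.0)


def transmissive_bc(state: VesselState, side: str) -> tuple:
    """Zero-gradient boundary (pulse leaves the domain)."""
    if side == "left":
        return (float(state.A[0]), float(state.q[0]))
    return (float(state.A[-1]), float(state.q[-1]))
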
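"""Nonlinear coupling at vessel junctions and at every 1D-0D interface.

All couplings share the same closure: each vessel end contributes its
outgoing generalized Riemann invariant

    W(+/-) = u -/+ Integral c(a)/a da

(the characteristic that leaves the vessel interior towards the boundary),
and the remaining equations enforce discrete mass conservation and
total-pressure continuity:

* junctions of N vessels: N invariants + (N-1) total-pressure equalities +
  1 mass balance, solved by Newton with an analytic Jacobian;
* terminal arteries: invariant + total-pressure drop R_a q across the
  proximal bed resistance;
* terminal veins: mirror image with the venular resistance R_v on the inlet
  side;
* caval veins / coronary sinus into the right atrium: invariant + total
  pressure equal to the atrial pressure;
* aortic root and valve/Starling-resistor vessel ends: prescribed element
  flow + invariant.

Dynamic pressure (rho u^2 / 2) is included on the 1D side of every coupling;
0D compartments carry static pressures only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

from .solver import (VesselGrid, VesselState, cell_celerity, cell_dgamma,
                     cell_dpdA, cell_pressure)

_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)

NEWTON_TOL = 1e-11   # scaled residual target (bound is 1e-10)
MAX_ITER = 60


class CouplingError(RuntimeError):
    pass


@dataclass
class BoundaryEnd:
    """One vessel end participating in a coupling.

    ``g`` is the junction orientation flag: +1 when the vessel's distal
    (outlet) end meets the node, -1 for the proximal (inlet) end.
    """

    grid: VesselGrid
    state: VesselState
    g: int                     # +1 distal end, -1 proximal end

    def __post_init__(self):
        self.cell = self.grid.n_cells - 1 if self.g == +1 else 0
        self.A_in = float(self.state.A[self.cell])
        self.u_in = float(self.state.q[self.cell] / self.state.A[self.cell])
        self.w_b = float(self.state.w[self.cell])

    def invariant_integral(self, A_star: float) -> float:
        """Integral of c(a)/a from the interior state A_in to A_star."""
        a, b = self.A_in, float(A_star)
        if a == b:
            return 0.0
        x = 0.5 * (b - a) * _GL_X + 0.5 * (a + b)
        c = cell_celerity(self.grid, self.cell, x)
        return float(0.5 * (b - a) * np.sum(_GL_W * c / x))

    def u_star(self, A_star: float) -> float:
        """Boundary velocity from the outgoing Riemann invariant."""
        return self.u_in - self.g * self.invariant_integral(A_star)

    def du_star_dA(self, A_star: float) -> float:
        return -self.g * float(cell_celerity(self.grid, self.cell, A_star)[0]) / A_star

    def pressure(self, A_star: float) -> float:
        return float(cell_pressure(self.grid, self.cell, A_star, self.w_b)[0])

    def dpdA(self, A_star: float) -> float:
        return float(cell_dpdA(self.grid, self.cell, A_star)[0]) \
            + float(cell_dgamma(self.grid, self.cell, A_star)[0]) * self.w_b

    def total_pressure(self, A_star: float) -> float:
        u = self.u_star(A_star)
        return self.pressure(A_star) + 0.5 * self.grid.rho * u * u

    def admissible(self, A_star: float) -> bool:
        c = float(cell_celerity(self.grid, self.cell, A_star)[0])
        return abs(self.u_star(A_star)) < c


# ---------------------------------------------------------------------------
# Junction solve
# ---------------------------------------------------------------------------

@dataclass
class JunctionResult:
    A: list
    q: list
    mass_residual: float
    pressure_spread: float
    iterations: int


def solve_junction(ends: list[BoundaryEnd], tol: float = NEWTON_TOL,
                   label: str = "junction") -> JunctionResult:
    """Boundary states at a junction of N >= 2 vessel ends.

    Enforces sum g_k q_k* = 0 and equality of total pressure across members,
    with each member's outgoing Riemann invariant preserved. Newton with
    analytic Jacobian and residual-halving damping.
    """
    N = len(ends)
    A = np.array([e.A_in for e in ends])
    rho = ends[0].grid.rho
    # scales for the stopping test
    c_ref = np.array([float(cell_celerity(e.grid, e.cell, e.A_in)[0]) for e in ends])
    q_scale = max(float(np.max(A * c_ref)), 1e-30)
    p_scale = max(float(np.max(rho * c_ref ** 2)), 1e-30)

    def residual(Avec):
        u = np.array([e.u_star(Avec[k]) for k, e in enumerate(ends)])
        q = Avec * u
        ptot = np.array([ends[k].pressure(Avec[k]) + 0.5 * rho * u[k] ** 2
                         for k in range(N)])
        r = np.empty(N)
        r[0] = sum(e.g * q[k] for k, e in enumerate(ends)) / q_scale
        r[1:] = (ptot[0] - ptot[1:]) / p_scale
        return r, q, ptot

    def converged(r, q):
        # discrete conservation relative to the flows actually present,
        # with an absolute floor for quiescent junctions
        mass_ok = abs(r[0]) * q_scale <= max(1e-11 * np.max(np.abs(q)),
                                             1e-15 * q_scale)
        return mass_ok and np.max(np.abs(r[1:])) <= tol

    def jacobian(Avec):
        J = np.zeros((N, N))
        u = np.array([e.u_star(Avec[k]) for k, e in enumerate(ends)])
        for k, e in enumerate(ends):
            du = e.du_star_dA(Avec[k])
            dq = u[k] + Avec[k] * du
            J[0, k] = e.g * dq / q_scale
            dptot = e.dpdA(Avec[k]) + rho * u[k] * du
            if k == 0:
                J[1:, 0] = dptot / p_scale
            else:
                J[k, k] = -dptot / p_scale
        return J

    def subsonic(Avec):
        for k, e in enumerate(ends):
            c = float(cell_celerity(e.grid, e.cell, Avec[k])[0])
            if abs(e.u_star(Avec[k])) >= 0.98 * c:
                return False
        return True

    def newton(A, r, q, ptot):
        it = 0
        while not converged(r, q):
            it += 1
            if it > MAX_ITER:
                return A, r, q, ptot, it, np.max(np.abs(r)) < 1e-10
            try:
                step = np.linalg.solve(jacobian(A), -r)
            except np.linalg.LinAlgError:
                return A, r, q, ptot, it, False
            lam, base = 1.0, float(np.max(np.abs(r)))
            improved = False
            for _ in range(40):
                trial = A + lam * step
                # stay on the positive, subsonic branch: the closures have a
                # spurious supersonic root where the Jacobian misleads
                if np.all(trial > 1e-12) and subsonic(trial):
                    r_t, q_t, p_t = residual(trial)
                    if float(np.max(np.abs(r_t))) < base or lam < 1e-6:
                        A, r, q, ptot = trial, r_t, q_t, p_t
                        improved = True
                        break
                lam *= 0.5
            if not improved:
                return A, r, q, ptot, it, np.max(np.abs(r)) < 1e-10
        return A, r, q, ptot, it, True

    r, q, ptot = residual(A)
    A, r, q, ptot, it, ok = newton(A.copy(), r, q, ptot)
    if not ok:
        # fall back to a dense root-finder from the interior state
        from scipy.optimize import root as _root

        def rfun(Avec):
            return residual(np.maximum(Avec, 1e-12))[0]

        sol = _root(rfun, np.array([e.A_in for e in ends]), method="hybr",
                    options={"xtol": 1e-13})
        if sol.success:
            A = np.maximum(sol.x, 1e-12)
            r, q, ptot = residual(A)
        if not converged(r, q) and np.max(np.abs(r)) > 1e-8:
            raise CouplingError(
                f"{label}: Newton failed (residual {np.max(np.abs(r)):.2e})")
    # relative to the larger of the actual total pressures and the wave
    # pressure scale rho c^2 (total pressure itself crosses zero in
    # collapsed veins and cannot serve as a denominator there)
    spread = float(np.max(ptot) - np.min(ptot)) \
        / max(float(np.max(np.abs(ptot))), p_scale, 1e-30)
    # project the flows onto the mass-conservation hyperplane: the residual
    # left by the Newton tolerance (~1e-12 scaled) is redistributed equally,
    # so discrete conservation holds to rounding at every junction instant
    g = np.array([e.g for e in ends], dtype=float)
    q = np.asarray(q, dtype=float)
    q -= g * float(np.dot(g, q)) / N
    mass = float(np.dot(g, q))
    return JunctionResult(A=list(A), q=list(q), mass_residual=mass,
                          pressure_spread=spread, iterations=it)


# ---------------------------------------------------------------------------
# Scalar couplings (terminals, atrium, prescribed flow)
# ---------------------------------------------------------------------------

def _solve_scalar(end: BoundaryEnd, f, df, label: str, tol: float = NEWTON_TOL):
    """Newton with expanding-bracket bisection fallback on a scalar residual
    f(A*) (scaled by caller); returns A*."""
    A = end.A_in
    val = f(A)
    it = 0
    while abs(val) > tol:
        it += 1
        if it > MAX_ITER:
            break
        d = df(A)
        if d == 0.0 or not np.isfinite(d):
            break
        step = -val / d
        lam = 1.0
        improved = False
        for _ in range(40):
            trial = A + lam * step
            if trial > 1e-12:
                v_t = f(trial)
                if abs(v_t) < abs(val) or lam < 1e-6:
                    A, val = trial, v_t
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            break
    if abs(val) <= tol:
        return A
    # bisection fallback on an expanding bracket around the interior area
    lo, hi = 0.25 * end.A_in, 4.0 * end.A_in
    flo, fhi = f(lo), f(hi)
    tries = 0
    while flo * fhi > 0 and tries < 40:
        lo *= 0.7
        hi *= 1.3
        flo, fhi = f(lo), f(hi)
        tries += 1
    if flo * fhi > 0:
        # no root on this branch (transient choking): take the least-bad
        # admissible state; the subsonic clamp downstream bounds the flow
        scan = np.geomspace(0.05 * end.A_in, 6.0 * end.A_in, 240)
        vals = np.array([abs(f(a)) for a in scan])
        A_best = float(scan[int(np.argmin(vals))])
        log.warning("%s: no root for scalar coupling, using closest state "
                    "(|residual| %.3g)", label, float(np.min(vals)))
        return A_best
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tol:
            return mid
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


SONIC_FRACTION = 0.95


def _admissible(end: BoundaryEnd, A: float) -> tuple:
    """Clamp a scalar-coupling solution to the subsonic branch.

    The total-pressure closures admit a second, supersonic root; if the
    solver lands there (possible during violent startup transients), the
    boundary state is pulled back to the choked-flow point |u*| =
    SONIC_FRACTION * c, the physical flow limit of the characteristic.
    """
    def ok(a):
        u = end.u_star(a)
        c = float(cell_celerity(end.grid, end.cell, a)[0])
        return abs(u) < SONIC_FRACTION * c

    if ok(A):
        return A, A * end.u_star(A)
    # bisect toward the interior state, which is subsonic in any state the
    # solver has accepted; land just inside the admissible side
    b = end.A_in
    if not ok(b):
        c_b = float(cell_celerity(end.grid, end.cell, b)[0])
        u_b = end.u_star(b)
        q = b * math.copysign(SONIC_FRACTION * c_b, u_b)
        log.warning("vessel %s: interior state near sonic; flow clamped",
                    end.grid.vessel_id)
        return b, q
    a = A
    for _ in range(80):
        mid = 0.5 * (a + b)
        if ok(mid):
            b = mid
        else:
            a = mid
    log.warning("vessel %s: boundary state choked at the sonic limit",
                end.grid.vessel_id)
    return b, b * end.u_star(b)


def couple_terminal_artery(end: BoundaryEnd, p_bed: float, R_a: float):
    """Terminal-artery outlet into its arteriolar compartment through R_a.

    Total-pressure continuity across the resistance:
    p* + rho u*^2/2 - p_bed = R_a q*. Returns (A*, q*).
    """
    rho = end.grid.rho
    p_scale = max(rho * float(cell_celerity(end.grid, end.cell, end.A_in)[0]) ** 2, 1.0)

    def f(A):
        u = end.u_star(A)
        return (end.pressure(A) + 0.5 * rho * u * u - p_bed - R_a * A * u) / p_scale

    def df(A):
        u = end.u_star(A)
        du = end.du_star_dA(A)
        return (end.dpdA(A) + rho * u * du - R_a * (u + A * du)) / p_scale

    A = _solve_scalar(end, f, df, f"terminal artery {end.grid.vessel_id}")
    return _admissible(end, A)


def couple_terminal_vein(end: BoundaryEnd, p_bed: float, R_v: float):
    """Terminal-vein inlet fed by its venular compartment through R_v.

    p_bed - R_v q* = p* + rho u*^2/2 (momentum balance across the inlet
    resistance, dynamic pressure on the 1D side). Returns (A*, q*)."""
    rho = end.grid.rho
    p_scale = max(rho * float(cell_celerity(end.grid, end.cell, end.A_in)[0]) ** 2, 1.0)

    def f(A):
        u = end.u_star(A)
        return (p_bed - R_v * A * u - end.pressure(A) - 0.5 * rho * u * u) / p_scale

    def df(A):
        u = end.u_star(A)
        du = end.du_star_dA(A)
        return (-R_v * (u + A * du) - end.dpdA(A) - rho * u * du) / p_scale

    A = _solve_scalar(end, f, df, f"terminal vein {end.grid.vessel_id}")
    return _admissible(end, A)


def couple_pressure_outlet(end: BoundaryEnd, p_target: float):
    """Vessel end whose total pressure is pinned to a 0D pressure (caval
    veins and coronary sinus at the right atrium; test reservoirs)."""
    rho = end.grid.rho
    p_scale = max(rho * float(cell_celerity(end.grid, end.cell, end.A_in)[0]) ** 2, 1.0)

    def f(A):
        u = end.u_star(A)
        return (end.pressure(A) + 0.5 * rho * u * u - p_target) / p_scale

    def df(A):
        u = end.u_star(A)
        return (end.dpdA(A) + rho * u * end.du_star_dA(A)) / p_scale

    A = _solve_scalar(end, f, df, f"pressure outlet {end.grid.vessel_id}")
    return _admissible(end, A)


def couple_prescribed_flow(end: BoundaryEnd, q_set: float):
    """Vessel end with element-prescribed flow (aortic valve, venous valve,
    Starling resistor): solve the invariant for A* given q* = q_set.

    If the demanded flow exceeds what the vessel's characteristics can
    supply (no admissible state), the flow is pulled back toward the
    interior flow until a state exists; this guard only engages during
    violent transients and is logged.
    """

    def make_fdf(qs):
        scale = max(abs(end.u_in) + 1.0, 1.0)

        def f(A):
            return (qs / A - end.u_star(A)) / scale

        def df(A):
            return (-qs / A ** 2 - end.du_star_dA(A)) / scale
        return f, df

    label = f"prescribed flow {end.grid.vessel_id}"
    try:
        f, df = make_fdf(q_set)
        return _solve_scalar(end, f, df, label), q_set
    except CouplingError:
        q_int = end.A_in * end.u_in
        frac = 0.5
        for _ in range(12):
            q_try = q_int + frac * (q_set - q_int)
            try:
                f, df = make_fdf(q_try)
                A = _solve_scalar(end, f, df, label)
                log.warning("%s: demanded flow %.3g unreachable, clamped to %.3g",
                            label, q_set, q_try)
                return A, q_try
            except CouplingError:
                frac *= 0.5
        raise
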
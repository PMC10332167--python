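"""Vessel wall mechanics: tube laws, celerities and wall-parameter derivation.

All quantities are CGS (cm, g, s, dyn); pressures in dyn/cm^2.

Two tube laws close the 1D blood-flow equations:

* arteries -- a mixture-theory law combining elastin (linear in strain) and
  collagen (recruited progressively, log-sigmoid in strain), plus a
  viscoelastic rate term;
* veins / dural sinuses -- a collapsible-tube power law
  ``K[(A/A0)^m - (A/A0)^n]`` whose exponents control passive stiffening (m)
  and collapse behaviour (n), plus a viscoelastic rate term.

Per-vessel wall parameters are not free: they are derived from the reference
radius through the rules implemented at the bottom of this module (radius
groups and constituent weights for arteries, a celerity-radius relation for
veins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

MMHG = 1333.22  # dyn/cm^2 per mmHg
ML_PER_MMHG = 1.0 / MMHG  # cm^5/dyn per (mL/mmHg)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluidParams:
    """Blood properties. Newtonian; perforators use a lower viscosity."""

    rho: float = 1.04        # g/cm^3
    mu: float = 0.04         # P
    mu_perforator: float = 0.01  # P

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0 or self.mu_perforator <= 0:
            raise ValueError("fluid parameters must be positive")


@dataclass(frozen=True)
class ArterialWallParams:
    """Per-cell arterial wall state parameters."""

    A0: float                # cm^2, reference area
    R0: float                # cm, reference radius
    h0: float                # cm, wall thickness
    Ee_eff: float            # dyn/cm^2, effective elastin modulus
    Ec_eff: float            # dyn/cm^2, effective collagen modulus
    Km: float                # dyn s/cm^2, effective viscoelastic coefficient
    p0: float = 1.0e5        # dyn/cm^2, reference transmural pressure
    eps0: float = 0.25       # strain at 50% collagen recruitment
    eps_r: float = 0.05      # spread of the recruitment distribution

    def __post_init__(self):
        if self.A0 <= 0 or self.h0 <= 0 or self.eps_r <= 0:
            raise ValueError("A0, h0 and eps_r must be positive")


@dataclass(frozen=True)
class VenousWallParams:
    """Per-cell venous (or dural sinus) wall parameters."""

    A0: float                # cm^2
    K: float                 # dyn/cm^2, effective stiffness
    m: float = 10.0          # stiffening exponent
    n: float = -1.5          # collapse exponent
    Km: float = 0.0          # dyn s/cm^2, viscoelastic coefficient
    p0: float = 6666.66      # dyn/cm^2, reference transmural pressure

    def __post_init__(self):
        if self.A0 <= 0 or self.K <= 0:
            raise ValueError("A0 and K must be positive")
        if self.m <= self.n:
            raise ValueError("require m > n")


DURAL_SINUS_EXPONENTS = (0.5, 0.0)
VEIN_EXPONENTS = (10.0, -1.5)


@dataclass(frozen=True)
class ArterialParamRules:
    """Radius-group bounds, constituent weights and thickness constants.

    Group A: R0 > 0.18 cm; group B: 0.07 <= R0 <= 0.18; group C: R0 < 0.07.
    Weight columns (W_E, W_C, W_M) per group each sum to 1.
    """

    Ee: float = 4.0e6        # dyn/cm^2
    Ec: float = 1.0e9        # dyn/cm^2
    Km: float = 3.6e5        # dyn s/cm^2
    bound_AB: float = 0.18   # cm
    bound_BC: float = 0.07   # cm
    weights: dict = field(default_factory=lambda: {
        "A": {"E": 0.85, "C": 0.05, "M": 0.10},
        "B": {"E": 0.65, "C": 0.20, "M": 0.15},
        "C": {"E": 0.45, "C": 0.00, "M": 0.55},
    })
    # thickness-ratio constants: h0/R0 = a e^{b R0} + c e^{d R0}
    a: float = 0.2802
    b: float = -5.053        # 1/cm
    c: float = 0.1324
    d: float = -0.1114       # 1/cm
    thickness_is_ratio: bool = True
    p0: float = 1.0e5
    eps0: float = 0.25
    eps_r: float = 0.05


@dataclass(frozen=True)
class VenousParamRules:
    """Celerity-radius rule constants for venous stiffness derivation.

    ``c_min``/``c_max`` are not fixed by the underlying model description;
    the defaults are chosen as physiological venous wave speeds.
    """

    c_min: float = 100.0     # cm/s
    c_max: float = 400.0     # cm/s
    R_min: float = 0.08      # cm
    R_max: float = 0.80      # cm
    Khat: float = 708.98     # dyn s/cm^2 (viscoelastic radius rule constant)
    p0: float = 6666.66

    def __post_init__(self):
        if not (0 < self.c_min < self.c_max):
            raise ValueError("require 0 < c_min < c_max")
        if not (0 < self.R_min < self.R_max):
            raise ValueError("require 0 < R_min < R_max")


# ---------------------------------------------------------------------------
# Tube laws
# ---------------------------------------------------------------------------

def arterial_elastic_pressure(A, w: ArterialWallParams):
    """Elastic (rate-independent) part of the arterial transmural pressure."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("non-positive area")
    eps = A / w.A0 - 1.0
    chi = (eps - w.eps0) / w.eps_r
    wall = w.Ee_eff * eps + w.Ec_eff * w.eps_r * np.logaddexp(0.0, chi)
    return math.pi * w.R0 * w.h0 / A * wall + w.p0


def arterial_gamma(A, w: ArterialWallParams):
    """Viscoelastic coefficient Gamma(A): p_visc = Gamma * dA/dt."""
    A = np.asarray(A, dtype=float)
    return 0.5 * w.Km * np.sqrt(A) / w.A0


def arterial_pressure(A, dAdt, w: ArterialWallParams):
    """Full arterial transmural pressure p_tm(A, dA/dt)."""
    return arterial_elastic_pressure(A, w) + arterial_gamma(A, w) * np.asarray(dAdt, float)


def arterial_dpdA(A, w: ArterialWallParams):
    """d p_elastic / dA (analytic)."""
    A = np.asarray(A, dtype=float)
    eps = A / w.A0 - 1.0
    chi = (eps - w.eps0) / w.eps_r
    sig = 1.0 / (1.0 + np.exp(-chi))
    wall = w.Ee_eff * eps + w.Ec_eff * w.eps_r * np.logaddexp(0.0, chi)
    dwall = (w.Ee_eff + w.Ec_eff * sig) / w.A0
    return math.pi * w.R0 * w.h0 * (dwall / A - wall / A ** 2)


def venous_elastic_pressure(A, w: VenousWallParams):
    """Elastic part of the venous transmural pressure (collapsible-tube law)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("non-positive area")
    r = A / w.A0
    return w.K * (r ** w.m - r ** w.n) + w.p0


def venous_gamma(A, w: VenousWallParams):
    A = np.asarray(A, dtype=float)
    return w.Km * w.A0 / A


def venous_pressure(A, dAdt, w: VenousWallParams):
    return venous_elastic_pressure(A, w) + venous_gamma(A, w) * np.asarray(dAdt, float)


def venous_dpdA(A, w: VenousWallParams):
    A = np.asarray(A, dtype=float)
    r = A / w.A0
    return w.K * (w.m * r ** (w.m - 1.0) - w.n * r ** (w.n - 1.0)) / w.A0


def celerity(A, wall, rho: float):
    """Characteristic (elastic) wave speed c = sqrt(A/rho * dp/dA)."""
    if isinstance(wall, ArterialWallParams):
        dpdA = arterial_dpdA(A, wall)
    else:
        dpdA = venous_dpdA(A, wall)
    return np.sqrt(np.asarray(A, float) / rho * dpdA)


def elastic_pressure(A, wall):
    if isinstance(wall, ArterialWallParams):
        return arterial_elastic_pressure(A, wall)
    return venous_elastic_pressure(A, wall)


def gamma_coefficient(A, wall):
    if isinstance(wall, ArterialWallParams):
        return arterial_gamma(A, wall)
    return venous_gamma(A, wall)


def dpdA(A, wall):
    if isinstance(wall, ArterialWallParams):
        return arterial_dpdA(A, wall)
    return venous_dpdA(A, wall)


def invert_tube_law(p_target, wall, bracket=(1e-12, None)):
    """Area at which the elastic tube law gives ``p_target`` (scalar).

    Both laws are strictly increasing in A, so bisection is safe.
    """
    lo = bracket[0] * wall.A0 if bracket[0] < 1e-6 else bracket[0]
    lo = max(lo, 1e-12 * wall.A0)
    hi = bracket[1] if bracket[1] else 4.0 * wall.A0
    while float(elastic_pressure(hi, wall)) < p_target:
        hi *= 2.0
        if hi > 1e6 * wall.A0:
            raise ValueError("tube-law inversion failed to bracket")
    while float(elastic_pressure(lo, wall)) > p_target:
        lo *= 0.5
        if lo < 1e-15 * wall.A0:
            raise ValueError("tube-law inversion failed to bracket (low)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(elastic_pressure(mid, wall)) < p_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14 * wall.A0:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Arterial parameter derivation
# ---------------------------------------------------------------------------

def arterial_group(R0: float, rules: ArterialParamRules = ArterialParamRules()) -> str:
    """Radius group of an artery: 'A' (large), 'B' (medium) or 'C' (small)."""
    if R0 <= 0:
        raise ValueError("non-positive radius")
    if R0 > rules.bound_AB:
        return "A"
    if R0 >= rules.bound_BC:
        return "B"
    return "C"


def effective_wall_constants(group: str, rules: ArterialParamRules = ArterialParamRules()):
    """(Ee_eff, Ec_eff, Km_eff) from the mixture-theory weights."""
    w = rules.weights[group]
    return w["E"] * rules.Ee, w["C"] * rules.Ec, w["M"] * rules.Km


def wall_thickness(R0: float, rules: ArterialParamRules = ArterialParamRules()) -> float:
    """Arterial wall thickness h0(R0).

    The two-exponential formula is interpreted as the thickness-to-radius
    ratio by default (it yields ratios 0.12-0.35 over the physiological
    radius range); ``rules.thickness_is_ratio=False`` reads it as an
    absolute thickness.
    """
    if R0 <= 0:
        raise ValueError("non-positive radius")
    val = rules.a * math.exp(rules.b * R0) + rules.c * math.exp(rules.d * R0)
    return R0 * val if rules.thickness_is_ratio else val


def make_arterial_wall(R0: float, rules: ArterialParamRules = ArterialParamRules()) -> ArterialWallParams:
    """Assemble all per-cell arterial wall parameters from the radius."""
    g = arterial_group(R0, rules)
    Ee, Ec, Km = effective_wall_constants(g, rules)
    return ArterialWallParams(
        A0=math.pi * R0 ** 2, R0=R0, h0=wall_thickness(R0, rules),
        Ee_eff=Ee, Ec_eff=Ec, Km=Km,
        p0=rules.p0, eps0=rules.eps0, eps_r=rules.eps_r)


# ---------------------------------------------------------------------------
# Venous parameter derivation
# ---------------------------------------------------------------------------

def venous_celerity_and_stiffness(R0_mid: float, rules: VenousParamRules,
                                  rho: float, m: float, n: float):
    """(c, K) from the celerity-radius rule.

    c decreases from c_max at R_min to c_min at R_max with a square-root
    profile; K = rho c^2 / (m - n) so that the tube-law celerity at A0
    equals c exactly.
    """
    if R0_mid <= 0:
        raise ValueError("non-positive radius")
    Rhat = min(max(rules.R_min, R0_mid), rules.R_max)
    frac = (Rhat - rules.R_min) / (rules.R_max - rules.R_min)
    c = rules.c_max - (rules.c_max - rules.c_min) * math.sqrt(frac)
    K = rho * c ** 2 / (m - n)
    return c, K


def venous_viscoelastic(R0: float, rules: VenousParamRules = VenousParamRules()) -> float:
    """Venous viscoelastic coefficient Km = Khat / R0."""
    if R0 <= 0:
        raise ValueError("non-positive radius")
    return rules.Khat / R0


def make_venous_wall(R0: float, R0_mid: float, rules: VenousParamRules,
                     rho: float, dural_sinus: bool = False) -> VenousWallParams:
    """Assemble venous wall parameters at local radius R0.

    The stiffness K is derived from the celerity rule at the vessel-midpoint
    radius ``R0_mid`` (one K per vessel); A0 and Km use the local radius.
    """
    m, n = DURAL_SINUS_EXPONENTS if dural_sinus else VEIN_EXPONENTS
    _, K = venous_celerity_and_stiffness(R0_mid, rules, rho, m, n)
    return VenousWallParams(A0=math.pi * R0 ** 2, K=K, m=m, n=n,
                            Km=venous_viscoelastic(R0, rules), p0=rules.p0)


def with_km_scaled(wall, factor: float):
    """Copy of a wall-parameter set with the viscoelastic coefficient scaled."""
    return replace(wall, Km=wall.Km * factor)
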
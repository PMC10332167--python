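# Methods

`hemonet` simulates the closed human circulation as a network of 1D
compliant vessels (systemic arteries and veins) coupled to lumped (0D)
models of the heart, the cardiac valves, the pulmonary circulation, the
peripheral and coronary microcirculation, venous valves, Starling resistors
and the intracranial pressure. All internal quantities are CGS
(cm, g, s, dyn/cm²); 1 mmHg = 1333.22 dyn/cm².

## 1D blood flow and tube laws

Each vessel segment carries the cross-sectionally averaged equations

    A_t + q_x = 0
    q_t + (q²/A)_x + (A/ρ) p_x = −8πμ q/(ρA)

with a Poiseuille friction profile (μ = 0.04 P, 0.01 P in perforators;
ρ = 1.04 g/cm³). Luminal pressure is p = p_ext + p_tm, where p_ext is the
tissue/fluid pressure outside the vessel (the intracranial pressure for
tagged vessels, atmospheric zero otherwise) and p_tm the transmural
pressure carried by the wall:

* **Arteries** — a mixture law: p_tm = (πR₀h₀/A)[E_e ε + E_c ε_r ln(e^χ+1)]
  + Γ(A)·A_t + p₀, with strain ε = A/A₀ − 1, collagen recruitment variable
  χ = (ε − ε₀)/ε_r (ε₀ = 0.25, ε_r = 0.05), reference pressure
  p₀ = 10⁵ dyn/cm². Elastin responds linearly; collagen recruits through a
  soft-plus of χ, so the wall stiffens steeply above ~25% strain.
* **Veins and dural sinuses** — a collapsible-tube law
  p_tm = K[(A/A₀)^m − (A/A₀)^n] + Γ(A)·A_t + p₀ with p₀ = 6666.66 dyn/cm²
  (5 mmHg), (m, n) = (10, −3/2) for veins (stiffening/collapse) and
  (1/2, 0) for the stiffer dural sinuses.

The strain is read as ε = A/A₀ − 1 (the extracted source renders fractions
ambiguously; the same rendering pattern elsewhere fixes the thickness
formula as a ratio, see below, and the area-ratio reading is used
consistently).

Viscoelastic rate coefficients are taken exactly at the formulation's stated form:
Γ_art = (K_m/2)√A/A₀ and Γ_ven = K_m A₀/A. With the tabulated K_m values
these imply a very strong parabolic (diffusive) term; see the relaxation
discussion below.

### Per-vessel parameter derivation

Wall parameters are never free inputs; they derive from the reference
radius:

* arteries fall into radius groups A (R₀ > 0.18 cm), B (0.07–0.18) and
  C (< 0.07); mixture weights (W_E, W_C, W_M) per group scale the base
  moduli E_e = 4·10⁶, E_c = 10⁹ dyn/cm², K_m = 3.6·10⁵ dyn·s/cm²;
* wall thickness uses the two-exponential rule h₀/R₀ = a e^{bR₀} + c e^{dR₀}
  (a = 0.2802, b = −5.053 cm⁻¹, c = 0.1324, d = −0.1114 cm⁻¹), interpreted
  as a thickness-to-RADIUS ratio: the constants then give physiological
  ratios 0.12–0.35 across the radius range, whereas an absolute reading
  would exceed the radius itself for small vessels. A config flag restores
  the absolute reading.
* venous stiffness comes from a celerity-radius rule: c falls from c_max at
  R = 0.08 cm to c_min at R = 0.80 cm with a square-root profile, and
  K = ρc²/(m − n), which makes the tube-law wave speed at A₀ equal c
  exactly (unit-tested to 1e-10). c_min = 100 and c_max = 400 cm/s are
  free parameters of the rule; the defaults are **chosen** physiological
  venous wave speeds. The venous viscoelastic coefficient is K_m = 708.98/R₀.

Per-cell parameters are evaluated at the cell-centre radius of the linear
taper between the two tabulated end radii; the venous celerity rule uses
the vessel-midpoint radius.

## Numerical scheme (1D)

Cells are Δx ≈ 1 cm (vessels shorter than that get a single cell). The
viscoelastic rate term makes the system advection–diffusion; it is removed
by a relaxation variable w obeying w_t + (1/τ)q_x = −w/τ, which tends to
A_t in the stiff limit, with the pressure everywhere evaluated as
p_elastic + Γ·w. The relaxation time defaults to τ = ν/c² per vessel
(ν = ΓA/ρ at reference), which caps the relaxation wave speed near the
elastic celerity; the stiff source is integrated implicitly, so any τ is
stable and the w-update recovers the equilibrium w = −q_x exactly as
τ → 0. With the tabulated K_m magnitudes the strict parabolic limit would
demand wave speeds far above physiological celerities, so the default τ
trades exactness of the rate term for a bounded CFL; with K_m = 0 the
scheme reproduces the purely elastic solution bit-for-bit (tested).

One step of the finite-volume advance:

1. slope-limited reconstruction in (p, q, w) — reconstructing pressure
   rather than area is what makes the scheme **well-balanced**: a
   quiescent state with uniform total pressure has zero slopes and zero
   interface jumps however strongly A₀(x) and K(x) vary (held to ~1e-16
   over 10³ steps in the acceptance run). The default limiter is
   monotonized-central; measured L1 orders on a smooth pulse are
   2.19/2.19 across refinement pairs (minmod, also available, clips smooth
   extrema to ~1.8);
2. a cell-local ADER-type predictor evolves edge-extrapolated states to
   the half time (semi-implicit in the relaxation source);
3. path-conservative fluctuations: the non-conservative pressure term
   enters interfaces as (Ā/ρ)(p_R − p_L) and the Rusanov-type dissipation
   acts on the steady-state-preserving jump variables (Δp, Δq, Δw) rather
   than (ΔA, Δq, Δw). A full Osher-type path integral was not needed to
   meet the well-balance and order targets and was left out deliberately.

CFL = 0.9, Δt_max = 1 ms. Time steps are frozen at assembly (sized at
1.5× the reference-state wave speeds); a vessel whose state outruns that
sizing transiently gets its substeps refined (never coarsened) for the
affected macro steps, keeping runs deterministic.

**Local time stepping.** The macro (synchronization) step is the largest
stable per-vessel dt capped at Δt_max; each vessel takes
n_k = ceil(macro/stable_k) equal substeps, so all vessels meet at every
macro time with integer substep ratios. Vessel pairs joined by a venous
valve or Starling resistor are forced to a common dt. Boundary star states
are solved once per macro step and held over substeps, so the mass
exchanged with 0D elements is exactly q*·Δt (first-order in time at
interfaces, matching the explicit-Euler 0D integration).

## Junctions and 1D–0D coupling

All couplings combine each vessel end's outgoing generalized Riemann
invariant (u ∓ ∫c/a da, quadrature by 16-point Gauss–Legendre) with
conservation closures: N-member junctions enforce Σ g_k q_k = 0 and total
pressure continuity (energy-conserving); terminal arteries balance total
pressure against the bed pressure across R_a; terminal veins mirror this
with R_v; caval veins and the coronary sinus pin total pressure to the
right-atrial pressure; the aortic root and valve/Starling ends take the
element's flow. Dynamic pressure is carried on the 1D side only.

Newton with analytic Jacobians converges these to a scaled residual of
1e-11; converged junction flows are then projected onto the mass
hyperplane so discrete conservation holds to rounding at every instant.
The closures admit a spurious supersonic root; iterates are confined to
the subsonic branch, and if a transient demands more flow than the
characteristics can carry, the boundary state is clamped at the choked
(sonic) limit with a logged warning. Total-pressure spread is reported
relative to max(|p_tot|, ρc²), because total pressure itself crosses zero
in partially collapsed veins.

## Lumped elements

**Chambers.** Time-varying elastance with contraction/relaxation shape
g₁/(1+g₁)·1/(1+g₂), normalized per parameter set by dense sampling (10⁴
points/period) so the maximum equals E_max exactly. Chamber pressure
combines free-wall and septal elastances (harmonically), a flow-dependent
source resistance, the pericardial pressure (exponential in total cardiac
volume) and the contralateral chamber's pressure; the (LA, RA) and
(LV, RV) pairs are each solved as exact 2×2 linear systems per step.

**Valves.** Flow obeys L q̇ = Δp − B q|q| with B, L from an effective
orifice area interpolating between A_min and A_max with the opening state
ζ ∈ [0, 1]; ζ has separate opening/closing rate constants and a pressure
hysteresis band. A sealed valve's area is floored at 1e-6·A_max so B, L
stay finite. The quadratic drag is integrated semi-implicitly
(unconditionally stable for the enormous sealed-valve B); elements
adjacent to 1D vessels see the vessels' characteristic impedances as a
local linearization of the driving pressures, which suppresses the flow
overshoot of a naive explicit coupling and leaves steady states unbiased.

**Starling resistors** reuse the valve ODE but with a *fixed* orifice
(averaged from the adjacent segments): the state only blends the
downstream pressure with the external (intracranial) pressure,
p*_down = ζ p_down + (1−ζ) p_ext. Collapsed (ζ = 0), flow is driven by
p_up − p_ICP and is exactly independent of the sinus pressure — the
vascular waterfall (verified: <1e-12 % outflow change to a 10% downstream
drop when collapsed, 6.5% change when open). Venous valve constants
K_vo = 0.1, K_vc = 0.03; Starling constants K_so = K_sc = 0.01.

**Pulmonary.** Three CLR compartments (arteries, capillaries, veins) with
exponential pressure–volume laws, chained into the left atrium.

**Peripheral beds.** Each terminal artery feeds an RC arteriolar
compartment (R_a = 0.15 R_t, C from the network table); each
terminal vein drains a venular compartment; the two layers connect
many-to-many through capillary resistances splitting the equivalent
0.85 R_t by conductances proportional to the cubed radii of the draining
veins. Venular proximal resistances are the veins' characteristic
impedances ρc/Â. The residual systemic venous compliance
(C_v,data = 146 mL/mmHg minus the 1D venous compliance) is distributed
over extracranial, non-coronary venular compartments by
conductance-weighted feeder-compliance shares. **Intracranial venular
compartments get a small fixed compliance (1 mL/mmHg) instead**: placing
the flow-share (~12% of 146 mL/mmHg) inside the cranio-spinal cavity gives
the ICP feedback loop a gain k_ICP·C ≈ 3 per mmHg and it diverges
(verified on the fixture: ICP climbs to 50–100 mmHg and strangles cerebral
flow); small intracranial venous compliance is also what the Monro–Kellie
constraint implies.

**Coronary beds.** Each coronary arterio-venous connection carries a
three-layer (sub-epicardial/midwall/sub-endocardial) intramyocardial pump:
two volume compartments per layer whose resistances stiffen as
R = R₀(V₀/V)², squeezed by the intramyocardial pressure
p_im = CEP + SIP. CEP blends chamber and pericardial (or RV, for the
septum) pressures with layer weights 1/6, 1/2, 5/6. SIP is the stated
α·p_ch·(V_ch − V⁰_ch) with α = 8.2 carrying cm⁻³ — dimensionally
inconsistent as formulated, and numerically it exceeds tissue pressures a
thousandfold, which no closed-loop state survives; the engine therefore
clamps the SIP contribution to ±0.5·|p_ch| (configurable; `None` restores
the verbatim value). With the clamp, systolic sub-endocardial p_im ≈
1.3 p_LV and coronary flow shows the classic systolic impediment.
Reference volumes/compliances follow the perfusion constants
(η₁ = 2.5, η₂ = 8.0 cm³/100 g; κ₁ = 9.7501e-6, κ₂ = 1.905019e-4
cm⁵/dyn/100 g; ρ_myo = 1.05 g/cm³) applied to wall volumes partitioned by
cubed terminal radii; layer ratios 0.93/0.87 (volumes, to sub-endo),
0.6/0.2 (parallel layer resistances, to sub-epi) and 1.2/0.5 (series, to
the middle resistance), anchored to each connection's capillary
resistance.

**Intracranial pressure.** ṗ = k_ICP·p·(V̇_cbv + q_gen − q_abs) with
k_ICP = 0.15 mL⁻¹, generation balancing absorption, initial
p = 14665.42 dyn/cm² (11.0 mmHg); stepped on the Δt_max clock. V_cbv sums
intracranial 1D vessel volumes and cerebral bed compartment volumes.
Intracranial 1D vessels and cerebral compartments feel p_ICP as external
pressure; dural sinuses deliberately do not.

## Closed-loop operation

Initial state: every vessel at its reference area (q = 0), compartments at
their class reference *transmural* pressures (so cerebral compartments
start consistent with the ICP), chambers at plausible end-diastolic
volumes, pulmonary compartments near their working points. The total
stretched (stressed) volume — Σ(A − A(p_tm=0))Δx over 1D cells plus all 0D
stressed volumes — is measured at assembly and driven to the configured
set point by a constant-rate source over the first 3 s. The source feeds
the most compliant venular compartment (a neutral low-pressure site; the
right atrium cannot absorb fixture-scale corrections at hundreds of mL/s).
The config default set point is a whole-body literature value
(2273.643 cm³); fixture runs configure values near their own assembled
volume (the fixtures stand in for a thousands-of-vessels anatomy at ~1% of its
size, and their equilibria are their own).

A run advances whole cardiac cycles (period 0.9 s) until a configured
count or until the max-over-monitors relative L2 distance between
consecutive-cycle pressure traces falls below 1e-3 (the minimal fixture
reaches this within ~18 cycles).

Heart/valve/pericardium/pulmonary presets are plausible adult values in
the lineage of established elastance-heart models; they are not fitted to
any dataset and live in `lumped.default_*`.

## Fixtures (synthetic networks)

`build_fixture_network("minimal")` closes the loop through 4 vessels and
one peripheral bed; `"cerebral_coronary"` (14 vessels) adds a cerebral
branch (intracranial artery and vein, Starling resistor into a dural
sinus, jugular chain with one venous valve), a coronary perforator/vein
pair on an intramyocardial bed, a three-vessel venous confluence and a
many-to-many arterio-venous pattern (one artery feeding two veins, one
vein fed by two arteries). The seed perturbs radii by a few percent,
never topology. Calibers are sized so single serial pathways can carry
the full cardiac output: veins are vena-cava scale because at CVP ~2–4
mmHg the collapsible law puts them on the collapse branch, and a narrow
collapsed vein chokes (these fixtures concentrate flows that the real
anatomy spreads over hundreds of parallel vessels). What passing fixture
tests do **not** show: anatomically realistic wave reflection patterns,
regional flow distributions, or index values comparable to population
reference ranges — those require a full anatomical network of thousands
of vessels.

## Haemodynamic indexes and sensitivity

Cycle averages (MAP, CO, CVP, MPAP, mean ICP), extrema (SBP/DBP, pulse
pressures), LV stroke volume and ejection fraction from the volume trace,
end-systolic elastance and arterial elastance indexed by body surface area
(default 1.9 m²), pulse pressure amplification (brachial over aortic pulse
pressure), ankle-brachial index, and foot-to-foot pulse wave velocity with
the foot located by the intersecting-tangent method on the upstroke. The
index definitions follow standard clinical conventions.

Local sensitivity: S±(M, P) = 100·(M̂± − M̄)/M̄ from one-at-a-time ±10%
parameter perturbations (2|P| + 1 runs), ranked by |S|; failed perturbed
runs are excluded and reported.

## Known limitations

* The relaxation treatment of the viscoelastic term is exact only in the
  stiff limit, which the tabulated K_m magnitudes place beyond reachable
  wave speeds; the default τ yields a Maxwell-like lagged rate term.
* The SIP clamp bounds a dimensionally inconsistent expression; coronary flow levels are plausible but not source-exact.
* Boundary coupling is first-order in time; global conservation is still
  ~1e-4 %/cycle because boundary fluxes are star-state exact.
* No autoregulation, baroreflex, respiratory modulation or CSF imbalance.
* Choked-flow boundary states are clamped at the sonic limit rather than
  resolved with a full transonic Riemann analysis; the guard engages only
  in violent startup transients and logs when it does.
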
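# Methods

`lampsim` simulates steady anguilliform swimming as a closed sensorimotor
loop: a central pattern generator (CPG) built from phase oscillators
activates calcium-gated Hill-type muscle; muscle tension bends a
three-filament elastic body; the body exchanges force and velocity with a
2D viscous fluid; and the emergent midline curvature feeds back additively
into the oscillator dynamics.  This note records the model equations, the
parameter choices and their rationale, the numerical methods, and the known
limitations — in particular what the reduced desk-scale configuration does
and does not establish.

All internal units are cgs (cm, g, s, dyn); angles are radians.

## CPG

Two chains (left k = 1, right k = 2) of n phase oscillators:

    dθ_{k,i}/dt = ω + Σ_j α_{i,j} sin(θ_{k,j} − θ_{k,i} − ψ_{ij})
                  + α_c sin(θ_{k,i} − θ_{k*,i}) + η(κ_i),

with ω = 2π rad/s, ψ_{ij} = (i−j)·ψ̄, ψ̄ = 2π/n (one activation wave on the
chain), and distance-decaying asymmetric coupling

    α_{i,j} = A_a·exp(−|i−j|/λ_a)  (ascending, i < j),
              A_d·exp(−|i−j|/λ_d)  (descending, i > j),

A_a = 1, A_d = 10 rad/s, λ_a = 40, λ_d = 5 segments, α_{i,i} = 0.  The
contralateral strength α_c = 81.87 rad/s is ten times the strongest
descending connection.  Writing d = θ_1,i − θ_2,i, the contralateral pair
obeys dd/dt = 2α_c sin d + …, which makes the observed left–right
antiphase d = π a stable phase-locked state; an alternative sign (an extra
π inside this sine) would instead stabilize co-contraction and destroy the
alternating wave, so the antiphase-stabilizing sign is the only one
consistent with swimming.

Muscle activation is σ = 1 wherever sin θ ≥ τ.  For a phase advancing at a
constant rate the on-fraction per cycle is (π − 2 arcsin τ)/2π, so
τ = cos(π·duty) calibrates the threshold; the shipped default
τ = cos(0.36π) ≈ 0.4258 reproduces the 0.36 duty cycle of the
zero-feedback control at a 1 s period.

The coupling sum is evaluated as one complex matrix–vector product
(Σ_j α_{i,j} sin(θ_j − θ_i − ψ_{ij}) = Im[e^{−iθ_i}(Mz)_i] with
M = α∘e^{−iψ}, z = e^{iθ}), which makes a 280-oscillator chain essentially
free.  Phases are stored unwrapped so wave-speed analysis can differentiate
them; wrapping happens only inside sines.

Integration is classical RK4 at a fixed shared timestep (default 2·10⁻⁴ s
in the closed loop, 10⁻³ s for chain-only runs); feedback is held constant
across a step (explicit coupling, sampled from the body state at the start
of the step).

## Sensory feedback

Midline curvature κ = (x′y″ − y′x″)/((x′)² + (y′)²)^{3/2} is computed by
central differences with respect to cumulative arclength, which makes the
estimate insensitive to non-uniform node spacing.  Sign convention:
positive κ bends toward the animal's right side, which the body model
places at +y (body at rest along +x, head first).

Per-oscillator curvature κ_i interpolates the midline field at the
arclength midpoint of oscillator i's muscle segment (the first eighth of
the body is a passive head with no oscillators), then applies an 11-point
boxcar (±5 segments, truncated at the anterior end); the last 5 segments
receive no input.  The smoothing window is in oscillator-segment units.

Two feedback laws, gains in cm·rad/s so η(κ) lands in rad/s with κ in 1/cm:

* magnitude (M): η = η_m·|κ_i| on both sides; admissible |η_m| < 0.09;
* directional (D): η = (−1)^k·η_d·κ_i (k = 1 left, 2 right), so a right
  bend with η_d > 0 excites the right chain and inhibits the left;
  admissible |η_d| < 20.

Outside these ranges phase velocities can go negative and the activation
wave breaks up; the harness aborts when dθ/dt stays negative anywhere for
longer than 0.25 s.

A dynamical note that the directional results depend on: because the
curvature wave is phase-locked to the activation wave, κ_i ≈ K sin(θ_{2,i}
− χ) = −K sin(θ_{1,i} − χ).  The (−1)^k law then gives *both* chains the
same forcing as a function of their own phase, η_d·K·sin(θ − χ).  Such
phase-dependent velocity modulation reshapes the time spent inside the
activation window (duty cycle) at first order but leaves the cycle period
untouched — which is why directional feedback changes duty cycle without
changing frequency, while magnitude feedback (a nonnegative common drive)
changes frequency without changing duty cycle.

## Muscle

Each active lateral segment carries the calcium/Hill unit

    dC_f/dt = (k₄C_b − k₃C_f)(1 − C_b) + k₁(C − C_f − C_b)
              + k₂C_f(C − S − C_f − C_b),
    dC_b/dt = −(k₄C_b − k₃C_f)(1 − C_b),
    k₁ = σ·k̄₁, k₂ = (1−σ)·k̄₂, k₃ = k̄₃·m, k₄ = k̄₄·m,
    dm/dt = −k_m1·P̂_c·v_c  (v_c < 0),   −k_m2·(m − 1)  (v_c ≥ 0),
    P_c = P₀·α(v_c)·λ(l_c)·C_b · taper,

with C = 2 < S = 6 (S > C > 1 so the muscle can fully activate and fully
resequester).  P̂_c is P_c normalized by the segment's maximal force so m
stays O(1).  **Sign convention: shortening is v_c < 0**, so m grows during
loaded shortening.  With k₁ = k₂ = 0 the model conserves C_f + C_b exactly;
the (1−C_b) factor keeps C_b in [0, 1] and C_f stays nonnegative — both
properties are asserted numerically along trajectories.

The shapes of α and λ are not constrained beyond normalization at
(v_c = 0, l_c = rest): we use the standard Hill hyperbola in shortening
(zero force at v_max = 8 cm/s, curvature a = 0.25), a shallow linear branch
capped at 1.5 in lengthening, and a quadratic length–tension curve reaching
zero at ±40% strain.  The rate constants k̄₁ = 8, k̄₂ = 25, k̄₃ = 45,
k̄₄ = 30 s⁻¹, k_m1 = 1, k_m2 = 5 s⁻¹ are re-fitted, not transcribed: they
were chosen once so that an isometric segment driven by the 0.36-duty,
1 Hz control burst develops force through the burst (peak ≈ 0.94·P₀·taper
near the burst end) and relaxes essentially to zero before the next burst,
the transient shape characteristic of this muscle class.  All runs use
work-dependent deactivation and calcium-dependent passive stiffness (a
passive segment stiffness scaled by C_b, configurable off).

The contractile element (CE) is in series with an elastic stretch element
(SE).  The SE stretch under maximal force is 5–10% of segment rest length
(se_strain), fixing k_se = P₀·taper/(se_strain·l_rest); the CE/SE junction
carries a small numerical mass chosen so the junction relaxes at 4000 s⁻¹,
strongly overdamped and integrated stably by the shared RK4 step.  Muscle
force is scaled by the taper factor (w/w_max)², the area ratio of
elliptical out-of-plane cross-sections.

The skin is a tension-only spring per lateral segment (resists extension
beyond rest length, not compression); in the passive head region, which has
no muscle units, the skin springs live with the passive body elements.

## Body

Three filaments: a midline of 2n segments and two lateral filaments of n
segments (defaults 640/320, length L = 12.56 cm).  The width profile rises
along a quarter-ellipse to 10% L about 6% down the body, then tapers
linearly to 0.1% L at the tail (floored at the tail width so the three
filament tips stay distinct).  The first eighth of the body is passive.

Passive elements are Hookean springs with k = k_scale·weight·w_local/r₀
(elastic-rod scaling, length floored at the lateral spacing): midline
nearest and next-nearest axial springs (weighted 25× — the stiff,
near-inextensible midline; drift < 1% in closed-loop runs), transverse
crosslinks from each lateral node to its matched midline node, near-
diagonals to the unmatched (odd) midline neighbors, and diagonals spanning
two lateral segments fore and aft.  The near-diagonals matter numerically:
without them the odd midline nodes are transversally unconstrained and the
chain buckles at grid scale under muscle compression.  The spanning
diagonals provide the shear stiffness that converts differential
lateral-filament strain into midline bending.  There is no structural
damping (the surrounding fluid damps the network).

The single free scale k_scale is calibrated against the macroscopic bending
rigidity: equal and opposite couples are applied at the body ends (zero net
force and torque), the linearized network equilibrium is solved sparsely,
and E = M/(κ·I) is read off at mid-body with I = w³/12 (unit depth).  The
shipped default k_scale = 9.4398·10⁷ dyn/cm² measures E = 0.76 MPa within
a fraction of a percent; E is exactly linear in k_scale, so recalibration
is a one-line fixed-point update.

All force elements act in equal-and-opposite axial pairs, so the assembled
Lagrangian force field of the free swimmer carries zero net force and zero
net torque to rounding, asserted per-run.

## Fluid

The immersed boundary formulation couples the filaments to 2D
incompressible Navier–Stokes: body forces are spread to the staggered (MAC)
grid with the 4-point regularized delta kernel, and nodes advect at the
interpolated local fluid velocity (no-slip).  Spreading and interpolation
use the same kernel and are exact discrete adjoints; the kernel satisfies
the zeroth- and first-moment conditions for any offset.

The solver is a classical projection method: conservative central
advection (explicit), Crank–Nicolson diffusion and the pressure projection
both solved spectrally on a periodic domain.  Periodicity replaces the
no-stress walls of the reference setup — with the default 7.5L × 3L domain
the images are far from the swimmer, but wall effects are a documented
fidelity caveat.  An advective CFL guard (sub-stepping, error above 1)
protects the explicit part.  On a Taylor–Green vortex the solver matches
the closed-form viscous decay to ~0.01% over half a second at 64² cells.

A Reynolds-reduction mode scales μ up (mu_boost) for stable low-resolution
demonstrations; the achieved Re = ρUL/μ_eff is recorded in every
trajectory manifest.  At full scale (μ = 1 mPa·s, U = 0.52 L/s) the control
swimmer's Re is ≈ 8000.

### Resistive backend

For cheap closed-loop exercise the fluid can be replaced by a local
anisotropic drag law (tangential γ_t, normal γ_n per node).  Because the
body springs are stiff, the harness integrates this overdamped system
semi-implicitly: it factorizes (Γ + dt·K) every 25 steps, where Γ is the
block-diagonal drag at the current tangents and K the spring network plus
muscle series stiffness linearized at the current configuration, and solves
for node velocities each step.  This treats the stiff elastic modes
implicitly and lets the body share the loop timestep.  The resistive
backend is used only for quantities set by the CPG and muscle (frequency,
duty cycle, muscle work); hydrodynamic quantities (speed, Strouhal, wake)
require the immersed boundary backend.

## Analysis metrics

* speed: net center-of-mass displacement over the averaging window
  (default the final 4 s) divided by its duration, in L/s;
* tailbeat amplitude/frequency: the tail-tip transverse signal is
  detrended (global line, then a one-period running mean with the boundary
  half-windows cropped); frequency is the inverse median interval between
  upward zero crossings, amplitude half the mean peak-to-trough excursion;
* duty cycle: per-segment on-time over an integer number of cycles
  (delimited by that segment's own onsets), averaged over the final cycles
  and over segments; an always-on segment has duty 1;
* neuromechanical phase lag: per body position, each curvature peak is
  paired with the closest activation onset (within half a period, ties to
  the earlier onset) and the offset is normalized by the local
  onset-to-onset period; positive lag = onset after peak curvature
  (muscle active while shortening);
* wave speeds: activation wave speed from the oscillator phase,
  v_a = −θ_t/θ_s (central differences; the minus sign makes the
  head-to-tail wave speed positive), and curvature wave speed V from the
  unwrapped phase of the Hilbert transform of κ along time; the ratio
  ⟨V⟩/⟨v_a⟩ averages over s ∈ (0.5, 0.8) of the body and the last 7 beats;
* body wavelength: twice the mean spacing of curvature zero crossings
  along the body, averaged over steady frames;
* Strouhal number St = 2fA/U;
* cost of transport: (ΣW⁺ + f_neg·Σ|W⁻|)/(T·mass) from per-segment
  contractile power −P_c·v_c over the last full cycle, with f_neg = 0.3
  (the metabolic discount of negative work is not separately constrained;
  normalized comparisons against the control cancel most of the choice).
  The swimmer's mass is plan area × ρ per unit depth (≈ 8.7 g at default
  geometry).

Every metric is validated by round-trip against the synthetic
traveling-wave generator, which produces midline kinematics
y(s,t) = A(s)·sin(2π(ft − s/Λ)) on a translating backbone together with
the exact curvature (including the envelope-slope phase shift of the
curvature peaks) and activation patterns with prescribed duty and
per-position phase lag.

## Reduced desk-scale configuration

The shipped `reduced_config()` shortens the chain to 70 oscillators per
side (keeping the 7:1 active-to-head ratio; ψ̄ rescaled to keep one wave on
the chain), uses an 80-segment lateral / 160-segment midline body, the
resistive backend, and 8–10 s of simulated time.  The body stiffness scale
(10⁵ dyn/cm²) and muscle force (P₀ = 2·10⁵ dyn) were chosen together so the
emergent curvature amplitude lies in the physiological range (|κ| up to
≈ 1 cm⁻¹ toward the tail, tail amplitude a few percent of L) — the regime
in which the documented feedback gain ranges are meaningful (η_d·κ
comparable to ω near the range edge).  The dynamics are exactly invariant
under joint rescaling of all force scales and the drag, so only the ratios
k_scale/P₀ and γ/P₀ matter.

What the desk scale establishes: control duty 0.36 at 1 Hz; directional
frequency invariance across ±75% of the gain range; the signs of the
feedback trends (frequency increasing with η_m, duty decreasing with η_d,
magnitude duty constant); the sign of the cost-of-transport change with
gain; and monotone grid convergence of swimming speed for the immersed
boundary backend at reduced Reynolds number.  What it does not establish:
the full-fidelity kinematic numbers (0.52 L/s control speed, 0.12 L
amplitude, 0.75 L wavelength) and the quantitative cost-of-transport
percentages, which require the high-resolution (512 cells per domain
length, adaptive-mesh) Navier–Stokes runs at Re ≈ 8000 — cluster-scale
computations by construction.

## Known limitations

* Periodic rather than no-stress fluid boundaries; uniform grid (no
  adaptive refinement); 2D flow.
* The reduced-scale directional duty-cycle slope is smaller than the
  full-fidelity one (the emergent curvature–activation phase relation of
  the softer, drag-dominated reduced body differs from the high-Re
  swimmer); the sign is robust.  A direct consequence: the cost-of-
  transport trend with feedback gain is **not** reproduced at desk scale.
  The full-fidelity cost decrease with gain rides on large duty-cycle
  changes (co-contraction at negative gain wastes muscular work); with the
  desk-scale duty slope ~30× shallower, that work term is negligible and
  the residual CoT trend is set by small amplitude changes of opposite
  sign (measured: directional CoT mildly increasing with gain, magnitude
  CoT flat to 0.1%).  The acceptance tests for the CoT sign are therefore
  expected to fail at desk scale; the energetics pipeline itself is
  validated by its round-trip unit tests.
* The muscle rate constants are re-fitted to transient shape, not to
  experimental force records.
* Stretch-rate (dκ/dt) feedback, feedback delays, perturbation and turning
  experiments are out of scope.
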
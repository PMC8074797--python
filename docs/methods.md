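# Methods

## Models

All quantities are nondimensional: leg length and gravity are 1 and time is
measured in units of sqrt(l/g). Angles are in radians.

**Point-feet walker.** Two massless legs join a hip point mass M = 1 and
carry foot point masses m = β at their tips. The state is
s = (θ, φ, θ̇, φ̇): θ is the stance-leg angle from the normal of the
inclined plane, φ the inter-leg angle (the swing leg's absolute angle is
θ − φ). The walker descends a slope of angle γ; gravity in slope
coordinates is (sin γ, −cos γ). The equations of motion are derived from
the Lagrangian symbolically (`compassgait.symbolic`) and emitted as closed
forms (`compassgait._generated`); in the β → 0 limit they reduce exactly to
the classical hip-mass-dominated ("simplest") walker,
θ̈ = sin(θ − γ), φ̈ = sin(θ − γ) + θ̇² sin φ − cos(θ − γ) sin φ,
which serves as an independent test oracle together with the β → 0
collision law θ̇⁺/θ̇⁻ = cos 2θ.

At foot strike the leading leg undergoes a fully inelastic collision.
Angular momentum of the whole system about the new contact point and of
the trailing leg about the hip are conserved; impulses act only at the new
contact. This yields a velocity map linear in the pre-strike rates with
configuration-dependent coefficients. For the point-feet walker the map is
rank one — both post-strike rates are proportional to θ̇⁻ — and the
post-strike state additionally satisfies the relabelled strike relation
φ⁺ = 2θ⁺ and has zero trailing-leg angular momentum; hence all post-impact
perturbations live in a two-dimensional plane.

**Hamiltonian form.** The same mechanics with conjugate momenta
p = M(q) q̇ as state variables. Because the mass matrix depends on the
inter-leg angle, the velocity → momentum transform is nonlinear in the
state; this is what makes subspace-based stability measures
coordinate-form dependent. Collisions in momentum coordinates are the EL
collision conjugated with the transform; their Jacobians chain through the
transform Jacobian [[I, 0], [∂(Mq̇)/∂q, M]].

**Arc-feet walker.** The authoritative description of the circular-feet
model lives in a reference we could not consult, so this package defines
its own arc-feet walker and documents it fully: hip mass 1 and point
masses β at the leg tips (default β = 0.01), massless legs, arc feet of
radius r whose centre sits on the leg axis at distance 1 − r from the hip.
The stance foot rolls without slipping; gravity is tilted by γ (the ground
line stays horizontal). The state is s = (φ1, φ2, φ̇1, φ̇2) with the swing
(φ1) and stance (φ2) leg angles measured from the ground normal. At r = 0
the model coincides exactly with the point-feet walker (φ2 = θ,
φ1 = θ − φ), which anchors it to the validated dynamics. Consequences of
this mass placement that differ from distributed-leg-mass arc walkers are
flagged below under Limitations.

**Guards.** Foot strike is the zero crossing, from above, of the swing
foot clearance — cos θ − cos(θ − φ) for point feet,
(1 − r)(cos φ2 − cos φ1) for arc feet — while the scuff guard is armed:
θ < −0.05 rad (point feet) or swing leg in front with inter-leg angle
above 5° (arc feet). The arming prevents the mid-swing scuff (legs
aligned) from registering as a strike.

## Numerics

Swing phases are integrated with an adaptive Dormand–Prince 5(4) scheme
(compiled with numba) at absolute = relative tolerance 1e-8 for the
point-feet walker and 1e-10 for the arc-feet walker. The step controller
uses a conservative safety factor of 0.8 so that strike times computed at
tolerance 1e-8 agree with tolerance 1e-10 to better than 1e-7. Events are
located on the cubic-Hermite dense output by bisection of the armed-guard
condition to machine precision in time; the returned pre-strike state
satisfies the guard to ~1e-12. The step horizon is 10 time units; a step
that does not strike within it, drives the stance angle beyond ±π/2, or
breaks the integrator counts as a fall (`FALL_NO_STRIKE`, `FALL_BOUNDS`,
`FALL_NUMERIC`).

Period-one gaits are fixed points of the stride map (swing + collision on
the full 4D post-collision state), found by Newton–Raphson shooting with a
forward-difference Jacobian (step 1e-7), convergence ‖F‖∞ < 1e-10, at most
50 iterations, and a step cap of 0.3 to keep shots integrable. Cold starts
use the cube-root slope scaling of the stance amplitude
(θ0 ≈ 0.97 γ^{1/3}) with the collision law supplying the rates;
continuation seeds each grid combination with its neighbour's solution.
Floquet multipliers are eigenvalues of the central-difference stride-map
Jacobian (step 1e-7); a gait is stable iff every modulus is below 1, and
unstable solutions (including all short-period gaits) are excluded from
measures, robustness and correlations.

Because the strike event eliminates time, the stride map annihilates the
flow direction: its Jacobian maps f to zero, not to itself, and no unit
multiplier arises for this section. The analytically assembled monodromy
G·S·Φ(T) — swing fundamental matrix Φ from the variational equations,
event-stop projection S = I − f⁻∇hᵀ/(∇h·f⁻), collision Jacobian G —
reproduces the finite-difference stride Jacobian entrywise to 1e-4; the
time-parameterized crossing form J_FS·Φ(T) instead carries the unit flow
multiplier, with the same nontrivial spectrum. Liouville's identity
det Φ(T) = exp(∫ tr J dt) holds to relative 1e-5 and checks Φ
independently.

## Gait robustness

Robustness is the largest one-time perturbation after which the walker
still completes 30 consecutive steps (empirically ample for the transient
to decay). Two protocols:

* **step height**: the ground height of the first step's landing is offset
  by a signed amount (units of leg length);
* **push/pull**: a constant horizontal force (units of Mg, per leg,
  positive in the direction of progression) acts at each leg's midpoint
  for 0.1 time units, switched on when the hip (inter-leg) angle crosses
  zero mid-swing. "Hip angle" is read as the hip joint angle, the standard
  biomechanics meaning.

The maximal magnitude per direction is found by geometric bracketing
followed by bisection down to a configured precision (1e-5 point-feet
height, 1e-4 arc-feet height, 1e-2 push/pull), and verified: the returned
magnitude survives while magnitude + precision falls. Bisection assumes
survival is monotone in magnitude along the search path; an exhaustive
linear scan at equal precision reproduces the bisection result on the test
configuration. Height robustness is the sum of the maximal step-up and
step-down; force robustness the sum of the maximal push and pull.

## Phase-dependent stability measures

Along the periodic swing trajectory the perturbation dynamics
δ̇ = J(s(t))·δ are rotated into a moving orthonormal frame U(t) whose
first row is the normalized vector field. The frame is built pointwise as
the Householder completion of the tangent, anchored to the coordinate
axis whose tangent component stays farthest from zero over the swing; this
makes U a smooth function of the state (no sample-density dependence, no
sign flips) and never degenerates on the study grids. In frame
coordinates J̄ = U J Uᵀ + U̇ Uᵀ, with U̇ from fourth-order finite
differences on 1000 uniform samples per swing (one-sided stencils at the
boundary samples carry a slightly larger, ~1e-6, discretization floor).
The first column of J̄ below the diagonal vanishes — tangent perturbations
stay phase shifts — so deleting the tangent row and column leaves the
reduced Jacobian J′(t), and Γ(t) = tr J′(t) is the trajectory-normal
divergence rate. Γ is invariant under any rotation of the normal axes and
equals tr J − f̂ᵀJf̂ pointwise, so it is independent of every frame
discretization choice. Sampling for this pipeline uses tolerance 1e-11:
the dense-output noise is amplified by the inverse sample spacing when
differentiated.

Measures: (i) max Γ, (ii) min Γ, (iii) ∫ Γ dt over the swing (trapezoid;
Simpson agrees to 1e-6 at 1000 samples). (iv) the divergence of the foot
strike: the magnitude of the product of the non-vanishing eigenvalues of
the strike Jacobian — the discrete-event analogue of removing the
phase-shift dimension. (v) the magnitude of the product of the
non-vanishing Floquet multipliers, computed from the assembled monodromy
(less differencing noise than the finite-difference multipliers; both
agree).

Two designs were genuinely open and are resolved as follows:

* **Which strike Jacobian for measure iv.** The saltation-corrected event
  Jacobian J_FS = G + (f⁺ − G f⁻)∇hᵀ/(∇h·f⁻) is the differential of the
  time-parameterized event-crossing flow and satisfies J_FS f⁻ = f⁺; the
  bare collision Jacobian G is the differential of the instantaneous
  collision itself. Measure iv defaults to the bare collision Jacobian:
  the measure quantifies the volume multiplication of the discrete event,
  and the timing correction mixes in swing-flow information already
  carried by measures i–iii. Both variants are available and both are
  coordinate-form invariant; the saltation form is the one used in the
  monodromy assembly.
* **The vanishing threshold.** One eigenvalue of the strike Jacobian is
  structurally (near-)zero: exactly zero for point feet, up to ~1e-5 for
  arc feet at large radius (the foot masses sit a distance r from the
  rolling contact, so the collision is only approximately rank one).
  The package threshold ε_vanish = 1e-4 (relative to the largest modulus)
  separates these structural near-zeros from genuine multipliers, which
  stay above ~1e-3 on the study grids; a much smaller threshold would
  re-admit the structural eigenvalue at large foot radius and put an
  artificial discontinuity into measures iv and v along sweeps.

Eigenvalue-product measures computed on the full matrices (iv, v) are
invariant under the Euler–Lagrange ↔ Hamiltonian change of variables
(verified to relative ~1e-7 at integration tolerance 1e-12); the
frame-reduced 3×3 strike Jacobian is kept as a rank-collapse diagnostic,
but its individual eigenvalues depend on the frames and are not used for
measure iv. Measures i–iii are subspace quantities and change with the
state-space form — the package reproduces this form dependence as a
strict, far-above-tolerance inequality.

## Local divergence exponent

Per configuration, noisy walking is simulated: independent zero-mean
Gaussian floor-height offsets (sd 2e-5) at every step. The full 4D state
series, resampled uniformly at 50 samples per unperturbed stride, is the
direct input to Rosenstein's algorithm: nearest neighbour per point with a
one-stride temporal exclusion window, mean log-divergence curve, straight
line fitted over 0–0.5 stride, slope expressed per stride, averaged over
runs. Defaults follow the study protocol (5 runs × 200 steps); sweeps use
a scaled-down setting (3 runs × 60 steps) chosen so a full reduced grid
completes in seconds while the estimator remains stable (the two settings
agree to a few percent on spot checks). Runs in which the walker falls
are redrawn with fresh sub-seeds. On constructed signals
s(t) = s*(t) + ε e^{λt} u the estimator recovers λ within 5% for generic
directions u; directions nearly aligned with the local trajectory
structure degrade the estimate, a known weakness of nearest-neighbour
divergence tracking. A noise-free gait yields an exponent at the numerical
floor (|λ| < 0.1 per stride versus ~1.4 for the noisy gait).

## Sweeps and correlations

Grids follow the printed specifications: slopes γ = 0.001…0.012 in steps
of 2e-4 (56 values); mass ratios β = 0.002…0.1 in steps of 2e-3 (50
values), giving 2800 point-feet combinations; radii r = 0.01…0.49 in
steps of 0.04 (13 values) × the same slopes, giving 728 arc-feet
combinations. Grids are snake-ordered so adjacent combinations differ in
one parameter and continuation can seed every Newton shot. Each stable
gait gets measures, the LDE and robustness; failures are recorded and
never abort a sweep. Sweeps are deterministic given the configuration and
seed (per-combination noise seeds derive from the base seed and the
combination index) and resumable from a JSON record cache.

Kendall's rank correlation, tau-b (tie-corrected), summarizes each
measure against a robustness sum over all stable combinations; |τ| > 0.7
is flagged strong. Tie correction matters because robustness values are
quantized at the search precision. An exhaustive pair-enumeration oracle
verifies the statistic on short arrays.

`scripts/acceptance.py` runs reduced versions of both sweeps — the point
grid subsampled to 14 × 10 and the arc-feet grid to all 13 radii × 8
slopes, spanning the same parameter ranges — and reports every tau. On
the reduced point-feet grid the package reproduces the qualitative
pattern of the study: the swing divergence integral (iii) and the
foot-strike divergence (iv) correlate strongly and negatively with height
robustness (τ ≈ −0.75 for both), while the pointwise maximum (i), the LDE
and the full-cycle divergence (v) stay weak.

## Limitations

* The arc-feet walker is this package's own construction (tip point
  masses, default β = 0.01), not the distributed-mass model the original
  study imported from the literature. Its height-robustness correlations
  keep the same signs as the study's (including the positive correlation
  of measure ii), but its push robustness orders the (r, γ) grid almost
  independently of its step robustness (τ ≈ 0.17 between the two), so
  push-based correlations do not transfer; the measure–robustness
  relation is model dependent, and conclusions drawn from this model
  apply to this model.
* Full 2800/728-combination sweeps with robustness bisection take hours
  on one CPU; the shipped acceptance run subsamples the same ranges. The
  CLI `reproduce-figure --full` runs the complete grids.
* Survival is assumed monotone in perturbation magnitude during
  bisection; strong non-monotonicity (possible in principle for nonlinear
  walkers) would make "largest survivable" first-failure semantics.
* The frame-reduced per-eigenvalue profiles of J′(t) depend on the frame
  convention (only their sum Γ is convention-free); they are provided for
  inspection, not as measures.
* Only period-one gaits are analysed; period-two and chaotic regimes are
  out of scope, as are 3D walkers, actuation, hip springs and compliant
  ground.
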
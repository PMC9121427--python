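# Methods

## Model

The template is a planar point-mass body on two massless linear-spring
legs with passive torsional hip springs.  Parameters (normalized by body
mass m, rest leg length l₀ and gravity g):

| parameter | meaning | unit | default |
|---|---|---|---|
| k | leg spring stiffness | mg/l₀ | 20 |
| ω | swing-leg oscillation frequency | √(g/l₀) | 6.5 |
| φ_l, φ_r | neutral leg swing angles (NLSA) | rad | 0 |

Angles are measured from the downward vertical, counterclockwise positive
with forward motion along +x, so anterior (forward) foot placement is
positive.  The swing equation is implemented as

    α̈ = −(1/l₀)[ẍ cos α + (g + ÿ) sin α] − ω²(α − φ),

with the signs fixed by three physical requirements that the tests verify:
the body-coupling term cancels exactly in ballistic flight (the swing leg
is then an exact harmonic oscillator about φ with period 2π/ω); the
torsional term restores α toward φ; and for a held body the leg behaves as
a stable hanging pendulum, with linearized frequency √(ω² + g/l₀) about
vertical.  The stance equation is the second time derivative of the
holonomic anchor constraint x_c − x − y·tan α = 0 (infinite friction), and
the touchdown reset replaces the landing leg's angular velocity by the
unique value that keeps the new anchor stationary.  Both are verified
against a symbolic constraint-differentiation oracle.  The model is
conservative: the reset acts on a massless leg and does no work; tests
require energy drift below 10⁻⁶ per stride.

## Stride boundary value problem

Gaits are periodic solutions anchored at an apex (ẏ = 0) of the COM
height — in flight for aerial gaits, in single stance for walking, which
has no flight phase (double-support anchors are rejected).  A stride is
solved as a multi-phase boundary value problem: the unknowns are the
reduced apex state (y, ẋ, α_l, α̇_l, α_r, α̇_r with x ≡ 0; a stance
anchor's leg rate is pinned by the constraint), the four event times and
the stride time, under a *prescribed event ordering*; the residuals are
state periodicity (measured relative to the state scale), the apex closure
ẏ(T) = 0, and the four foot-height conditions y(t) = l₀ cos α at the
scheduled events.  One anchor (total energy, apex speed, or a
pseudo-arclength plane) closes the energy direction of the one-dimensional
solution family.  Hopping is additionally continued in the leg-synchronized
subspace (α_l = α_r, shared event times) for robustness.

Two deliberate conventions follow from the template's massless legs:

* **Scuffing is not an event.**  A swing foot may pass below ground level
  between scheduled events (any leg crossing vertical while the body is
  below leg length does so); contact is meaningful only at the solved
  touchdown times.  First-crossing event detection is still provided (and
  is the default of `simulate_stride`), and it is the validity oracle for
  flight-dominated gaits such as slow hopping; but walking and most
  running solutions exist only under the scheduled-event semantics.  The
  minimum swing-foot clearance is recorded on every solution as a
  diagnostic.
* **Premature touchdown is a recorded diagnostic.**  A touchdown with the
  leg still rotating anteriorly (α̇ > 0.02 √(g/l₀) at contact, a threshold
  chosen well above integration jitter and far below genuine swing rates)
  marks a solution as having an abrupt angular-velocity reset.  Tracing
  does not stop there by default, because posterior-NLSA running solutions
  with exactly this character are part of the studied structure; a
  `stop_on_premature` option restores the stricter behavior.

## Numerics

* Integrator: a numba-jitted adaptive Dormand–Prince 4(5) stepper,
  rtol 10⁻⁹ / atol 10⁻¹¹.  Free-mode events are bracketed per accepted
  step, pre-located on the cubic Hermite interpolant and polished by
  Newton iterations on exact Runge–Kutta substeps (event residuals
  ~10⁻¹²).  Simultaneous events within 10⁻⁹ are processed together,
  touchdowns before liftoffs.
* Root solving: Levenberg–Marquardt on the boundary-value residual with
  finite-difference Jacobians (relative step 10⁻⁷), convergence at
  residual norm 10⁻⁸ (scale-relative), with one warm restart if the
  iteration stalls just above tolerance.
* Continuation: pseudo-arclength predictor–corrector in the extended
  unknown space, secant tangents, step halving on corrector failure and
  growth factor 1.3–1.5 on success.  Timing degeneracies are crossed by
  flipping the two nearest scheduled events; the crossing point itself is
  re-solved with the simultaneity imposed by construction (the duplicated
  time removed from the unknowns, which avoids the ordering cliff).
* Floquet analysis: central-difference monodromy of the return map in the
  full six-dimensional apex coordinates; the free event-detecting map is
  used when it reproduces the solved stride, otherwise a map that re-solves
  the event schedule per evaluation.  Hop↔skip bifurcations are sign
  changes of det(B − I) for the 2×2 leg-desynchronization block, refined
  by secant iteration until the critical multiplier is within 10⁻³ of +1.
  Conservative fixed points carry exactly one unit multiplier (the
  energy/branch direction); two multipliers vanish to numerical precision
  because the touchdown resets erase the swing legs' incoming angular
  rates to leading order.
* Parameter transport: solutions are carried across (k, ω, φ_l, φ_r)
  changes by pseudo-arclength continuation along the parameter ray, which
  tracks the *same* solution through folds and past coexisting nearby
  fixed points; on breakdown the probe re-anchors along the local energy
  family and retries.

## Study recipes and problem sizes

`slipgait.study` assembles the standard analyses at sizes that run in
minutes on one core (branch point budgets 150–400, arclength steps up to
1.0, speed cap 30.5 √(g·l₀)):

* The symmetric continuum is seeded constructively: because the massless
  swing legs do not affect the COM, a symmetric single-stance step of the
  body-only SLIP is found by two nested scalar root solves, the swing-leg
  phases are attached analytically (flight-phase swing is exactly
  harmonic), and the full BVP polishes the assembled seed.  The branch is
  continued down to the walking↔running degeneracy — where the anchoring
  aerial phase itself vanishes, so the refined endpoint is solved with the
  simultaneity constraint — and up to its high-speed end.
* The asymmetric continuum starts from forward hopping (legs crossing
  vertical at the apex, where ground clearance is maximal), traced from
  near zero speed to its fold at the maximum speed; skipping is obtained
  by branch switching at the lower hop↔skip bifurcation and traversed
  through both skip↔AR degeneracies.
* Existence boundaries in NLSA are fold envelopes of fixed-speed slices
  continued in φ (speeds 0.5–4 for hopping's anterior boundary, 6–26 for
  running, 6.5–29 for skipping).  The anterior hopping boundary uses the
  1.7 rad bound on swing excursion about the neutral angle as the
  realism criterion, because the bare model admits periodic hops with
  arbitrarily wild swing motion at large φ.
* Transition catalogues across NLSA are computed by continuing the
  degeneracy points themselves through parameter space (solution plus φ as
  unknowns, simultaneity built in); catalogued on a φ_l grid of 0.02 rad,
  with the coupled diagonal excluded from the uncoupled catalogue (there
  the transition curve degenerates into the symmetric structure).

## Synthetic kinematics and fitting

The fixture generator emulates markerless pose tracks: one stride of a
periodic solution sampled at 40 frames per √(l₀/g) (500 fps at
l₀ ≈ 0.065 m) with independent Gaussian noise per channel (velocity noise
scaled like finite-differenced position noise).  It reproduces sampling
density and additive noise but none of the structured errors of real pose
estimation (marker swaps, occlusions, soft-tissue motion, COM-estimation
bias), nor step-to-step aperiodicity of real locomotion — passing recovery
tests therefore demonstrate identifiability under the model's own
assumptions, not field robustness.

Fitting minimizes the integrated squared deviation of all position and
velocity channels over one stride (trapezoidal quadrature on the sample
grid, channels weighted equally, data x-origin aligned to the first
sample, model time scaled to the empirical stride duration), jointly over
the periodic solution and the free parameters (ω, φ_l, φ_r; k optional)
with the boundary-value conditions as strongly weighted residuals of the
same least-squares problem.  Noisy data pulls the soft-constrained optimum
slightly off the periodic manifold, so the result is projected back by an
exact re-solve at the fitted parameters.  Median recovery errors over
repeated seeds at noise σ = 0.005 l₀ are below 2% in ω and 0.02 rad in the
neutral angles.

## Known limitations

* The fixed-sequence corrector can converge to a coexisting nearby
  solution if stepped too aggressively; transports therefore cap the
  per-substep parameter change, and branch tracing relies on the
  pseudo-arclength plane.
* Uncoupled-NLSA structures in this implementation span a smaller φ_l
  range than reported elsewhere for this model class (closed
  skipping/AR loops at φ_r = 0 vanish near φ_l ≈ −0.08; transition curves
  fold near +0.08), while all coupled-structure quantities are reproduced
  to 1–3%.  Left/right offsets beyond ≈0.1 rad admit no periodic solutions
  here; the trial-like fixture therefore uses a clearly labelled synthetic
  stand-in configuration (ω = 6.49, φ_l = 0.17, φ_r = 0.10) with a 0.07 rad
  offset.
* Anterior existence boundaries of hopping/skipping depend on the adopted
  swing-amplitude realism criterion; a pure existence criterion is
  unbounded in φ.
* The Poincaré section is ill-defined exactly at the walking↔running
  degeneracy (the anchoring aerial phase has zero length); the refined
  point is the limit from the running side.
* No stability-based gait selection: branches include unstable solutions,
  and left-advanced/right-advanced duplicates are related by the leg-swap
  symmetry rather than enumerated.
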
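# Methods

## The plant: a frontal-plane beam-column of the lumbar spine

The passive spine is a continuous elastic beam-column in the frontal plane
(X vertical, Z lateral), clamped at the sacrum and meshed with five two-node
elements whose nodes sit at the laterally bent reference posture

| node | L5 | L4 | L3 | L2 | L1 |
|------|----|----|----|----|----|
| X (mm) | 38 | 80 | 105 | 150 | 190 |
| Z (mm) | 0.4 | 1.7 | 3.0 | 6.2 | 10.0 |

with flexural rigidity EI = 1.9 N m² and cross-section area 1225 mm².  The
beam is stress-free in this posture; the controllers defend its lateral
(Z) coordinates under load.  Elements are corotational Euler–Bernoulli
beams: small strain inside the element, arbitrary rigid rotation of the
chord, with the geometric (stress-stiffening) terms of the current axial
force in the tangent.  This reproduces the two behaviours that matter here:
the Euler buckling load of the bare fixed-free column, π²EI/4L² ≈ 130 N
(every loading case exceeds it several-fold, which is why the uncontrolled
system collapses), and the P-delta moments that the muscles must balance.
Shear deformation is neglected (slenderness ≈ 190/35).  Only EI and the
area are stated inputs; where the axial rigidity EA is needed it follows
from a square section of the stated area (side 35 mm, I = a⁴/12,
E = EI/I ≈ 15.2 MPa, EA ≈ 18.6 kN).  Axial strain under the simulated loads
is then a few percent; it shortens the muscles slightly below their resting
lengths at steady state but has no other role.

Internal section loads are recovered per intervertebral level (cut in the
element just below each lumbar node) by summing external plus muscle forces
over the free body above the cut and projecting on the local deformed chord
tangent (compression) and normal (shear).  At a converged quasi-static
state this equals the element end force.

## Muscles

Ten Hill-type line actuators connect the pelvis to the five lumbar nodes,
one per side per level.  The force law is

    F = f_max (α fl(l) fv(l̇) + fp(l)),  f_max = 800 N,
    fl(r) = 5.1 − 29r + 56r² − 41r³ + 10r⁴          (clamped at 0)
    fv(x) = 0.1433 / (0.1074 + exp(−1.409 sinh(3.2x + 1.6)))
    fp(r) = exp(−10.671 + 7.675 r)

with r = l/l0 and x = l̇/l̇_max, l̇_max = l0/0.1 s.  The resting length l0 of
each muscle is its length in the reference (target) posture — the posture
the controller defends is the muscle's mechanical reference.  fl is clamped
at zero where the quartic goes negative (beyond ≈1.4 l0) so activation can
never push.  fv supplies the muscle's intrinsic damping; its slope at
l̇ = 0 gives each active muscle an effective damping of order
f_max α fl fv′(0)/l̇_max ≈ 1.3 α kN s/m, which is a large share of what
stabilises the supercritical column once the controllers are active.

**Attachment geometry.**  The lateral pelvis offset D (25/50/75 mm per
loading case) is measured from each vertebra's target position: the origin
of the muscle inserting at (X_k, Z_k) is (0, Z_k ± D), so the line-of-action
direction ratio is D/X_k for every level.  This convention reproduces the
published level-wise loads of both models; measuring D from the sacrum
midline instead leaves the equilibrium baseline 8–46 % below the published
compressions (the inverted muscle-force directions implied by those tables
are incompatible with sacrum-midline origins at all three D values).

**Passive term.**  As printed, fp carries 0.05 f_max = 40 N at the resting
length, i.e. ~400 N of tone across ten muscles, which would add ≈300 N of
L5–S1 compression at steady state — demonstrably absent from the published
spinal loads (a static analysis with full bilateral tone overshoots all
compressions by 29–40 %, without it they agree to ~5 %).  The plant
actuators therefore default to a slack parallel elastic element,
fp_slack(l) = max(0, fp(l) − fp(l0)): zero at and below rest, the same
exponential toe curve under stretch.  This is the conventional behaviour of
a parallel elastic element.  The as-printed variant remains available
(`muscles.passive: eq` in the configuration), and the `hill` module
implements all four published expressions exactly.

## Controllers

One SISO adaptive fuzzy neuro-controller per muscle.  Input: the lateral
position error e = Z_target − Z of its insertion node (mm) and its rate
ė = −Ż (mm/s, analytic from the integrator state, not finite-differenced).
Output: activation α ∈ [0, 1].  The network is a zero-order Takagi–Sugeno
system: a 7×7 grid of Gaussian memberships over the normalised (e, ė)
plane (normalisation 2 mm and 20 mm/s, inputs clipped to the unit box,
σ = grid spacing), one scalar consequent weight per rule, output the
normalised weighted sum clipped to [0, 1].  The sensitivity ∂α/∂wᵢ is the
normalised firing strength, which the learning rule uses directly.

Weights start at zero (no initial activation) and adapt every integration
step by steepest descent on the two-critic cost: with
r_e = h₁e + h₂ė + h₃∫e and r_α = |α|,

    Δwᵢ = η dt (k_e h₁ r_e j − k_α r_α) ∂α/∂wᵢ.

Gains: h₁ = h₂ = h₃ = 2, k_α = 0.2, and k_e = 15, 7, 2.5, 1, 0.1 for L1
through L5 — control priority decreases down the column, which also orders
the learning speeds.  The plant Jacobian enters only through its sign
j = sign(∂Z/∂α), fixed per muscle by the side of its origin.  The error
integral uses the rectangle rule with an anti-windup clamp at ±50 mm s.

The learning rate is expressed as a rate, η = 0.3 s⁻¹ (3×10⁻⁴ per 1 ms
step), so that refining the integration step does not change the learning
dynamics.  The value is the package's own tuning: much larger values (e.g.
5×10⁻² per step) drive the loop into a bang-bang limit cycle — the L1
muscle saturates, its ~800 N axial component pushes the column into a
higher buckling mode faster than the low-gain mid-column controllers can
learn, and the run diverges; much smaller values cannot track the 0.2 s
load ramp.  At η = 0.3 s⁻¹ the activation at L1 tracks the ramp smoothly
and the lower levels settle over tens of seconds.

At the learned fixed point of an active muscle, k_e h₁ r_e j = k_α α: the
residual kinematic critic is proportional to the activation penalty, and
since r_e then reduces to h₃∫e, the position error itself is driven to
zero with the integral holding the balance.  The suite verifies this
stationarity to 10⁻³ on a fully converged single-muscle loop.  On the full
plant the residual decays at a rate set by k_e, the loop gain and the
stability-bound η: in the gentlest loading case (uniform loads, D = 50 mm)
every active loop is within 0.07 of the fixed point at the 25 s horizon,
while the high-demand case (D = 25 mm) leaves the L1 loop still far from
it — kinematic convergence (sub-0.1 mm errors) arrives much earlier than
critic convergence.

## Quasi-static integration

The loading is quasi-static (masses and inertias of the trunk are
neglected); the transient exists only to let the controllers learn.  The
integrator is Newmark average acceleration (γ = ½, β = ¼) with full Newton
iteration per 1 ms step; the muscle stiffness (line-of-action geometric
term plus force–length slope) and force–velocity damping are part of the
iteration matrix.  Non-convergent steps are retried with halved substeps;
a run whose lateral displacement exceeds 50 mm (or whose Newton iteration
fails at the smallest substep) is aborted and flagged unstable — never
silently continued.

Two surrogates regularise the transient: lumped nodal masses of 0.1 kg
(rotary inertia 10⁻⁴ kg m²) and stiffness-proportional damping
C = βK₀ with β = 1.0 s, which puts the open-loop column in an overdamped
creep regime slow enough for weight adaptation to stabilise it.  Both are
verified side-effect-free where it matters: halving either the nodal mass
or the time step changes the steady muscle forces and section loads by
less than 1 % (the steady state is a static equilibrium).  External loads
ramp linearly over 0.2 s and are then held.

Steady state is declared when the maximum lateral error stays below 0.2 mm
and the maximum lateral speed below 1 mm/s continuously for 1 s after the
ramp; the horizon is 25 s.  With these settings all five loading cases
converge, with one muscle per level active (its antagonist below α = 0.01)
and worst-case tracking errors of ~0.2 mm during learning.  This model
settles faster (seconds) and more cleanly than the source system's
reported ~20 s convergence with sub-millimetre residual oscillation; the
difference is the fuzzy architecture and η, neither of which is documented
for the original system, and it leaves all steady-state quantities
unchanged except as noted under Limitations.

## The equilibrium baseline

The matched inverse model fixes the geometry at the reference posture and
requires the internal force transmitted across each of the five levels to
be a follower load: zero shear against the local tangent.  With one signed
muscle intensity per level this is a square 5×5 linear system; the sign of
each intensity selects the active side, and the system is re-solved with
the selected sides' exact line geometry until the side pattern is
consistent (two or three passes).  Tangents default to the chords of
adjacent nodes; a cubic-spline option exists because the source's
curvature treatment is undocumented (it changes compressions by < 0.5 %).
The solve is exact, so the residual shear is machine-zero — the small
nonzero shears in the published equilibrium columns suggest the original
was solved as a penalised optimisation; the compressions nevertheless
agree to 0–6 %.  By construction zero shear at every cut also implies zero
internal moment at every cut (the two 5-constraint systems are equivalent
for a serial chain), so the solution is the unique unilateral follower-load
state of the given geometry.

## Test scaffolding and what it shows

The toy fixtures (straight cantilever, fixed-free Euler column, one-muscle
statics) carry closed-form oracle values and pin the finite-element kernel
to 1 %.  The loading cases themselves are the study conditions: printed
geometry, loads, gains and Hill constants, not synthetic data.  Passing
tests therefore show that the implementation reproduces the idealised 2D
published system — not that the predictions transfer to 3D spines, other
postures, or real muscle architectures.

## Known limitations

* Idealised model by construction: frontal plane only, straight muscle
  lines, no activation dynamics, no reflex/spindle feedback, no
  intervertebral joint detail, no upper-body inertia.
* Loading case 4 (D = 25 mm): holding the target posture with the steep
  muscle lines requires ≈270 N in the L1 muscle, and the L1–L2 compression
  converges ≈29 % above the published control value (the published number
  implies ≈190 N there together with a −6 N residual shear, a bias state
  this implementation does not reproduce; all other level/case
  combinations agree within ±15 %, most within ±5 %).  The equilibrium
  baseline shows a milder version of the same effect (−5…−6 % at the top
  two levels of case 4).
* The critic fixed point is approached but not met to 10⁻³ on the full
  plant within the 25 s horizon (see Controllers); kinematic quantities
  are unaffected.
* In the L1 load sweep the lateral demand at L2 crosses zero near 250 N,
  so the active side at that level switches between sweep points; the
  linear-scaling result holds for the signed level force (side in the
  sign), which is the continuous variable.  The source model's L2 muscle
  evidently stayed on one side over the same range.
* The transient is shaped by the damping/mass surrogates, so only its
  qualitative features (bounded errors, force rise/fall under load pulses,
  eventual unilateral pattern) are meaningful; steady-state quantities are
  surrogate-insensitive to < 1 %.
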
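# Methods

This note records the modeling assumptions, parameter choices, and numerical decisions behind
`precigrip`, and what the packaged tests do and do not demonstrate.

## Model and procedure

A precision grip is synthesized in three nested stages:

1. **Effort QP.**  For a fixed posture and contact set, the decision vector `x = [f; a]`
   (stacked contact forces, then 37 activations) minimizes `E = Σ a_i²` subject to object
   force/moment equilibrium `G f = [-mg; 0]`, linearized friction `N f ≤ 0`, the force balance
   `Jᵀ f − Mᵀ F_max a = 0` over the 21 actuated axes (the 6-DOF carpal base is unactuated and
   contributes no balance row), and `0 ≤ a ≤ 1`.  The problem is convex; its optimum is the
   unique minimal-effort coordination for that posture.
2. **Inverse kinematics.**  Carpal pose `(p, e)` and joint angles `q` minimize
   `L = w₁ Σ|dₗ − dₗ⁰|² + w₂ Σ sₘ² + w₃|p − p⁰|² + w₄|e − e⁰|² + w₅|q − q⁰|²`, where `dₗ` are
   the active fingertip contact sites, `sₘ` the 65 skin-sphere penetration depths, and
   `(p⁰, e⁰, q⁰)` an anatomically natural initial pose.  Only fingers participating in the
   grasp contribute the first term.
3. **Contact-position search.**  CMA-ES over the in-plane coordinates `(u, v)` of each
   grasping fingertip on its assigned planar surface (4 variables for a two-finger pinch).
   Candidates that cannot reach or cannot be held receive the penalty
   `E = 100 + Σ(q − q⁰)²`; 100 exceeds the largest possible effort (37), so any feasible
   posture outranks any infeasible one, and infeasible postures are ranked by posture
   deviation, which gives the search a gradient back toward workable regions.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| friction planning margin | μ_eff = μ_actual / 2 | grip safety margin attributed to the nervous system; μ = 0.8 → 0.4 |
| friction pyramid | 12 facets, inscribed | forces satisfying the pyramid always satisfy the exact cone (no-slip guaranteed); tangential capacity varies between μ·cos(π/12) and μ with azimuth |
| soft-pair offset | 2 mm | emulates pad torsion transmission; a tangential couple at ±2 mm gives 0.004·F N·m about the normal |
| IK weights | w₁ = w₂ = 100, w₃ = w₄ = 1, w₅ = 0.1 (SI) | contact and non-penetration dominate; base pose weakly regularized; joint naturalness weakest. Unpublished in the source; these encode the stated priority ordering |
| penalty constant | 100 | any value > 37 preserves the ordering; only the ordering matters |
| CMA-ES | population 4 + ⌊3 ln d⌋, σ₀ = half the largest surface dimension, ≤ 200 generations, stall tolerance 1e-6 over 20 generations | σ₀ must sample the whole patch: with a smaller step a far-end start can idle in the penalty regime, whose ranking signal (posture deviation) is weak |
| muscle strength scale | 30 N per table unit (pipeline only) | see below |
| QP feasibility tolerances | equality ≤ 1e-8·scale, facets ≤ 1e-10 | scale = max(1, m‖g‖); the active-set solver typically reaches 1e-13 |

### The muscle strength scale

The packaged muscle table stores the tabulated maximum-force column verbatim (e.g. flexor
pollicis longus 2.7).  Read as newtons these values are an order of magnitude below
physiological strength — the strongest possible index MP flexion torque would be ~76 mN·m,
several-fold less than **any** two-finger hold of a ~200 g object demands, making every grasp
infeasible.  The column is therefore interpreted as a normalized strength unit (a
tension-fraction measure) and the synthesis pipeline multiplies by
`DEFAULT_STRENGTH_SCALE = 30 N/unit`, the classical conversion from tension fractions to
muscle force; `load_muscle_table()` itself defaults to the verbatim values so the table remains
inspectable as published.  With this scale a centered pinch of the 198.4 g fixture costs
E ≈ 0.07 with peak activations ≈ 0.15 — the regime the method is meant to operate in.

### Geometry

The CT-derived bone geometry behind the original model is unpublished.  The packaged hand is a
parametric surrogate: documented anthropometric segment lengths scaled to a ~19 cm hand, hinge
axes along the anatomical medio-lateral direction (flexion applied before adduction at 2-DOF
joints), a thumb column mounted by three configurable rotations, and 65 skin spheres placed
along the bones with per-segment radii (the distal-most sphere of each phalanx is tangent to
the fingertip so a tip contact carries zero penetration).  Two "anatomically natural" reference
postures ship with the model — an opposed tip pinch and an opposed pad pinch, both with a
~40 mm aperture — and the initial carpal pose for a candidate is computed by aligning the
contact sites and their outward site normals with the target points and the *anticipated*
contact-force directions (inward surface normal tilted against gravity by the expected load
share).  This alignment is what lets contact-force lines pass near the distal joint axes,
where the weak distal muscles can balance them; without it most placements are
force-infeasible even though they are reachable.

All results are therefore model-dependent in the way any surrogate geometry is: the *structure*
of the findings transfers, specific effort values do not.

## The device fixture

The validation object is a two-plate force-sensing device: 198.4 g, two parallel
20 × 49 mm plates.  Plate separation (40 mm) and friction (μ = 0.8) are not printed in the
source and are configurable defaults.  The 49 mm plate axis is mounted horizontally: an offset
of the pinch axis parallel to gravity produces no gravitational moment, so the observed
center-vs-end effort differences require the long axis to be the horizontal one; the vertical
(load) direction spans the 20 mm side.

## Numerical choices

* **QP solver.**  HiGHS LP probe for a feasibility certificate and a starting vertex, then a
  primal active-set iteration whose equality-constrained subproblems are solved in the
  constraint null space by least squares — this tolerates the rank deficiency of soft-contact
  pairs (two point contacts cannot resist a moment about their connecting line) and of the
  positive-semidefinite Hessian.  Because `E` is strictly convex only in `a`, the force vector
  is made deterministic by a secondary minimum-norm-`f` solve at the optimal activations.
  An independent SLSQP backend (fed a row-reduced equality system) is used for cross-checks.
* **IK optimizer.**  Bounded L-BFGS with analytic gradients for `p` and `q` (via the contact
  and sphere-center Jacobians) and central differences for the 3 orientation components;
  rotation vectors are wrapped to norm < π.  Convergence: gradient ∞-norm < 1e-6 or
  ΔL < 1e-14, ≤ 500 iterations.  The penetration term uses depth² (the depth is not squared
  twice); depth is `max(0, r − signed distance)` against a union of boxes.
* **Contact construction.**  The contact centroid is the converged fingertip site projected
  onto the surface patch (clipped to its bounds); the soft pair is laid along the distal
  phalanx's medio-lateral axis projected into the contact plane, falling back to the surface's
  long axis when nearly parallel to the normal.  A candidate whose site misses its target by
  more than 3 mm is treated as unreachable.
* **CMA-ES.**  A compact seeded (μ/μ_w, λ) implementation with rank-μ update and cumulative
  step-size adaptation; out-of-bounds samples are folded back by boundary reflection.  Runs are
  bitwise reproducible for a fixed seed.

## Problem sizes used in the packaged tests

The test suite runs the outer search with population 6 and ≤ 10 generations from two opposite
plate-end initializations, and the effort-ordering sweeps evaluate single candidates at the
center and ±6 / ±12 mm offsets for both grip styles.  These sizes give stable results on this
fixture (two-initialization agreement within ~1%); production searches can simply use the
defaults (population 8, ≤ 200 generations).

## What the tests show — and do not

The packaged fixture reproduces the *mechanical structure* of the reference experiment: exact
mass recovery from equilibrium, constraint residuals at solver precision, agreement of the QP
with grid-search and multi-start oracles, convergence of far- and near-end searches to the
same effort, effort rising away from the object's center of mass, and pad grips beating
fingertip grips off-center.  At the exactly centered placement the tip/pulp efforts are a
near-tie on this surrogate geometry (within ~1.5%, tip marginally lower): the per-style
designed postures largely erase the distal-lever penalty there, so the pad-grip advantage is
asserted across placements rather than pointwise.  Published absolute effort values and
simulated force components depend on the unpublished CT geometry and are not reproduction
targets.

## Known limitations

Constant moment arms (no posture dependence), no pennation or force–length/velocity scaling,
no muscle paths or finger-extensor web, rigid skin spheres (no pad compliance), planar contact
patches only, two-finger grasps exercised (the machinery accepts up to five), and a surrogate
hand geometry.  Forward-dynamic grasping and EMG-level validation are out of scope.
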
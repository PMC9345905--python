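# precigrip

Synthesis of biomechanically feasible human **precision-grip postures** by minimization of
muscle effort.

Given a rigid object and a musculoskeletal hand model, `precigrip` finds fingertip contact
positions, a hand posture, fingertip forces, and muscle activations that hold the object in
static equilibrium while minimizing the summed squared muscle activation — a criterion
neurophysiology suggests the central nervous system itself uses.  It is aimed at motor-control
researchers and at virtual ergonomic assessment of handheld products: how a change in an
object's dimensions or mass changes the muscular cost of gripping it, without building mockups.

## The model

**Hand.** A chain of 21 rigid bone segments (forearm, carpus, five metacarpals, fourteen
phalanges) with 21 actuated revolute axes — thumb CMC and MP joints with two degrees of freedom
each plus the IP hinge, and MP (2-DOF), PIP, DIP for each finger; the finger CMC joints are
immobile.  The palmar surface is approximated by 65 spheres used for non-penetration tests.
Because the original CT-derived geometry is not published, the packaged geometry is a
documented anthropometric parameterization (~19 cm hand), fully configurable.

**Muscles.** 37 intrinsic and extrinsic hand muscles with maximum forces and constant, signed
moment arms (packaged as `data/muscles.csv`).  Muscle force is `F_i = F_i_max a_i` with
activation `a_i ∈ [0, 1]`, and joint torques are `τ = Mᵀ F_max a` with the 37×21 moment-arm
matrix `M`.

**Grasp statics.**  For `n` point contacts with forces `f`, the object must satisfy

```
G f = [-m g; 0]              (force and moment equilibrium; G is the 6×3n grasp matrix)
n_{k,h} · f_k ≤ 0            (Coulomb friction, cone linearized as a 12-facet pyramid)
Jᵀ f = Mᵀ F_max a            (contact forces must be producible by the muscles)
0 ≤ a ≤ 1
```

Soft contact of a finger pad (its ability to transmit torsion about the surface normal) is
emulated by a pair of contact points 2 mm either side of the contact centroid.  Grasps are
planned against **half** the actual friction coefficient — the safety margin the nervous system
applies — so a surface with μ = 0.8 is gripped as if μ = 0.4.

**Pipeline.**  The effort `E = Σ a_i²` is minimized as a convex QP over `[f; a]` (an exact
primal active-set solver with an LP feasibility probe).  An outer CMA-ES searches the in-plane
contact coordinates of each grasping fingertip on its assigned surface; each candidate is posed
by inverse kinematics (a quasi-Newton minimization of target misses, skin–object penetration,
and posture-naturalness terms) and scored by the QP, with postures that cannot be held
receiving a large penalty.

## Worked example

`examples/03_qp_anatomy.py` pinches the packaged validation fixture — a 198.4 g sensing device
with two parallel 20 × 49 mm plates — at the plate centers and dissects the solved QP:

```
feasible: True,  effort E = 0.0719
residuals: equality 1.14e-14, friction facets 1.17e-15, bounds -0.00e+00
sum of vertical force components: 1.9463 N
recovered object mass: 198.4 g   (device mass: 198.4 g)
```

`E = 0.0719` is the minimal summed squared activation for this hold; equilibrium forces the
vertical components of the four (two per finger) contact forces to sum to the object's weight
`m·g = 1.946 N`, so dividing by `g` recovers the mass exactly.  `examples/02_effort_landscape.py`
maps the effort across grip placements:

```
 offset [mm]    E (tip)   E (pulp)
         -12     2.8017     2.5455
          -6     0.7058     0.6733
           0     0.0719     0.0729
           6     0.7163     0.6751
          12     2.8453     2.5931
```

Pinching away from the center of mass loads the fingertips with a gravitational torsional
moment and effort rises steeply; pad ("pulp") grips are cheaper than fingertip grips
off-center.  The other examples run the full CMA-ES synthesis, the inverse kinematics in
isolation, and the measured-vs-simulated force validation.

A thin command-line interface wraps the same library calls:

```sh
precigrip synthesize run.yaml --out results/
precigrip validate measured.csv simulated.csv --out report/
precigrip fixtures sensing_device
precigrip qp-solve problem.json
```

## Layout

```
src/precigrip/        hand.py (kinematics), muscles.py, mechanics.py (grasp statics),
                      qp.py (effort QP), ik.py, cmaes.py, search.py (outer loop),
                      validation.py, cli.py, data/ (muscle table, reference force tables)
examples/             one short narrative script per capability
docs/methods.md       modeling assumptions, parameter choices, limitations
tests/                pytest suite, including tests/test_acceptance.py
```
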
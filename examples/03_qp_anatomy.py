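"""Dissect one grasp QP: constraints, residuals, and mass recovery.

Evaluates a centered tip pinch and inspects the solved QP: the equilibrium constraint
G f = [-m g; 0] forces the gravity-opposing components of the contact forces to sum to the
object's weight, so dividing by g recovers the object mass.
"""

import numpy as np

from precigrip import SearchConfig, build_parametric_hand, evaluate_candidate, sensing_device

model = build_parametric_hand()
device = sensing_device()
res = evaluate_candidate(model, device, SearchConfig(), np.zeros(4))
qp = res.qp

print(f"feasible: {res.feasible},  effort E = {qp.effort:.4f}")
print(f"residuals: equality {qp.residual_equality:.2e}, "
      f"friction facets {qp.residual_facets:.2e}, bounds {qp.residual_bounds:.2e}")

vertical = float(qp.forces[:, 2].sum())          # gravity-opposing components, N
mass_g = vertical / 9.81 * 1000.0
print(f"sum of vertical force components: {vertical:.4f} N")
print(f"recovered object mass: {mass_g:.1f} g   (device mass: {device.mass*1000:.1f} g)")
print("Equilibrium is an equality constraint, so any feasible solution supports the full "
      "weight exactly; the friction pyramids and activation bounds decide how cheaply.")
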
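"""Effort-minimization QP: oracles, invariants, and the infeasibility penalty."""

import numpy as np
import pytest
from scipy.optimize import minimize

from precigrip import (
    GraspProblem,
    assemble_facet_matrix,
    friction_pyramid,
    infeasibility_penalty,
    solve_grasp_qp,
)


def planar_toy(mass=1.0, mu_eff=0.5, f_max=20.0, beta=0.3):
    """Point mass pinched by two opposing horizontal contacts.

    One torque row per side, tau_k = f_kx_normal + beta * f_kz, each driven by an antagonist
    muscle pair with unit arms (+1 / -1 m) and equal maximum force.
    """
    # contacts coincide with the mass center: moment rows are trivially satisfied
    G = np.zeros((6, 6))
    G[:3, :3] = np.eye(3)
    G[:3, 3:] = np.eye(3)
    J = np.zeros((6, 2))
    J[0, 0] = 1.0   # tau_1 senses f1x
    J[2, 0] = beta  # ... and f1z
    J[3, 1] = -1.0  # tau_2 senses -f2x (its normal points -x)
    J[5, 1] = beta
    M = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    fmax = np.full(4, f_max)
    N = assemble_facet_matrix(
        [friction_pyramid([1, 0, 0], mu_eff), friction_pyramid([-1, 0, 0], mu_eff)]
    )
    return GraspProblem(J=J, M=M, f_max=fmax, G=G, N=N, mass=mass)


def planar_toy_grid_optimum(problem, beta=0.3, f_max=20.0):
    """Dense enumeration over the toy's feasible force distributions.

    With y components at zero (they only tighten friction) the force set reduces to the squeeze
    N and the vertical split z1.  Effort rises monotonically with N (both torques grow), so for
    each z1 on a dense grid the minimal squeeze is read off the facet inequalities exactly
    (each facet gives N >= nu_z z / (-nu_x)); the minimum-effort activations of a unit-arm
    antagonist pair are a = |tau| / f_max on the agonist side only.
    """
    w = problem.mass * 9.81

    def n_min(facets, sign, z):
        # force (sign * N, 0, z): nu_x sign N + nu_z z <= 0 for all facets
        lo = np.zeros_like(z)
        for nu in facets:
            denom = -nu[0] * sign
            if denom > 1e-12:
                lo = np.maximum(lo, np.outer(z, [nu[2]]).ravel() / denom)
        return lo

    F1 = problem.N[:12, 0:3]
    F2 = problem.N[12:, 3:6]
    z = np.linspace(-0.5, w + 0.5, 200_001)
    Nmin = np.maximum(n_min(F1, +1.0, z), n_min(F2, -1.0, w - z))
    tau1 = Nmin + beta * z
    tau2 = Nmin + beta * (w - z)
    feas = (np.abs(tau1) <= f_max) & (np.abs(tau2) <= f_max)
    E = np.where(feas, (tau1 / f_max) ** 2 + (tau2 / f_max) ** 2, np.inf)
    return float(E.min())


class TestSolveGraspQP:
    def test_massless_object_needs_no_effort(self):
        sol = solve_grasp_qp(planar_toy(mass=0.0))
        assert sol.ok
        assert sol.effort == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sol.forces, 0.0, atol=1e-8)
        np.testing.assert_allclose(sol.activations, 0.0, atol=1e-8)

    def test_matches_dense_grid_search_oracle(self):
        prob = planar_toy()
        sol = solve_grasp_qp(prob)
        assert sol.ok
        E_grid = planar_toy_grid_optimum(prob)
        assert sol.effort == pytest.approx(E_grid, abs=1e-4)

    def test_backends_agree(self):
        prob = planar_toy()
        e1 = solve_grasp_qp(prob, method="active-set").effort
        e2 = solve_grasp_qp(prob, method="slsqp").effort
        assert e1 == pytest.approx(e2, abs=1e-6)

    def test_doubling_mass_weakly_increases_effort(self):
        e1 = solve_grasp_qp(planar_toy(mass=1.0)).effort
        e2 = solve_grasp_qp(planar_toy(mass=2.0)).effort
        assert e2 >= e1 - 1e-9

    def test_residuals_within_tolerance_at_solution(self):
        prob = planar_toy()
        sol = solve_grasp_qp(prob)
        assert sol.residual_equality <= 1e-8 * prob.scale
        assert sol.residual_facets <= 1e-10
        assert sol.residual_bounds <= 1e-12

    def test_unsupportable_load_reported_infeasible(self):
        # a single horizontal contact with low friction cannot balance gravity
        G = np.zeros((6, 3))
        G[:3, :] = np.eye(3)
        N = friction_pyramid([1, 0, 0], 0.2).facet_normals
        J = np.zeros((3, 2))
        J[0, 0] = 1.0
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        prob = GraspProblem(J=J, M=M, f_max=[5.0, 5.0], G=G, N=N, mass=1.0)
        sol = solve_grasp_qp(prob)
        assert sol.status == "infeasible"
        assert not sol.ok

    def test_json_round_trip(self):
        prob = planar_toy()
        clone = GraspProblem.from_json(prob.to_json())
        assert solve_grasp_qp(clone).effort == pytest.approx(solve_grasp_qp(prob).effort, abs=1e-10)

    def test_dimension_validation(self):
        with pytest.raises(ValueError):
            GraspProblem(J=np.zeros((5, 2)), M=np.zeros((2, 2)), f_max=[1, 1],
                         G=np.zeros((6, 5)), N=np.zeros((12, 5)), mass=1.0)


def random_small_problem(rng, n_muscles=6):
    """Random two-contact problem with opposing-ish normals; may be infeasible.

    Muscles come in antagonist pairs with independent random arm rows, so the torque cone spans
    all of torque space and feasibility hinges on magnitudes and friction only.
    """
    d = 3
    p1 = np.array([0.03, 0, 0]) + rng.normal(scale=0.004, size=3)
    p2 = np.array([-0.03, 0, 0]) + rng.normal(scale=0.004, size=3)
    # two point contacts cannot resist a moment about their connecting line, so static
    # equilibrium requires the center of mass to lie in the plane spanned by that line and
    # gravity (passing through the line)
    axis = p2 - p1
    com = (p1 + p2) / 2 + rng.uniform(-0.2, 0.2) * axis \
        + rng.uniform(-0.005, 0.005) * np.array([0.0, 0.0, 1.0])
    n1 = np.array([-1.0, 0, 0]) + rng.normal(scale=0.1, size=3)
    n2 = np.array([1.0, 0, 0]) + rng.normal(scale=0.1, size=3)
    n1, n2 = n1 / np.linalg.norm(n1), n2 / np.linalg.norm(n2)
    from precigrip.mechanics import skew

    G = np.zeros((6, 6))
    G[:3, :3] = G[:3, 3:] = np.eye(3)
    G[3:, :3] = skew(p1 - com)
    G[3:, 3:] = skew(p2 - com)
    N = assemble_facet_matrix([friction_pyramid(n1, 0.6), friction_pyramid(n2, 0.6)])
    J = rng.normal(scale=0.05, size=(6, d))
    D = rng.normal(scale=0.02, size=(n_muscles // 2, d))
    M = np.vstack([D, -D])[:n_muscles]
    fmax = rng.uniform(5.0, 20.0, n_muscles)
    return GraspProblem(J=J, M=M, f_max=fmax, G=G, N=N, mass=0.2)


def multistart_reference(problem, n_starts=50, seed=0):
    """Independent oracle: a general nonlinear solver from many random starting points."""
    rng = np.random.default_rng(seed)
    from precigrip.qp import _independent_rows

    A_eq, b_eq = _independent_rows(*problem.equality())
    A_ub = problem.facet_inequality()
    nf, nm = problem.n_forces, problem.n_muscles
    bounds = [(None, None)] * nf + [(0.0, 1.0)] * nm
    best = np.inf
    for _ in range(n_starts):
        x0 = np.concatenate([rng.normal(scale=1.0, size=nf), rng.uniform(0, 1, nm)])
        res = minimize(
            lambda x: float(x[nf:] @ x[nf:]),
            x0,
            jac=lambda x: np.concatenate([np.zeros(nf), 2 * x[nf:]]),
            method="SLSQP",
            bounds=bounds,
            constraints=[
                {"type": "eq", "fun": lambda x: A_eq @ x - b_eq},
                {"type": "ineq", "fun": lambda x: -A_ub @ x},
            ],
            options={"maxiter": 300, "ftol": 1e-12},
        )
        if res.success:
            x = res.x
            r_eq = np.max(np.abs(A_eq @ x - b_eq))
            r_in = np.max(A_ub @ x, initial=0.0)
            if r_eq < 1e-6 and r_in < 1e-6:
                best = min(best, float(x[nf:] @ x[nf:]))
    return best


def test_qp_matches_multistart_nonlinear_oracle():
    rng = np.random.default_rng(7)
    checked = 0
    attempts = 0
    while checked < 3 and attempts < 30:
        attempts += 1
        prob = random_small_problem(rng)
        sol = solve_grasp_qp(prob)
        if not sol.ok:
            continue
        ref = multistart_reference(prob, seed=attempts)
        assert np.isfinite(ref)
        assert sol.effort == pytest.approx(ref, abs=1e-5)
        checked += 1
    assert checked == 3


class TestInfeasibilityPenalty:
    def test_zero_deviation_gives_the_offset(self):
        q = np.ones(21)
        assert infeasibility_penalty(q, q) == pytest.approx(100.0)

    def test_small_deviation_arithmetic(self):
        q0 = np.zeros(21)
        q = q0.copy()
        q[3] = 0.1
        assert infeasibility_penalty(q, q0) == pytest.approx(100.01)

    def test_penalty_monotone_in_each_deviation(self, rng):
        q0 = rng.normal(size=21)
        base = infeasibility_penalty(q0, q0)
        for j in range(0, 21, 5):
            prev = base
            for step in (0.1, 0.2, 0.4):
                q = q0.copy()
                q[j] += step
                val = infeasibility_penalty(q, q0)
                assert val > prev
                prev = val

    def test_penalty_exceeds_any_feasible_effort(self):
        # E = sum a_i^2 <= 37; any infeasible posture must rank below any feasible one
        assert infeasibility_penalty(np.zeros(21), np.zeros(21)) > 37.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            infeasibility_penalty(np.zeros(3), np.zeros(4))
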
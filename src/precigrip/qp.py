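"""Muscle-effort minimization as a convex quadratic program.

Decision vector ``x = [f_1 ... f_n, a_1 ... a_nm]`` stacks the contact forces and muscle
activations.  The objective is the muscle effort ``E = sum a_i^2`` (``1/2 x^T diag(0, 2 I) x`` up
to the conventional factor), subject to

* object force/moment equilibrium          ``G f = [-m g; 0]``
* linearized friction cones                ``N f <= 0``
* fingertip force / muscle torque balance  ``J^T f - M^T F_max a = 0``
* activation bounds                        ``0 <= a_i <= 1``.

The equality system may be rank-deficient (soft-contact pairs share a segment), so feasibility is
judged by residual tolerances rather than rank.  The solver pipeline is: an LP feasibility probe
(HiGHS) that also supplies a feasible vertex, then a primal active-set iteration whose
equality-constrained subproblems are solved in the constraint null space (exact for these small
dense problems); optionally a secondary strictly convex solve picks the minimum-norm force
vector among the effort-optimal solutions, making reported forces deterministic.  An SLSQP
backend is available as an independent cross-check; any convex backend must reproduce the
optimal effort to well below 1e-6.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .mechanics import GRAVITY

FEAS_TOL = 1e-8
PENALTY_OFFSET = 100.0  # exceeds the largest possible effort (37 muscles at full activation)


@dataclass(frozen=True)
class GraspProblem:
    """All matrices of one grasp QP instance.

    Shapes for the full hand pipeline are J: (3n, 21), M: (37, 21), G: (6, 3n), N: (12n, 3n);
    smaller toy instances with the same block structure are accepted (dimensions are validated
    for mutual consistency, not fixed).
    """

    J: np.ndarray            # (3n, d) contact Jacobian
    M: np.ndarray            # (nm, d) moment-arm matrix (m)
    f_max: np.ndarray        # (nm,) maximum muscle forces (N)
    G: np.ndarray            # (6, 3n) grasp matrix
    N: np.ndarray            # (nf, 3n) stacked friction-facet normals
    mass: float              # kg
    g: np.ndarray = field(default_factory=lambda: GRAVITY.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "J", np.asarray(self.J, float))
        object.__setattr__(self, "M", np.asarray(self.M, float))
        object.__setattr__(self, "f_max", np.asarray(self.f_max, float).reshape(-1))
        object.__setattr__(self, "G", np.asarray(self.G, float))
        object.__setattr__(self, "N", np.asarray(self.N, float))
        object.__setattr__(self, "g", np.asarray(self.g, float).reshape(3))
        n3 = self.J.shape[0]
        if n3 % 3 or self.G.shape != (6, n3) or self.N.shape[1] != n3:
            raise ValueError("inconsistent contact dimensions")
        if self.M.shape[1] != self.J.shape[1]:
            raise ValueError("J and M must share the joint dimension")
        if self.f_max.shape[0] != self.M.shape[0]:
            raise ValueError("f_max must have one entry per muscle")
        if self.mass < 0:
            raise ValueError("mass must be non-negative")

    @property
    def n_contacts(self) -> int:
        return self.J.shape[0] // 3

    @property
    def n_joints(self) -> int:
        return self.J.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.M.shape[0]

    @property
    def n_forces(self) -> int:
        return self.J.shape[0]

    # -- constraint assembly ------------------------------------------------
    def equality(self) -> tuple[np.ndarray, np.ndarray]:
        nf, nm = self.n_forces, self.n_muscles
        A = np.zeros((6 + self.n_joints, nf + nm))
        A[:6, :nf] = self.G
        A[6:, :nf] = self.J.T
        A[6:, nf:] = -self.M.T * self.f_max[None, :]
        b = np.concatenate([-self.mass * self.g, np.zeros(3), np.zeros(self.n_joints)])
        return A, b

    def facet_inequality(self) -> np.ndarray:
        nf, nm = self.n_forces, self.n_muscles
        A = np.zeros((self.N.shape[0], nf + nm))
        A[:, :nf] = self.N
        return A

    @property
    def scale(self) -> float:
        return max(1.0, self.mass * float(np.linalg.norm(self.g)))

    # -- serialization (oracle interchange) ---------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "J": self.J.tolist(), "M": self.M.tolist(), "f_max": self.f_max.tolist(),
                "G": self.G.tolist(), "N": self.N.tolist(), "mass": self.mass,
                "g": self.g.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str | Path) -> "GraspProblem":
        if isinstance(text, Path):
            text = text.read_text()
        d = json.loads(text)
        return cls(
            J=np.array(d["J"]), M=np.array(d["M"]), f_max=np.array(d["f_max"]),
            G=np.array(d["G"]), N=np.array(d["N"]), mass=float(d["mass"]),
            g=np.array(d.get("g", GRAVITY)),
        )


@dataclass(frozen=True)
class QPSolution:
    """Solved grasp QP: stacked decision vector, effort, and feasibility residuals."""

    x: np.ndarray
    forces: np.ndarray        # (n, 3)
    activations: np.ndarray   # (nm,)
    effort: float             # E = sum a_i^2
    status: str               # "optimal" | "infeasible"
    residual_equality: float
    residual_facets: float
    residual_bounds: float

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _residuals(problem: GraspProblem, x: np.ndarray) -> tuple[float, float, float]:
    A, b = problem.equality()
    nf = problem.n_forces
    a = x[nf:]
    r_eq = float(np.max(np.abs(A @ x - b))) if A.size else 0.0
    r_fac = float(np.max(problem.N @ x[:nf], initial=0.0))
    r_bnd = float(max(np.max(-a, initial=0.0), np.max(a - 1.0, initial=0.0)))
    return r_eq, r_fac, r_bnd


def _make_solution(problem: GraspProblem, x: np.ndarray, status: str) -> QPSolution:
    nf = problem.n_forces
    a = np.clip(x[nf:], 0.0, 1.0)
    x = np.concatenate([x[:nf], a])
    r_eq, r_fac, r_bnd = _residuals(problem, x)
    return QPSolution(
        x=x,
        forces=x[:nf].reshape(-1, 3),
        activations=a,
        effort=float(a @ a),
        status=status,
        residual_equality=r_eq,
        residual_facets=r_fac,
        residual_bounds=r_bnd,
    )


def _infeasible(problem: GraspProblem) -> QPSolution:
    nv = problem.n_forces + problem.n_muscles
    x = np.zeros(nv)
    return QPSolution(x, x[: problem.n_forces].reshape(-1, 3), x[problem.n_forces:],
                      float("inf"), "infeasible", float("inf"), float("inf"), float("inf"))


def _polish(problem: GraspProblem, x: np.ndarray, tol: float) -> np.ndarray | None:
    """Null-space re-solve of the equality-constrained QP on the detected active set."""
    A_eq, b_eq = problem.equality()
    nf, nm = problem.n_forces, problem.n_muscles
    nv = nf + nm
    a = x[nf:]
    Nf = problem.N @ x[:nf]
    rows = [A_eq]
    rhs = [b_eq]
    act_facets = np.where(Nf > -tol)[0]
    if act_facets.size:
        F = np.zeros((act_facets.size, nv))
        F[:, :nf] = problem.N[act_facets]
        rows.append(F)
        rhs.append(np.zeros(act_facets.size))
    for bound, val in ((a < tol, 0.0), (a > 1 - tol, 1.0)):
        idx = np.where(bound)[0]
        if idx.size:
            B = np.zeros((idx.size, nv))
            B[np.arange(idx.size), nf + idx] = 1.0
            rows.append(B)
            rhs.append(np.full(idx.size, val))
    C = np.vstack(rows)
    d = np.concatenate(rhs)
    xp, *_ = np.linalg.lstsq(C, d, rcond=None)
    if np.max(np.abs(C @ xp - d)) > 1e-9 * problem.scale:
        return None
    Z = null_space(C)
    if Z.size:
        H = np.zeros(nv)
        H[nf:] = 1.0
        ZHZ = (Z * H[:, None]).T @ Z
        rhs_y = -(Z * H[:, None]).T @ xp
        y, *_ = np.linalg.lstsq(ZHZ, rhs_y, rcond=None)
        xp = xp + Z @ y
    r_eq, r_fac, r_bnd = _residuals(problem, xp)
    if max(r_eq / problem.scale, r_fac, r_bnd) > 1e-7:
        return None
    return xp


def _active_set_qp(
    H: np.ndarray,
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    C: np.ndarray,
    d: np.ndarray,
    x0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 400,
) -> np.ndarray:
    """Primal active-set method for ``min 1/2 x^T diag(H) x`` s.t. ``A_eq x = b_eq, C x <= d``.

    ``x0`` must be feasible (an LP vertex).  Equality-constrained subproblems are solved in the
    null space of the working constraints with least-squares pseudo-inverses, which tolerates
    the rank deficiency of soft-contact pairs and of the positive-semidefinite Hessian.
    """
    x = x0.copy()
    work = set(np.where(C @ x - d > -tol)[0])

    def subproblem(active: set) -> np.ndarray:
        rows = [A_eq] if A_eq.size else []
        rhs = [b_eq] if A_eq.size else []
        if active:
            idx = sorted(active)
            rows.append(C[idx])
            rhs.append(d[idx])
        Ct = np.vstack(rows)
        dt = np.concatenate(rhs)
        xp, *_ = np.linalg.lstsq(Ct, dt, rcond=None)
        Z = null_space(Ct)
        if Z.size:
            ZHZ = (Z * H[:, None]).T @ Z
            y, *_ = np.linalg.lstsq(ZHZ, -(Z * H[:, None]).T @ xp, rcond=None)
            xp = xp + Z @ y
        return xp

    for _ in range(max_iter):
        x_star = subproblem(work)
        p = x_star - x
        if np.max(np.abs(p)) < 1e-11:
            # check multipliers of the working inequalities
            g = H * x
            if not work:
                return x
            idx = sorted(work)
            K = np.vstack([A_eq, C[idx]]).T if A_eq.size else C[idx].T
            mults, *_ = np.linalg.lstsq(K, -g, rcond=None)
            lam = mults[A_eq.shape[0]:] if A_eq.size else mults
            j_min = int(np.argmin(lam))
            if lam[j_min] >= -1e-9:
                return x
            work.remove(idx[j_min])
            continue
        # largest feasible step along p
        Cp = C @ p
        slack = d - C @ x
        blocking = -1
        alpha = 1.0
        for j in np.where(Cp > 1e-13)[0]:
            if j in work:
                continue
            a_j = slack[j] / Cp[j]
            if a_j < alpha:
                alpha = a_j
                blocking = j
        x = x + max(alpha, 0.0) * p
        if blocking >= 0:
            work.add(blocking)
    return x


def _min_norm_forces(problem: GraspProblem, x: np.ndarray) -> np.ndarray:
    """Among effort-optimal solutions with activations fixed, pick the minimum-norm f."""
    nf = problem.n_forces
    a = x[nf:]
    A_f = problem.equality()[0][:, :nf]
    b_f = problem.equality()[1] - problem.equality()[0][:, nf:] @ a
    f = _active_set_qp(
        np.ones(nf), A_f, b_f, problem.N, np.zeros(problem.N.shape[0]), x[:nf].copy()
    )
    cand = np.concatenate([f, a])
    r_eq, r_fac, r_bnd = _residuals(problem, cand)
    if max(r_eq / problem.scale, r_fac, r_bnd) <= 1e-7 and f @ f <= x[:nf] @ x[:nf] + 1e-9:
        return cand
    return x


def _independent_rows(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A maximal linearly independent subset of the rows of [A | b]."""
    from scipy.linalg import qr

    if A.size == 0:
        return A, b
    _, R, piv = qr(A.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)))
    rows = np.sort(piv[:rank])
    return A[rows], b[rows]


def solve_grasp_qp(
    problem: GraspProblem,
    method: str = "active-set",
    tie_break: bool = True,
) -> QPSolution:
    """Solve the grasp QP to its global minimum, or report infeasibility.

    ``method`` selects the convex backend: "active-set" (the exact primal active-set iteration,
    default) or "slsqp" (an independent general-purpose solver, polished on its detected active
    set).  Any backend must agree on the optimal effort to well below 1e-6.
    """
    A_eq, b_eq = problem.equality()
    nf, nm = problem.n_forces, problem.n_muscles
    nv = nf + nm
    A_ub = problem.facet_inequality()
    lb = np.concatenate([np.full(nf, -np.inf), np.zeros(nm)])
    ub = np.concatenate([np.full(nf, np.inf), np.ones(nm)])

    # LP feasibility probe: HiGHS provides a reliable infeasibility certificate and a vertex
    lp = linprog(
        c=np.zeros(nv), A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=np.zeros(A_ub.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if not lp.success:
        return _infeasible(problem)
    x0 = lp.x

    H = np.zeros(nv)
    H[nf:] = 2.0
    # stack facet rows and activation-bound rows into one inequality system C x <= d
    bound_up = np.zeros((nm, nv))
    bound_up[:, nf:] = np.eye(nm)
    C = np.vstack([A_ub, bound_up, -bound_up])
    d = np.concatenate([np.zeros(A_ub.shape[0]), np.ones(nm), np.zeros(nm)])

    if method == "active-set":
        x = _active_set_qp(H, A_eq, b_eq, C, d, x0)
    elif method == "slsqp":
        # SLSQP cannot digest linearly dependent equality rows (zero moment rows, duplicated
        # soft-pair rows); hand it an independent subset, residuals are re-verified below
        A_red, b_red = _independent_rows(A_eq, b_eq)
        res = minimize(
            lambda x: float(x[nf:] @ x[nf:]),
            x0,
            jac=lambda x: H * x,
            method="SLSQP",
            bounds=list(zip(lb, ub)),
            constraints=[
                {"type": "eq", "fun": lambda x: A_red @ x - b_red, "jac": lambda x: A_red},
                {"type": "ineq", "fun": lambda x: -A_ub @ x, "jac": lambda x: -A_ub},
            ],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        x = res.x
        for tol in (1e-6, 1e-5, 1e-4):
            polished = _polish(problem, x, tol)
            if polished is not None and polished[nf:] @ polished[nf:] <= x[nf:] @ x[nf:] + 1e-9:
                x = polished
                break
    else:
        raise ValueError(f"unknown QP backend {method!r}")

    r_eq, r_fac, r_bnd = _residuals(problem, x)
    if max(r_eq / problem.scale, r_fac, r_bnd) > 1e-6:
        return _infeasible(problem)
    if tie_break:
        x = _min_norm_forces(problem, x)
    return _make_solution(problem, x, "optimal")


def infeasibility_penalty(q: np.ndarray, q0: np.ndarray, offset: float = PENALTY_OFFSET) -> float:
    """Effort surrogate for postures with no feasible force solution.

    ``offset + sum (q_j - q0_j)^2``: the offset exceeds the largest attainable effort (37), so
    any feasible posture beats any infeasible one, and infeasible postures are ranked by their
    squared deviation from the initial posture.
    """
    q = np.asarray(q, float).reshape(-1)
    q0 = np.asarray(q0, float).reshape(-1)
    if q.shape != q0.shape:
        raise ValueError("q and q0 must have the same length")
    d = q - q0
    return float(offset + d @ d)
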
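"""Inverse kinematics of the hand against a grasped object.

Finds the carpal pose (p, e) and joint angles q that bring the active fingertip contact sites to
their target positions on the object surface while keeping the 65-sphere skin proxy out of the
object, by minimizing the weighted objective

    L = w1 sum_l |d_l(p, q, e) - d_l^0|^2  +  w2 sum_m s_m^2
      + w3 |p - p^0|^2 + w4 |e - e^0|^2 + w5 |q - q^0|^2

with a quasi-Newton method (bounded L-BFGS).  ``d_l`` are the active fingertip sites, ``s_m`` the
sphere penetration depths, and (p0, e0, q0) the initial, anatomically natural pose that the last
three terms regularize toward.  Only fingers participating in the grasp contribute the target
term.

Default weights (SI units) encode the priority ordering: contact and non-penetration dominate
(w1 = w2 = 100), base-pose deviation is mildly penalized (w3 = w4 = 1), and joint naturalness
regularizes weakly (w5 = 0.1).  The penetration term uses depth squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .hand import FINGERS, BasePose, HandModel, KinematicState, forward_kinematics, point_jacobian
from .mechanics import RigidObject
from .muscles import N_JOINTS


@dataclass(frozen=True)
class IKWeights:
    w1: float = 100.0   # fingertip target attraction
    w2: float = 100.0   # skin non-penetration
    w3: float = 1.0     # carpal position regularization
    w4: float = 1.0     # carpal orientation regularization
    w5: float = 0.1     # joint naturalness

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4, self.w5) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class IKProblem:
    """Targets, initial pose, weights, and the object providing penetration terms."""

    model: HandModel
    obj: RigidObject | None
    targets: dict[str, np.ndarray]       # finger -> world target of its contact site
    q0: np.ndarray
    base0: BasePose = field(default_factory=BasePose)
    weights: IKWeights = field(default_factory=IKWeights)
    contact_style: str = "tip"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one active fingertip target required")
        unknown = set(self.targets) - set(FINGERS)
        if unknown:
            raise ValueError(f"unknown fingers {sorted(unknown)}")
        object.__setattr__(self, "q0", np.asarray(self.q0, float).reshape(N_JOINTS))

    @property
    def active_fingers(self) -> list[str]:
        return [f for f in FINGERS if f in self.targets]


@dataclass(frozen=True)
class IKSolution:
    base: BasePose
    q: np.ndarray
    L: float
    terms: dict[str, float]
    converged: bool
    iterations: int
    trace: np.ndarray | None = None   # per-iteration L values


def _site_positions(problem: IKProblem, state: KinematicState) -> dict[str, np.ndarray]:
    return {
        f: state.point_on(problem.model.fingertip_segment(f),
                          problem.model.contact_site(f, problem.contact_style))
        for f in problem.active_fingers
    }


def objective_L(
    problem: IKProblem, p: np.ndarray, e: np.ndarray, q: np.ndarray
) -> tuple[float, dict[str, float]]:
    """Evaluate L and its per-term breakdown at the given state."""
    base = BasePose(np.asarray(p, float), _wrap_rotvec(np.asarray(e, float)))
    state = forward_kinematics(problem.model, q, base)
    w = problem.weights

    sites = _site_positions(problem, state)
    t_target = sum(float(np.sum((sites[f] - problem.targets[f]) ** 2)) for f in sites)
    if problem.obj is not None and w.w2 > 0:
        radii = np.array([s.radius for s in problem.model.spheres])
        depths = np.maximum(0.0, radii - problem.obj.signed_distance(state.sphere_centers))
        t_pen = float(np.sum(depths**2))
    else:
        t_pen = 0.0
    dp = base.p - problem.base0.p
    de = base.e - problem.base0.e
    dq = np.asarray(q, float) - problem.q0
    terms = {
        "target": w.w1 * t_target,
        "penetration": w.w2 * t_pen,
        "base_position": w.w3 * float(dp @ dp),
        "base_orientation": w.w4 * float(de @ de),
        "posture": w.w5 * float(dq @ dq),
    }
    return sum(terms.values()), terms


def _wrap_rotvec(e: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(e)
    if n >= np.pi:
        e = e * (1.0 - 2.0 * np.pi / n)
        return _wrap_rotvec(e)
    return e


def _objective_and_grad(problem: IKProblem, x: np.ndarray) -> tuple[float, np.ndarray]:
    model, w = problem.model, problem.weights
    p, e, q = x[:3], x[3:6], x[6:]
    base = BasePose(p, _wrap_rotvec(e))
    state = forward_kinematics(model, q, base)

    grad_p = np.zeros(3)
    grad_q = np.zeros(N_JOINTS)
    L = 0.0

    sites = _site_positions(problem, state)
    for f, pos in sites.items():
        r = pos - problem.targets[f]
        L += w.w1 * float(r @ r)
        seg = model.fingertip_segment(f)
        Jl = point_jacobian(model, state, pos[None, :], [seg])
        grad_q += 2.0 * w.w1 * (Jl.T @ r)
        grad_p += 2.0 * w.w1 * r

    if problem.obj is not None and w.w2 > 0:
        radii = np.array([s.radius for s in model.spheres])
        dist = problem.obj.signed_distance(state.sphere_centers)
        depths = np.maximum(0.0, radii - dist)
        pen = depths > 0
        L += w.w2 * float(np.sum(depths**2))
        if np.any(pen):
            gd = problem.obj.distance_gradient(state.sphere_centers[pen])
            owners = [model.spheres[i].owner for i in np.where(pen)[0]]
            Js = point_jacobian(model, state, state.sphere_centers[pen], owners)
            for row, (s_m, g_m) in enumerate(zip(depths[pen], gd)):
                grad_q += 2.0 * w.w2 * s_m * (-(Js[3 * row: 3 * row + 3].T @ g_m))
                grad_p += 2.0 * w.w2 * s_m * (-g_m)

    dp = p - problem.base0.p
    de = e - problem.base0.e
    dq = q - problem.q0
    L += w.w3 * float(dp @ dp) + w.w4 * float(de @ de) + w.w5 * float(dq @ dq)
    grad_p += 2.0 * w.w3 * dp
    grad_q += 2.0 * w.w5 * dq

    # orientation gradient by central differences (3 components only)
    grad_e = np.zeros(3)
    h = 1e-6
    for i in range(3):
        for s, sign in ((h, 1.0), (-h, -1.0)):
            ei = e.copy()
            ei[i] += s
            Li, _ = objective_L(problem, p, ei, q)
            grad_e[i] += sign * Li
    grad_e /= 2 * h

    return L, np.concatenate([grad_p, grad_e, grad_q])


def solve_ik(
    problem: IKProblem,
    optimize_base: bool = True,
    free_joints: np.ndarray | None = None,
    max_iterations: int = 500,
    gtol: float = 1e-6,
    keep_trace: bool = False,
) -> IKSolution:
    """Minimize L from the problem's initial state; returns the best iterate found.

    ``free_joints`` optionally restricts optimization to a boolean subset of the 21 angles
    (others stay pinned at q0); ``optimize_base=False`` pins the carpal pose.  Deterministic for
    fixed inputs.
    """
    model = problem.model
    x0 = np.concatenate([problem.base0.p, problem.base0.e, problem.q0])

    lb = np.full(x0.shape, -np.inf)
    ub = np.full(x0.shape, np.inf)
    lb[3:6], ub[3:6] = -3.0, 3.0
    if model.joint_limits is not None:
        lb[6:] = model.joint_limits[:, 0]
        ub[6:] = model.joint_limits[:, 1]
    if not optimize_base:
        lb[:6] = ub[:6] = x0[:6]
    if free_joints is not None:
        pinned = ~np.asarray(free_joints, bool)
        lb[6:][pinned] = ub[6:][pinned] = problem.q0[pinned]
    x0 = np.clip(x0, lb, ub)

    trace: list[float] = []

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        return _objective_and_grad(problem, x)

    def cb(xk: np.ndarray) -> None:
        trace.append(objective_L(problem, xk[:3], xk[3:6], xk[6:])[0])

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        callback=cb if keep_trace else None,
        options={"maxiter": max_iterations, "ftol": 1e-14, "gtol": gtol, "maxcor": 30},
    )
    p, e, q = res.x[:3], _wrap_rotvec(res.x[3:6]), res.x[6:]
    L, terms = objective_L(problem, p, e, q)
    return IKSolution(
        base=BasePose(p, e),
        q=q,
        L=L,
        terms=terms,
        converged=bool(res.success),
        iterations=int(res.nit),
        trace=np.array(trace) if keep_trace else None,
    )
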
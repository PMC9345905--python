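"""Outer grasp-posture search.

Searches the in-plane contact coordinates (u, v) of each grasping fingertip on its assigned
object surface with CMA-ES.  Each candidate is evaluated by the full pipeline: inverse
kinematics brings the fingertip sites to the candidate points, soft-contact pairs are built at
the converged contact centroids, and the muscle-effort QP is solved; the candidate's score is
the optimal effort E, or the infeasibility penalty when no force solution exists (or the finger
cannot reach).  The search stops when the best effort stalls or a generation cap is reached.

The grasp is planned against a friction coefficient of half the actual surface value — the
safety margin the central nervous system is assumed to apply — so all friction pyramids use
``mu_eff = mu_actual / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .cmaes import CMAResult, cma_es
from .hand import BasePose, HandModel, forward_kinematics, point_jacobian
from .ik import IKProblem, IKSolution, IKWeights, solve_ik
from .mechanics import (
    Contact,
    PlanarSurface,
    RigidObject,
    assemble_facet_matrix,
    friction_pyramid,
    grasp_matrix,
    soft_contact_pair,
)
from .muscles import DEFAULT_STRENGTH_SCALE, MuscleSet, load_muscle_table
from .qp import GraspProblem, QPSolution, infeasibility_penalty, solve_grasp_qp

REACH_TOL = 0.003  # m: IK must place each site within this distance of its target


def effective_mu(mu_actual: float) -> float:
    """Planning friction coefficient: half the actual value (grip safety margin)."""
    if mu_actual < 0:
        raise ValueError("friction coefficient must be non-negative")
    return mu_actual / 2.0


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the outer contact-position search."""

    finger_surfaces: dict[str, str] = field(
        default_factory=lambda: {"thumb": "plate_a", "index": "plate_b"}
    )
    contact_style: str = "tip"               # "tip" or "pulp"
    population: int | None = None            # default 4 + floor(3 ln d)
    sigma0: float | None = None              # default: half the largest surface dimension
    max_generations: int = 200
    tol_stall: float = 1e-6
    stall_generations: int = 20
    seed: int = 0
    ik_weights: IKWeights = field(default_factory=IKWeights)
    ik_max_iterations: int = 300
    initial_uv: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.finger_surfaces:
            raise ValueError("at least one finger-to-surface assignment required")


@dataclass(frozen=True)
class CandidateResult:
    """One evaluated candidate: effort plus full diagnostics."""

    effort: float
    feasible: bool
    uv: dict[str, tuple[float, float]]
    ik: IKSolution
    qp: QPSolution | None
    contacts: tuple[Contact, ...]
    reach_errors: dict[str, float]


@dataclass(frozen=True)
class PostureSolution:
    """Converged grasp: contact coordinates, posture, forces, activations, and diagnostics."""

    uv: dict[str, tuple[float, float]]
    candidate: CandidateResult
    effort: float
    generations: int
    evaluations: int
    trace: np.ndarray
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# initial pose heuristic
# ---------------------------------------------------------------------------

def _expected_force_dir(obj: RigidObject, surface: PlanarSurface, mu_eff: float) -> np.ndarray:
    """Anticipated direction of the contact force on this surface: inward normal tilted
    against gravity by the load share carried at the friction-cone margin."""
    n_in = obj.vector_to_world(surface.normal)
    weight = obj.mass * np.linalg.norm(obj.g)
    if weight <= 0 or mu_eff <= 0:
        return n_in
    up = -obj.g / np.linalg.norm(obj.g)
    normal_mag = (weight / 2.0) / (mu_eff * np.cos(np.pi / 12))
    f = normal_mag * n_in + (weight / 2.0) * up
    return f / np.linalg.norm(f)


def initial_base_pose(
    model: HandModel,
    obj: RigidObject,
    config: SearchConfig,
    targets: dict[str, np.ndarray],
) -> BasePose:
    """Carpal pose aligning the hand's contact sites and their outward site normals with the
    target points and the anticipated contact-force directions.

    The site normal (along the distal phalanx toward the contact site) is aligned with the
    expected force line so that contact forces pass close to the distal joint axes, which is
    what makes the smallest-effort solutions reachable for the weak distal muscles.
    """
    fingers = sorted(targets, key=["thumb", "index", "middle", "ring", "little"].index)
    q0 = model.natural_posture(config.contact_style)
    state = forward_kinematics(model, q0, BasePose())
    mu_eff = effective_mu(obj.mu_actual)

    sites, normals, fdirs, tpts = [], [], [], []
    for f in fingers:
        seg = model.fingertip_segment(f)
        local = model.contact_site(f, config.contact_style)
        sites.append(state.point_on(seg, local))
        normals.append(state.rotations[seg] @ (local / np.linalg.norm(local)))
        surf = obj.surface(config.finger_surfaces[f])
        fdirs.append(_expected_force_dir(obj, surf, mu_eff))
        tpts.append(np.asarray(targets[f], float))

    a_vecs, b_vecs, wts = [], [], []
    if len(fingers) >= 2:
        span_a = sites[1] - sites[0]
        span_b = tpts[1] - tpts[0]
        a_vecs.append(span_a / np.linalg.norm(span_a))
        b_vecs.append(span_b / np.linalg.norm(span_b))
        wts.append(1.0)
    for s_n, f_d in zip(normals, fdirs):
        a_vecs.append(s_n)
        b_vecs.append(f_d)
        wts.append(1.0)
    # roll: keep the fingers pointing across the surface width
    surf0 = obj.surface(config.finger_surfaces[fingers[0]])
    approach = -obj.vector_to_world(surf0.u_axis)
    a_vecs.append(np.array([0.0, 0.0, 1.0]))
    b_vecs.append(approach)
    wts.append(0.3)

    rot, _ = Rotation.align_vectors(b_vecs, a_vecs, weights=wts)
    R = rot.as_matrix()
    p = np.mean(tpts, axis=0) - R @ np.mean(sites, axis=0)
    e = rot.as_rotvec()
    if np.linalg.norm(e) >= np.pi:
        e = e * (1.0 - 2 * np.pi / np.linalg.norm(e))
    return BasePose(p, e)


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

def _build_contacts(
    model: HandModel,
    obj: RigidObject,
    config: SearchConfig,
    ik_sol: IKSolution,
    fingers: list[str],
) -> tuple[tuple[Contact, ...], np.ndarray, np.ndarray, np.ndarray]:
    """Soft-contact pairs at the converged contact centroids, plus the G, N, J matrices."""
    state = forward_kinematics(model, ik_sol.q, ik_sol.base)
    mu_eff = effective_mu(obj.mu_actual)
    contacts: list[Contact] = []
    pyramids = []
    for f in fingers:
        surf = obj.surface(config.finger_surfaces[f])
        seg = model.fingertip_segment(f)
        site = state.point_on(seg, model.contact_site(f, config.contact_style))
        o_w = obj.to_world(surf.origin)
        u_w = obj.vector_to_world(surf.u_axis)
        v_w = obj.vector_to_world(surf.v_axis)
        n_w = obj.vector_to_world(surf.normal)
        rel = site - o_w
        centroid = o_w + np.clip(rel @ u_w, -surf.half_u, surf.half_u) * u_w \
            + np.clip(rel @ v_w, -surf.half_v, surf.half_v) * v_w
        lateral = state.rotations[seg] @ np.array([0.0, 1.0, 0.0])
        lateral -= (lateral @ n_w) * n_w
        if np.linalg.norm(lateral) < 1e-9:
            lateral = v_w if surf.half_v >= surf.half_u else u_w
        pair = soft_contact_pair(centroid, n_w, lateral, finger=f, segment=seg)
        contacts.extend(pair)
        pyr = friction_pyramid(n_w, mu_eff)
        pyramids.extend([pyr, pyr])
    pts = np.array([c.point for c in contacts])
    owners = [c.segment for c in contacts]
    J = point_jacobian(model, state, pts, owners)
    G = grasp_matrix(contacts, obj.com_world)
    N = assemble_facet_matrix(pyramids)
    return tuple(contacts), G, N, J


def evaluate_candidate(
    model: HandModel,
    obj: RigidObject,
    config: SearchConfig,
    uv: np.ndarray | dict[str, tuple[float, float]],
    muscle_set: MuscleSet | None = None,
) -> CandidateResult:
    """Full pipeline for one candidate contact placement.

    ``uv`` stacks (u, v) per active finger (finger order: thumb..little).  Never raises on
    infeasibility: unreachable targets and force-infeasible postures return the penalty effort.
    """
    muscle_set = muscle_set or load_muscle_table(strength_scale=DEFAULT_STRENGTH_SCALE)
    fingers = sorted(config.finger_surfaces, key=["thumb", "index", "middle", "ring", "little"].index)
    if isinstance(uv, dict):
        uv_arr = np.array([uv[f] for f in fingers], float).reshape(-1)
    else:
        uv_arr = np.asarray(uv, float).reshape(-1)
    if uv_arr.size != 2 * len(fingers):
        raise ValueError("uv must provide (u, v) per active finger")
    uv_map = {f: (float(uv_arr[2 * i]), float(uv_arr[2 * i + 1])) for i, f in enumerate(fingers)}

    targets = {
        f: obj.to_world(obj.surface(config.finger_surfaces[f]).point_at(*uv_map[f]))
        for f in fingers
    }
    q0 = model.natural_posture(config.contact_style)
    base0 = initial_base_pose(model, obj, config, targets)
    ik_prob = IKProblem(
        model=model, obj=obj, targets=targets, q0=q0, base0=base0,
        weights=config.ik_weights, contact_style=config.contact_style,
    )
    ik_sol = solve_ik(ik_prob, max_iterations=config.ik_max_iterations)

    state = forward_kinematics(model, ik_sol.q, ik_sol.base)
    reach = {
        f: float(np.linalg.norm(
            state.point_on(model.fingertip_segment(f), model.contact_site(f, config.contact_style))
            - targets[f]
        ))
        for f in fingers
    }
    if max(reach.values()) > REACH_TOL:
        E = infeasibility_penalty(ik_sol.q, q0)
        return CandidateResult(E, False, uv_map, ik_sol, None, (), reach)

    contacts, G, N, J = _build_contacts(model, obj, config, ik_sol, fingers)
    problem = GraspProblem(
        J=J, M=muscle_set.moment_arm_matrix, f_max=muscle_set.f_max, G=G, N=N,
        mass=obj.mass, g=obj.g,
    )
    qp_sol = solve_grasp_qp(problem)
    if not qp_sol.ok:
        E = infeasibility_penalty(ik_sol.q, q0)
        return CandidateResult(E, False, uv_map, ik_sol, qp_sol, contacts, reach)
    return CandidateResult(qp_sol.effort, True, uv_map, ik_sol, qp_sol, contacts, reach)


# ---------------------------------------------------------------------------
# CMA-ES outer loop
# ---------------------------------------------------------------------------

def synthesize_grasp(
    model: HandModel,
    obj: RigidObject,
    config: SearchConfig | None = None,
    muscle_set: MuscleSet | None = None,
) -> PostureSolution:
    """CMA-ES search over the fingertip contact coordinates; returns the converged grasp.

    Best-so-far effort is non-increasing across generations, and the whole run is reproducible
    for a fixed seed.
    """
    config = config or SearchConfig()
    muscle_set = muscle_set or load_muscle_table(strength_scale=DEFAULT_STRENGTH_SCALE)
    fingers = sorted(config.finger_surfaces, key=["thumb", "index", "middle", "ring", "little"].index)
    surfs = [obj.surface(config.finger_surfaces[f]) for f in fingers]

    lo = np.concatenate([[-s.half_u, -s.half_v] for s in surfs])
    hi = np.concatenate([[s.half_u, s.half_v] for s in surfs])
    if config.initial_uv is not None:
        x0 = np.concatenate([config.initial_uv[f] for f in fingers])
    else:
        x0 = np.zeros(2 * len(fingers))
    x0 = np.clip(x0, lo, hi)
    # step size large enough that the whole patch is sampled from any starting corner
    sigma0 = config.sigma0 or float(max(max(2 * s.half_u, 2 * s.half_v) for s in surfs)) / 2.0

    def score(uv: np.ndarray) -> float:
        return evaluate_candidate(model, obj, config, uv, muscle_set).effort

    res: CMAResult = cma_es(
        score, x0, sigma0, bounds=(lo, hi),
        population=config.population,
        max_generations=config.max_generations,
        tol_stall=config.tol_stall,
        stall_generations=config.stall_generations,
        seed=config.seed,
    )
    best = evaluate_candidate(model, obj, config, res.x_best, muscle_set)
    return PostureSolution(
        uv=best.uv,
        candidate=best,
        effort=best.effort,
        generations=res.generations,
        evaluations=res.evaluations,
        trace=res.trace,
        converged=res.converged,
        seed=config.seed,
    )
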
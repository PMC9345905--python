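"""Parametric musculoskeletal hand kinematics.

The hand is a chain of 21 rigid bone segments (forearm, carpus, five metacarpals, fourteen
phalanges) rooted at the carpus, whose world pose is the free 6-DOF base.  21 actuated revolute
axes drive the chain: for the thumb, CMC1 flexion-extension and adduction-abduction, MP1
flexion-extension and adduction-abduction, and IP1 flexion-extension; for each finger, MP
flexion-extension and adduction-abduction plus PIP and DIP hinges.  The second to fifth
carpometacarpal joints are immobile.  The palmar skin surface is approximated by an aggregate of
65 spheres used for non-penetration tests against a grasped object.

Segment frames follow the anatomical convention used throughout the package: +z points
proximo-distally along the bone, +y medio-laterally (flexion axis), +x dorso-palmarly.  For
two-DOF joints, flexion-extension is applied first, then adduction-abduction, both about
joint-center axes.  All quantities are SI (meters, radians).

The default geometry is a documented anthropometric parameterization scaled to a hand length of
roughly 19 cm; every length, axis and radius is configurable, and results are model-dependent in
the way any surrogate geometry is.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .muscles import JOINT_AXES, N_JOINTS

N_SEGMENTS = 21
N_SPHERES = 65
FINGERS = ("thumb", "index", "middle", "ring", "little")

# ---------------------------------------------------------------------------
# default geometry
# ---------------------------------------------------------------------------

DEFAULT_GEOMETRY: dict = {
    # bone segment lengths, mm (distance from the segment origin to its distal child's origin,
    # or to the fingertip for distal phalanges)
    "segment_lengths_mm": {
        "forearm": 250.0,
        "carpus": 20.0,
        "mc1": 46.0, "mc2": 68.0, "mc3": 64.0, "mc4": 58.0, "mc5": 54.0,
        "pp1": 32.0, "pp2": 40.0, "pp3": 45.0, "pp4": 42.0, "pp5": 33.0,
        "mp2": 24.0, "mp3": 27.0, "mp4": 25.0, "mp5": 18.0,
        "dp1": 23.0, "dp2": 18.0, "dp3": 18.0, "dp4": 18.0, "dp5": 16.0,
    },
    # metacarpal base positions in the carpal frame, mm (x palmar, y radial, z distal)
    "metacarpal_bases_mm": {
        "mc1": [8.0, 22.0, 12.0],
        "mc2": [0.0, 15.0, 20.0],
        "mc3": [0.0, 5.0, 20.0],
        "mc4": [0.0, -5.0, 20.0],
        "mc5": [0.0, -15.0, 20.0],
    },
    # orientation of the thumb column relative to the carpus: pronation about the bone axis,
    # then palmar and radial tilts of the column (degrees)
    "thumb_orientation_deg": {"pronation": -122.0, "palmar_tilt": 65.0, "radial_tilt": 55.0},
    # skin-proxy sphere radii, mm, by segment
    "sphere_radii_mm": {
        "carpus": 12.0,
        "mc1": 11.0, "mc2": 10.0, "mc3": 10.0, "mc4": 10.0, "mc5": 10.0,
        "pp1": 9.0, "pp2": 8.0, "pp3": 8.0, "pp4": 8.0, "pp5": 7.0,
        "mp2": 7.0, "mp3": 7.0, "mp4": 7.0, "mp5": 6.0,
        "dp1": 7.0, "dp2": 6.0, "dp3": 6.0, "dp4": 6.0, "dp5": 5.5,
    },
    # optional box joint limits, degrees; enabled by default
    "joint_limits_deg": {
        "cmc1_fe": [-30.0, 70.0], "cmc1_aa": [-40.0, 40.0],
        "mp1_fe": [-10.0, 70.0], "mp1_aa": [-30.0, 30.0], "ip1_fe": [-15.0, 90.0],
        "mp2_fe": [-30.0, 90.0], "mp2_aa": [-25.0, 25.0],
        "pip2_fe": [0.0, 110.0], "dip2_fe": [-5.0, 80.0],
        "mp3_fe": [-30.0, 90.0], "mp3_aa": [-25.0, 25.0],
        "pip3_fe": [0.0, 110.0], "dip3_fe": [-5.0, 80.0],
        "mp4_fe": [-30.0, 90.0], "mp4_aa": [-25.0, 25.0],
        "pip4_fe": [0.0, 110.0], "dip4_fe": [-5.0, 80.0],
        "mp5_fe": [-30.0, 90.0], "mp5_aa": [-25.0, 25.0],
        "pip5_fe": [0.0, 110.0], "dip5_fe": [-5.0, 80.0],
    },
    "limits_enabled": True,
    # anatomically natural joint angles (degrees) used as the inverse-kinematics reference
    # posture q0; one preset per grip style
    "natural_posture_deg": {
        # opposed tip pinch: thumb and index distal phalanges face each other tip-on at a
        # ~40 mm aperture; uninvolved fingers curl toward the palm, clear of the pinch
        "tip": {
            "cmc1_fe": 0.0, "cmc1_aa": -22.0, "mp1_fe": 29.0, "mp1_aa": 1.0, "ip1_fe": 69.0,
            "mp2_fe": 34.0, "mp2_aa": 0.0, "pip2_fe": 62.0, "dip2_fe": 61.0,
            "mp3_fe": 60.0, "mp3_aa": 0.0, "pip3_fe": 95.0, "dip3_fe": 50.0,
            "mp4_fe": 60.0, "mp4_aa": 0.0, "pip4_fe": 95.0, "dip4_fe": 50.0,
            "mp5_fe": 60.0, "mp5_aa": 0.0, "pip5_fe": 95.0, "dip5_fe": 50.0,
        },
        # opposed pad (pulp) pinch: straighter distal joints, pads facing each other
        "pulp": {
            "cmc1_fe": -2.0, "cmc1_aa": -23.0, "mp1_fe": 34.0, "mp1_aa": 0.0, "ip1_fe": 39.0,
            "mp2_fe": 47.0, "mp2_aa": 0.0, "pip2_fe": 54.0, "dip2_fe": 32.0,
            "mp3_fe": 60.0, "mp3_aa": 0.0, "pip3_fe": 95.0, "dip3_fe": 50.0,
            "mp4_fe": 60.0, "mp4_aa": 0.0, "pip4_fe": 95.0, "dip4_fe": 50.0,
            "mp5_fe": 60.0, "mp5_aa": 0.0, "pip5_fe": 95.0, "dip5_fe": 50.0,
        },
    },
}

_SEGMENT_NAMES = (
    "carpus", "forearm",
    "mc1", "mc2", "mc3", "mc4", "mc5",
    "pp1", "dp1",
    "pp2", "mp2", "dp2",
    "pp3", "mp3", "dp3",
    "pp4", "mp4", "dp4",
    "pp5", "mp5", "dp5",
)

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One rigid bone segment: rest transform in the parent frame plus its actuated axes."""

    name: str
    parent: str | None
    t0: np.ndarray          # origin in parent frame (m)
    R0: np.ndarray          # rest rotation in parent frame
    joints: tuple[tuple[str, np.ndarray], ...] = ()  # (axis name, unit axis in local frame)
    length: float = 0.0     # m, along local +z


@dataclass(frozen=True)
class BasePose:
    """World pose of the carpal segment: position ``p`` and rotation vector ``e`` (radians)."""

    p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    e: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float).reshape(3))
        object.__setattr__(self, "e", np.asarray(self.e, dtype=float).reshape(3))
        if np.linalg.norm(self.e) >= np.pi + 1e-9:
            raise ValueError("rotation-vector magnitude must be < pi")

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_rotvec(self.e).as_matrix()


@dataclass(frozen=True)
class SkinSphere:
    owner: str
    center: np.ndarray  # owning-segment frame (m)
    radius: float       # m

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class HandModel:
    """Assembled hand: segments, actuated joints, fingertip sites, and the 65-sphere skin proxy."""

    segments: tuple[Segment, ...]
    joint_names: tuple[str, ...]
    joint_limits: np.ndarray | None          # (21, 2) radians, or None when disabled
    spheres: tuple[SkinSphere, ...]
    natural_postures: dict                   # grip style -> q (21,) radians
    config: dict

    def __post_init__(self) -> None:
        if len(self.segments) != N_SEGMENTS:
            raise ValueError(f"expected {N_SEGMENTS} segments")
        if tuple(self.joint_names) != JOINT_AXES:
            raise ValueError("joint axes must match the canonical 21-axis ordering")
        if len(self.spheres) != N_SPHERES:
            raise ValueError(f"expected {N_SPHERES} skin spheres")

    # -- lookups ------------------------------------------------------------
    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def segment_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def path_joints(self, segment: str) -> tuple[int, ...]:
        """Indices of actuated joints on the chain from the carpus to ``segment`` (inclusive)."""
        if segment not in self._paths:
            raise KeyError(f"unknown segment {segment!r}")
        return self._paths[segment]

    @property
    def _paths(self) -> dict[str, tuple[int, ...]]:
        paths: dict[str, tuple[int, ...]] = {}
        jidx = {name: i for i, name in enumerate(self.joint_names)}
        for seg in self.segments:
            inherited = paths.get(seg.parent, ()) if seg.parent else ()
            own = tuple(jidx[a] for a, _ in seg.joints)
            paths[seg.name] = inherited + own
        return paths

    def natural_posture(self, style: str = "tip") -> np.ndarray:
        return self.natural_postures[style].copy()

    def fingertip_segment(self, finger: str) -> str:
        return {"thumb": "dp1", "index": "dp2", "middle": "dp3", "ring": "dp4", "little": "dp5"}[finger]

    def contact_site(self, finger: str, style: str = "tip") -> np.ndarray:
        """Contact site on the distal phalanx, in its local frame.

        ``tip``: the phalanx tip (0, 0, L).  ``pulp``: the palmar point of the distal skin
        sphere, (r, 0, L - r) — the pad of the finger.
        """
        seg = self.segment(self.fingertip_segment(finger))
        L = seg.length
        r = self.config["sphere_radii_mm"][seg.name] * 1e-3
        if style == "tip":
            return np.array([0.0, 0.0, L])
        if style == "pulp":
            return np.array([r, 0.0, L - r])
        raise ValueError(f"unknown contact style {style!r}")

    def to_json(self) -> str:
        return json.dumps(self.config, sort_keys=True, indent=1)


@dataclass(frozen=True)
class KinematicState:
    """Forward-kinematics result: world poses and derived points."""

    rotations: dict[str, np.ndarray]       # segment -> world rotation
    positions: dict[str, np.ndarray]       # segment -> world origin
    fingertips: np.ndarray                 # (5, 3), thumb..little tip sites
    joint_axes_world: np.ndarray           # (21, 3)
    joint_centers_world: np.ndarray        # (21, 3)
    sphere_centers: np.ndarray             # (65, 3)

    def point_on(self, segment: str, local: np.ndarray) -> np.ndarray:
        return self.positions[segment] + self.rotations[segment] @ np.asarray(local, float)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _deep_merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(axis, float) * angle).as_matrix()


def build_parametric_hand(geometry_config: dict | None = None) -> HandModel:
    """Build the 21-segment hand from a geometry configuration.

    ``geometry_config`` overrides entries of :data:`DEFAULT_GEOMETRY` (deep-merged); ``None``
    requests the packaged defaults.  Raises ``ValueError`` on non-positive lengths or malformed
    axes.  Deterministic for a fixed configuration.
    """
    cfg = _deep_merge(DEFAULT_GEOMETRY, geometry_config)
    L = {k: v * 1e-3 for k, v in cfg["segment_lengths_mm"].items()}
    for name, val in L.items():
        if not val > 0:
            raise ValueError(f"segment length for {name!r} must be positive")
    bases = {k: np.asarray(v, float) * 1e-3 for k, v in cfg["metacarpal_bases_mm"].items()}

    th = cfg["thumb_orientation_deg"]
    R_mc1 = (
        _rot(_X, -np.deg2rad(th["radial_tilt"]))
        @ _rot(_Y, np.deg2rad(th["palmar_tilt"]))
        @ _rot(_Z, np.deg2rad(th["pronation"]))
    )

    I3 = np.eye(3)
    segs: list[Segment] = [
        Segment("carpus", None, np.zeros(3), I3, (), L["carpus"]),
        Segment("forearm", "carpus", np.zeros(3), _rot(_Y, np.pi), (), L["forearm"]),
        Segment("mc1", "carpus", bases["mc1"], R_mc1,
                (("cmc1_fe", _Y), ("cmc1_aa", _X)), L["mc1"]),
    ]
    for i, f in zip(range(2, 6), ("index", "middle", "ring", "little")):
        segs.append(Segment(f"mc{i}", "carpus", bases[f"mc{i}"], I3, (), L[f"mc{i}"]))
    # thumb phalanges
    segs.append(Segment("pp1", "mc1", np.array([0, 0, L["mc1"]]), I3,
                        (("mp1_fe", _Y), ("mp1_aa", _X)), L["pp1"]))
    segs.append(Segment("dp1", "pp1", np.array([0, 0, L["pp1"]]), I3,
                        (("ip1_fe", _Y),), L["dp1"]))
    # finger phalanges
    for i in range(2, 6):
        segs.append(Segment(f"pp{i}", f"mc{i}", np.array([0, 0, L[f"mc{i}"]]), I3,
                            ((f"mp{i}_fe", _Y), (f"mp{i}_aa", _X)), L[f"pp{i}"]))
        segs.append(Segment(f"mp{i}", f"pp{i}", np.array([0, 0, L[f"pp{i}"]]), I3,
                            ((f"pip{i}_fe", _Y),), L[f"mp{i}"]))
        segs.append(Segment(f"dp{i}", f"mp{i}", np.array([0, 0, L[f"mp{i}"]]), I3,
                            ((f"dip{i}_fe", _Y),), L[f"dp{i}"]))
    # topological order: parents before children, canonical name order preserved
    order = {n: i for i, n in enumerate(_SEGMENT_NAMES)}
    segs.sort(key=lambda s: order[s.name])

    for s in segs:
        for axis_name, axis in s.joints:
            if abs(np.linalg.norm(axis) - 1.0) > 1e-12:
                raise ValueError(f"joint axis {axis_name} is not a unit vector")

    radii = cfg["sphere_radii_mm"]
    spheres: list[SkinSphere] = []
    # carpus/palm: three spheres across the palm, slightly palmar of the bone plane
    for c in ([2.0, 10.0, 10.0], [2.0, 0.0, 8.0], [2.0, -10.0, 10.0]):
        spheres.append(SkinSphere("carpus", np.asarray(c) * 1e-3, radii["carpus"] * 1e-3))
    for i in range(1, 6):
        name = f"mc{i}"
        for frac in (0.2, 0.4, 0.6, 0.8):
            spheres.append(SkinSphere(name, np.array([0, 0, frac * L[name]]), radii[name] * 1e-3))
    phalanges = ["pp1", "dp1"] + [f"{p}{i}" for i in range(2, 6) for p in ("pp", "mp", "dp")]
    for name in phalanges:
        r = radii[name] * 1e-3
        # distal-most sphere tangent to the tip so a tip contact carries zero skin penetration
        for z in (0.25 * L[name], 0.6 * L[name], L[name] - r):
            spheres.append(SkinSphere(name, np.array([0, 0, z]), r))
    assert len(spheres) == N_SPHERES

    limits = None
    if cfg.get("limits_enabled", True):
        limits = np.deg2rad(np.array([cfg["joint_limits_deg"][a] for a in JOINT_AXES]))

    postures = {
        style: np.deg2rad(np.array([table[a] for a in JOINT_AXES]))
        for style, table in cfg["natural_posture_deg"].items()
    }
    return HandModel(
        segments=tuple(segs),
        joint_names=JOINT_AXES,
        joint_limits=limits,
        spheres=tuple(spheres),
        natural_postures=postures,
        config=cfg,
    )


def load_hand_config(path: str | Path) -> dict:
    """Read a YAML or JSON hand geometry configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_hand_config(cfg: dict, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg, sort_keys=True, indent=1))
    else:
        p.write_text(yaml.safe_dump(cfg, sort_keys=True))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def check_joint_angles(model: HandModel, q: np.ndarray, enforce_limits: bool = False) -> np.ndarray:
    q = np.asarray(q, dtype=float).reshape(-1)
    if q.shape != (N_JOINTS,):
        raise ValueError(f"q must have length {N_JOINTS}")
    if enforce_limits and model.joint_limits is not None:
        lo, hi = model.joint_limits[:, 0], model.joint_limits[:, 1]
        if np.any(q < lo - 1e-9) or np.any(q > hi + 1e-9):
            raise ValueError("joint angles outside configured limits")
    return q


def forward_kinematics(model: HandModel, q: np.ndarray, base: BasePose | None = None) -> KinematicState:
    """World poses of all segments plus fingertip sites, joint frames, and sphere centers."""
    q = check_joint_angles(model, q)
    base = base or BasePose()
    qmap = dict(zip(model.joint_names, q))

    R: dict[str, np.ndarray] = {}
    P: dict[str, np.ndarray] = {}
    jax = np.zeros((N_JOINTS, 3))
    jcen = np.zeros((N_JOINTS, 3))
    jidx = {name: i for i, name in enumerate(model.joint_names)}

    for seg in model.segments:
        if seg.parent is None:
            Rw = base.rotation
            pw = base.p.copy()
        else:
            Rp, pp = R[seg.parent], P[seg.parent]
            pw = pp + Rp @ seg.t0
            Rw = Rp @ seg.R0
        for axis_name, axis in seg.joints:
            k = jidx[axis_name]
            jax[k] = Rw @ axis
            jcen[k] = pw
            Rw = Rw @ _rot(axis, qmap[axis_name])
        R[seg.name] = Rw
        P[seg.name] = pw

    tips = np.array([
        P[model.fingertip_segment(f)]
        + R[model.fingertip_segment(f)] @ model.contact_site(f, "tip")
        for f in FINGERS
    ])
    centers = np.array([P[s.owner] + R[s.owner] @ s.center for s in model.spheres])
    return KinematicState(R, P, tips, jax, jcen, centers)


def point_jacobian(
    model: HandModel,
    state: KinematicState,
    points_world: np.ndarray,
    owners: list[str],
) -> np.ndarray:
    """Jacobian of world points attached to segments, with respect to the 21 joint angles.

    Returns a (3 n, 21) matrix whose row-blocks follow the point ordering.  Column ``j`` of a
    block is ``omega_j x (c - p_j)`` for joints on the carpus-to-owner chain and zero elsewhere.
    """
    points_world = np.atleast_2d(np.asarray(points_world, float))
    if len(owners) != len(points_world):
        raise ValueError("one owner segment per point required")
    J = np.zeros((3 * len(points_world), N_JOINTS))
    for i, (c, owner) in enumerate(zip(points_world, owners)):
        for j in model.path_joints(owner):
            J[3 * i: 3 * i + 3, j] = np.cross(state.joint_axes_world[j], c - state.joint_centers_world[j])
    return J


def contact_jacobian(
    model: HandModel,
    q: np.ndarray,
    base: BasePose,
    contact_points: np.ndarray,
    owners: list[str],
) -> np.ndarray:
    """The (3 n x 21) Jacobian of ``n`` contact points with respect to the joint angles."""
    state = forward_kinematics(model, q, base)
    return point_jacobian(model, state, contact_points, owners)


def penetration_depths(model: HandModel, q: np.ndarray, base: BasePose, obj) -> np.ndarray:
    """Non-negative penetration depth of each of the 65 skin spheres into ``obj`` (m).

    ``obj`` must provide ``signed_distance(points) -> (n,)`` distances from points to its surface
    (negative inside).  Depth is ``max(0, radius - distance)``; zero when not penetrating.
    """
    state = forward_kinematics(model, q, base)
    d = obj.signed_distance(state.sphere_centers)
    radii = np.array([s.radius for s in model.spheres])
    return np.maximum(0.0, radii - d)
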
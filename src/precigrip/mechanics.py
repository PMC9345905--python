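"""Object-side grasping statics.

For an object held by ``n`` point contacts with forces ``f_k``, static equilibrium requires

    G f = [-m g; 0],        G = [[I ... I], [S(r_1) ... S(r_n)]],

where ``G`` is the 6 x 3n grasp matrix, ``r_k`` the vector from the object's center of mass to
contact ``k`` and ``S`` the cross-product (skew) matrix.  Coulomb friction confines each contact
force to a cone of apex half-angle ``theta = atan(mu)`` about the inward surface normal; the cone
is linearized as a twelve-sided pyramid whose facet normals ``n_{k,h}`` give linear constraints
``n_{k,h} . f_k <= 0``.  The pyramid is inscribed in the exact cone (facet planes contain rays at
tangential/normal ratio ``mu``), so any pyramid-feasible force is also exact-cone feasible.

Soft contact of a finger pad, which can transmit a torsional moment about the surface normal, is
emulated by a pair of point contacts 2 mm either side of the contact centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

GRAVITY = np.array([0.0, 0.0, -9.81])  # m/s^2, world frame
N_FACETS = 12
SOFT_PAIR_OFFSET = 0.002  # m


# ---------------------------------------------------------------------------
# object geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanarSurface:
    """A bounded planar contact patch in the object frame.

    ``origin`` is the patch center; ``normal`` the inward unit normal (into the object);
    ``u_axis``/``v_axis`` an orthonormal in-plane basis with half-extents ``half_u``/``half_v``.
    """

    name: str
    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    half_u: float
    half_v: float

    def __post_init__(self) -> None:
        for attr in ("origin", "normal", "u_axis", "v_axis"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), float).reshape(3))
        for v in (self.normal, self.u_axis, self.v_axis):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("surface axes must be unit vectors")

    def point_at(self, u: float, v: float) -> np.ndarray:
        """Object-frame point at in-plane coordinates (u, v), clipped to the patch bounds."""
        u = float(np.clip(u, -self.half_u, self.half_u))
        v = float(np.clip(v, -self.half_v, self.half_v))
        return self.origin + u * self.u_axis + v * self.v_axis


@dataclass(frozen=True)
class RigidObject:
    """Rigid object: mass properties, friction, contact surfaces, and a solid box union.

    The solid (``boxes``: axis-aligned (center, half_extents) pairs in the object frame) supports
    signed-distance queries for the skin-sphere non-penetration terms.  ``pose`` is the world pose
    (R, t) of the object frame.
    """

    mass: float                       # kg
    com: np.ndarray                   # object frame (m)
    mu_actual: float
    surfaces: tuple[PlanarSurface, ...]
    boxes: tuple[tuple[np.ndarray, np.ndarray], ...] = ()
    g: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    pose_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    pose_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be non-negative")
        if self.mu_actual < 0:
            raise ValueError("friction coefficient must be non-negative")
        object.__setattr__(self, "com", np.asarray(self.com, float).reshape(3))
        object.__setattr__(self, "g", np.asarray(self.g, float).reshape(3))

    # -- frames -------------------------------------------------------------
    def to_world(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.pose_rotation.T + self.pose_translation

    def to_object(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.pose_translation) @ self.pose_rotation

    def vector_to_world(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, float) @ self.pose_rotation.T

    @property
    def com_world(self) -> np.ndarray:
        return self.to_world(self.com)

    def surface(self, name: str) -> PlanarSurface:
        for s in self.surfaces:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_pose(self, rotation: np.ndarray, translation: np.ndarray) -> "RigidObject":
        return replace(self, pose_rotation=np.asarray(rotation, float),
                       pose_translation=np.asarray(translation, float))

    # -- signed distance ----------------------------------------------------
    def signed_distance(self, points_world: np.ndarray) -> np.ndarray:
        """Signed distance (m) from world points to the object solid; negative inside."""
        p = np.atleast_2d(self.to_object(points_world))
        if not self.boxes:
            return np.full(len(p), np.inf)
        d = np.full(len(p), np.inf)
        for center, half in self.boxes:
            qv = np.abs(p - center) - half
            outside = np.linalg.norm(np.maximum(qv, 0.0), axis=1)
            inside = np.minimum(np.max(qv, axis=1), 0.0)
            d = np.minimum(d, outside + inside)
        return d

    def distance_gradient(self, points_world: np.ndarray) -> np.ndarray:
        """Gradient of the signed distance with respect to the world point, shape (n, 3)."""
        p = np.atleast_2d(self.to_object(points_world))
        best_d = np.full(len(p), np.inf)
        grad = np.zeros_like(p)
        for center, half in self.boxes:
            rel = p - center
            qv = np.abs(rel) - half
            pos = np.maximum(qv, 0.0)
            outside = np.linalg.norm(pos, axis=1)
            inside = np.minimum(np.max(qv, axis=1), 0.0)
            d = outside + inside
            g = np.zeros_like(p)
            out_mask = outside > 0
            g[out_mask] = (pos[out_mask] / outside[out_mask, None]) * np.sign(rel[out_mask])
            in_mask = ~out_mask
            if np.any(in_mask):
                ax = np.argmax(qv[in_mask], axis=1)
                rows = np.where(in_mask)[0]
                g[rows, ax] = np.sign(rel[rows, ax])
            upd = d < best_d
            best_d[upd] = d[upd]
            grad[upd] = g[upd]
        return grad @ self.pose_rotation.T


# ---------------------------------------------------------------------------
# contacts and friction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contact:
    """One point contact: world-frame point, inward unit normal, and its owning finger segment."""

    point: np.ndarray
    normal: np.ndarray
    finger: str
    segment: str
    is_soft_pair: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, float).reshape(3))
        n = np.asarray(self.normal, float).reshape(3)
        if np.linalg.norm(n) < 1e-12:
            raise ValueError("contact normal must be nonzero")
        object.__setattr__(self, "normal", n / np.linalg.norm(n))

    def r(self, com_world: np.ndarray) -> np.ndarray:
        return self.point - np.asarray(com_world, float)


@dataclass(frozen=True)
class FrictionPyramid:
    """Twelve-sided linearization of the friction cone at one contact.

    ``facet_normals`` (12, 3): outward unit normals of the pyramid's side facets; an admissible
    contact force satisfies ``facet_normals @ f <= 0``.
    """

    facet_normals: np.ndarray
    apex_half_angle: float   # atan(mu_eff), radians
    mu_eff: float

    def __post_init__(self) -> None:
        if self.facet_normals.shape != (N_FACETS, 3):
            raise ValueError("friction pyramid must have exactly 12 facets")

    def contains(self, f: np.ndarray, tol: float = 1e-12) -> bool:
        return bool(np.all(self.facet_normals @ np.asarray(f, float) <= tol))


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return t1, t2


def friction_pyramid(normal: np.ndarray, mu_eff: float) -> FrictionPyramid:
    """Inscribed 12-facet pyramid approximating the friction cone about the inward ``normal``.

    Edge rays are ``n + mu (cos a_h t1 + sin a_h t2)`` at twelve equal azimuths ``a_h``; the facet
    between adjacent edges receives the outward normal of their common plane.  Forces with
    tangential/normal ratio up to ``mu_eff * cos(pi/12)`` (the inscribed circle of the edge
    polygon) satisfy every facet.
    """
    if mu_eff < 0:
        raise ValueError("friction coefficient must be non-negative")
    n = np.asarray(normal, float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("zero contact normal")
    n = n / norm
    t1, t2 = _tangent_basis(n)
    az = 2.0 * np.pi * np.arange(N_FACETS + 1) / N_FACETS
    tang = np.outer(np.cos(az), t1) + np.outer(np.sin(az), t2)
    edges = n + mu_eff * tang  # (13, 3); edge 12 == edge 0
    facets = np.zeros((N_FACETS, 3))
    for h in range(N_FACETS):
        nu = np.cross(edges[h], edges[h + 1])
        if np.linalg.norm(nu) < 1e-12:
            # mu == 0: the pyramid collapses to the normal ray; constrain the tangential
            # component along each azimuth bisector
            nu = (tang[h] + tang[h + 1]) / np.linalg.norm(tang[h] + tang[h + 1])
        else:
            nu = nu / np.linalg.norm(nu)
        mid = tang[h] + tang[h + 1]
        if nu @ mid < 0:          # orient outward (positive tangential component)
            nu = -nu
        facets[h] = nu
    return FrictionPyramid(facets, float(np.arctan(mu_eff)), float(mu_eff))


def soft_contact_pair(
    centroid: np.ndarray,
    normal: np.ndarray,
    lateral_axis: np.ndarray,
    finger: str = "",
    segment: str = "",
    offset: float = SOFT_PAIR_OFFSET,
) -> tuple[Contact, Contact]:
    """Two contact points 2 mm either side of the contact centroid, in the contact plane.

    Emulates soft contact of the distal phalanx: equal and opposite tangential forces at the pair
    produce a torsional moment about the contact normal.  ``lateral_axis`` is projected into the
    contact plane; it must not be (near) parallel to the normal.
    """
    c = np.asarray(centroid, float).reshape(3)
    n = np.asarray(normal, float).reshape(3)
    n = n / np.linalg.norm(n)
    a = np.asarray(lateral_axis, float).reshape(3)
    a = a - (a @ n) * n
    if np.linalg.norm(a) < 1e-9:
        raise ValueError("lateral axis is degenerate (parallel to the contact normal)")
    a = a / np.linalg.norm(a)
    mk = lambda s: Contact(c + s * offset * a, n, finger, segment, is_soft_pair=True)
    return mk(+1.0), mk(-1.0)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = np.asarray(v, float)
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def grasp_matrix(contacts: list[Contact], com_world: np.ndarray) -> np.ndarray:
    """The 6 x 3n grasp matrix: identity force blocks over skew moment blocks ``S(r_k)``."""
    if not contacts:
        raise ValueError("at least one contact required")
    n = len(contacts)
    G = np.zeros((6, 3 * n))
    for k, c in enumerate(contacts):
        G[:3, 3 * k: 3 * k + 3] = np.eye(3)
        G[3:, 3 * k: 3 * k + 3] = skew(c.r(com_world))
    return G


def assemble_facet_matrix(pyramids: list[FrictionPyramid]) -> np.ndarray:
    """Block-diagonal stack of per-contact facet normals, shape (12 n, 3 n)."""
    n = len(pyramids)
    N = np.zeros((N_FACETS * n, 3 * n))
    for k, pyr in enumerate(pyramids):
        N[N_FACETS * k: N_FACETS * (k + 1), 3 * k: 3 * k + 3] = pyr.facet_normals
    return N


def equilibrium_rhs(obj: RigidObject) -> np.ndarray:
    """Right-hand side ``[-m g; 0]`` of the object equilibrium constraint (world frame)."""
    return np.concatenate([-obj.mass * obj.g, np.zeros(3)])


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

def sensing_device(
    mass_g: float = 198.4,
    plate_separation_mm: float = 40.0,
    mu: float = 0.8,
) -> RigidObject:
    """The two-plate fingertip force-sensing device used for validation.

    Two parallel aluminum plates, 20 mm x 49 mm each, mounted on opposite sides of the sensor
    body; total mass 198.4 g.  Object frame: +x is the grip/normal direction (the k axis of the
    sensor), +z is vertical (the load direction, spanning the 20 mm plate side), and +y runs
    along the 49 mm plate side, held horizontally — so pinching toward either end of a plate
    (u away from 0) offsets the contact axis horizontally from the center of mass and loads the
    fingertips with a gravitational torsional moment about the contact normal, while a vertical
    offset produces none.  Plate separation and friction are configurable (the packaged defaults
    are 40 mm and 0.8).
    """
    s = plate_separation_mm * 1e-3 / 2.0
    half = np.array([s, 0.0245, 0.010])
    plates = (
        PlanarSurface("plate_a", [s, 0, 0], [-1, 0, 0], [0, 1, 0], [0, 0, 1], 0.0245, 0.010),
        PlanarSurface("plate_b", [-s, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], 0.0245, 0.010),
    )
    return RigidObject(
        mass=mass_g * 1e-3,
        com=np.zeros(3),
        mu_actual=mu,
        surfaces=plates,
        boxes=((np.zeros(3), half),),
    )


def load_object_config(path: str | Path) -> RigidObject:
    """Build a RigidObject from a YAML/JSON config (mass_g, com_mm, mu, surfaces, boxes)."""
    cfg = yaml.safe_load(Path(path).read_text())
    surfaces = tuple(
        PlanarSurface(
            s["name"],
            np.asarray(s["origin_mm"], float) * 1e-3,
            np.asarray(s["normal"], float),
            np.asarray(s["u_axis"], float),
            np.asarray(s["v_axis"], float),
            s["half_u_mm"] * 1e-3,
            s["half_v_mm"] * 1e-3,
        )
        for s in cfg["surfaces"]
    )
    boxes = tuple(
        (np.asarray(b["center_mm"], float) * 1e-3, np.asarray(b["half_mm"], float) * 1e-3)
        for b in cfg.get("boxes", [])
    )
    return RigidObject(
        mass=cfg["mass_g"] * 1e-3,
        com=np.asarray(cfg.get("com_mm", [0, 0, 0]), float) * 1e-3,
        mu_actual=cfg["mu"],
        surfaces=surfaces,
        boxes=boxes,
    )


def save_object_config(obj: RigidObject, path: str | Path) -> None:
    cfg = {
        "mass_g": obj.mass * 1e3,
        "com_mm": (obj.com * 1e3).tolist(),
        "mu": obj.mu_actual,
        "surfaces": [
            {
                "name": s.name,
                "origin_mm": (s.origin * 1e3).tolist(),
                "normal": s.normal.tolist(),
                "u_axis": s.u_axis.tolist(),
                "v_axis": s.v_axis.tolist(),
                "half_u_mm": s.half_u * 1e3,
                "half_v_mm": s.half_v * 1e3,
            }
            for s in obj.surfaces
        ],
        "boxes": [
            {"center_mm": (c * 1e3).tolist(), "half_mm": (h * 1e3).tolist()}
            for c, h in obj.boxes
        ],
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
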
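"""Elastic-foundation contact between cartilage triangle meshes.

The articulating cartilage is treated as a thin compliant layer on rigid
bone: each surface element carries an independent spring, so the local
contact pressure is proportional to the local interpenetration depth,

    p = K_layer * d,
    K_layer = E (1 - nu) / ((1 + nu)(1 - 2 nu) h),

the confined-compression (uniaxial-strain) modulus of a layer of Young's
modulus ``E``, Poisson ratio ``nu`` and combined thickness ``h``.  There
is no coupling between elements, no friction and no damping - the model is
quasi-static.

The foundation is discretized on the tibial mesh: for every tibial face
the penetration depth is measured along the element's inward ray to the
opposing femoral surface.  The femoral surfaces are fixed in the femur
frame, so their ray-acceleration structure is built once per mesh and
reused across solver iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .joint_coordinates import BodyPose

__all__ = [
    "ContactParameters",
    "ContactResult",
    "PenetrationField",
    "penetration_field",
    "contact_wrench",
]


@dataclass(frozen=True)
class ContactParameters:
    """Elastic-foundation layer parameters (linear pressure law)."""

    layer_modulus_E: float = 5.0     # MPa, combined cartilage layer
    poisson_nu: float = 0.45
    layer_thickness_h: float = 4.0   # mm, femoral + tibial layer combined
    pressure_law: str = "linear"
    max_pressure_cap: float | None = None  # MPa

    def __post_init__(self):
        if self.layer_modulus_E <= 0:
            raise ValueError("layer modulus must be positive")
        if not 0.0 <= self.poisson_nu < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5); nu = 0.5 "
                             "is an incompressible layer with infinite "
                             "foundation stiffness")
        if self.layer_thickness_h <= 0:
            raise ValueError("layer thickness must be positive")
        if self.pressure_law != "linear":
            raise ValueError("only the linear pressure law is supported")

    @property
    def foundation_stiffness(self) -> float:
        """K_layer in MPa/mm (= N/mm^3)."""
        E, nu, h = self.layer_modulus_E, self.poisson_nu, self.layer_thickness_h
        return E * (1 - nu) / ((1 + nu) * (1 - 2 * nu) * h)


@dataclass
class PenetrationField:
    """Per-element penetration of a tibial mesh against a femoral surface.

    All quantities are in the femur frame; one entry per tibial face.
    """

    depths: np.ndarray        # mm, >= 0, 0 where not in contact
    normals: np.ndarray       # tibial outward unit normals
    centers: np.ndarray       # tibial face centers, mm
    areas: np.ndarray         # tibial face areas, mm^2


@dataclass
class ContactResult:
    """Resultant of an elastic-foundation contact evaluation.

    ``total_force`` acts on the tibia (the femur receives the opposite);
    ``total_torque`` is the moment of that force distribution about the
    femur-frame origin, in N*mm.
    """

    total_force: np.ndarray
    total_torque: np.ndarray
    resultant_magnitude: float
    max_pressure: float
    contact_area: float
    penetration_depths: np.ndarray

    @classmethod
    def zero(cls, n_elements: int = 0) -> "ContactResult":
        return cls(np.zeros(3), np.zeros(3), 0.0, 0.0, 0.0,
                   np.zeros(n_elements))

    def __add__(self, other: "ContactResult") -> "ContactResult":
        return ContactResult(
            self.total_force + other.total_force,
            self.total_torque + other.total_torque,
            float(np.linalg.norm(self.total_force + other.total_force)),
            max(self.max_pressure, other.max_pressure),
            self.contact_area + other.contact_area,
            np.concatenate([self.penetration_depths,
                            other.penetration_depths]))


# ---------------------------------------------------------------------------
# ray casting against the (fixed) femoral surface
#
# trimesh's ray backends need rtree/embree; the query here is a vectorized
# Moller-Trumbore intersection over KD-tree-pruned candidate triangles,
# which is exact and fast for the short, near-surface rays the elastic
# foundation needs.

_PARALLEL_EPS = 1e-12
_BARY_EPS = 1e-9


def _cross(a, b):
    """Row-wise cross product without np.cross overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


class _SurfaceRayQuery:
    """Short-ray intersection structure for one static triangle mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        tris = mesh.triangles.view(np.ndarray)
        areas = mesh.area_faces
        ok = areas > 1e-12
        if not ok.all():
            warnings.warn(f"skipping {np.count_nonzero(~ok)} degenerate "
                          "triangles in contact surface")
        self.v0 = tris[ok, 0]
        self.e1 = tris[ok, 1] - tris[ok, 0]
        self.e2 = tris[ok, 2] - tris[ok, 0]
        self.normals = mesh.face_normals[ok]
        centroids = tris[ok].mean(axis=1)
        # circumscribing radius bound per triangle for prune safety
        self._tri_radius = float(np.sqrt(
            ((tris[ok] - centroids[:, None, :]) ** 2).sum(-1).max()))
        self._tree = cKDTree(centroids)

    def first_hit(self, origins: np.ndarray, directions: np.ndarray,
                  max_distance: float):
        """First intersection along each ray within ``max_distance``.

        Returns (distance, triangle_normal) arrays; distance is inf for
        rays without a valid hit.
        """
        n = len(origins)
        dist = np.full(n, np.inf)
        normal = np.zeros((n, 3))
        radius = max_distance + self._tri_radius + 1e-9
        cand = self._tree.query_ball_point(origins, r=radius)
        ray_idx = np.concatenate([np.full(len(c), i, dtype=np.intp)
                                  for i, c in enumerate(cand)]) \
            if n else np.empty(0, dtype=np.intp)
        tri_idx = np.concatenate([np.asarray(c, dtype=np.intp) for c in cand]) \
            if n else np.empty(0, dtype=np.intp)
        if len(ray_idx) == 0:
            return dist, normal

        o = origins[ray_idx]
        d = directions[ray_idx]
        v0, e1, e2 = self.v0[tri_idx], self.e1[tri_idx], self.e2[tri_idx]
        h = _cross(d, e2)
        a = np.einsum("ij,ij->i", e1, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(np.abs(a) > _PARALLEL_EPS, 1.0 / a, 0.0)
        s = o - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = _cross(s, e1)
        v = f * np.einsum("ij,ij->i", d, q)
        t = f * np.einsum("ij,ij->i", e2, q)
        valid = ((np.abs(a) > _PARALLEL_EPS)
                 & (u >= -_BARY_EPS) & (v >= -_BARY_EPS)
                 & (u + v <= 1 + _BARY_EPS)
                 & (t >= -1e-6) & (t <= max_distance))
        t = np.where(valid, np.maximum(t, 0.0), np.inf)
        np.minimum.at(dist, ray_idx, t)
        # recover the triangle normal of the winning hit
        won = valid & (t <= dist[ray_idx] + 1e-12) & np.isfinite(t)
        normal[ray_idx[won]] = self.normals[tri_idx[won]]
        return dist, normal


def _ray_query(mesh: trimesh.Trimesh) -> _SurfaceRayQuery:
    """Cached per-mesh query structure (the femur is static)."""
    q = getattr(mesh, "_kneesim_ray_query", None)
    if q is None:
        q = _SurfaceRayQuery(mesh)
        mesh._kneesim_ray_query = q
    return q


def penetration_field(femur_surface: trimesh.Trimesh,
                      tibia_surface: trimesh.Trimesh,
                      pose: BodyPose,
                      max_depth: float = 6.0) -> PenetrationField:
    """Penetration depths of tibial elements against the femoral surface.

    ``pose`` is the tibia-in-femur pose; the tibial mesh is given in the
    tibia frame, the femoral mesh in the femur frame.  For every tibial
    face a ray is cast from the face center along the inward (anti-normal)
    direction; a hit on an opposing-oriented femoral face within
    ``max_depth`` mm is an interpenetration of that depth.  Elements out
    of contact report depth 0.
    """
    R, t = pose.rotation, pose.translation
    tri = tibia_surface.triangles.view(np.ndarray)
    areas = tibia_surface.area_faces
    ok = areas > 1e-12
    if not ok.all():
        warnings.warn(f"skipping {np.count_nonzero(~ok)} degenerate "
                      "triangles in tibial surface")
    centers = tri[ok].mean(axis=1) @ R.T + t
    normals = tibia_surface.face_normals[ok] @ R.T

    query = _ray_query(femur_surface)
    dist, hit_normal = query.first_hit(centers, -normals, max_depth)
    # a genuine penetration exits through a femoral face oriented against
    # the tibial element (surfaces facing each other)
    opposing = np.einsum("ij,ij->i", hit_normal, normals) < -0.1
    depths = np.where(np.isfinite(dist) & opposing, dist, 0.0)

    full_depths = np.zeros(len(tri))
    full_depths[ok] = depths
    full_normals = np.zeros((len(tri), 3))
    full_normals[ok] = normals
    full_centers = np.zeros((len(tri), 3))
    full_centers[ok] = centers
    return PenetrationField(full_depths, full_normals, full_centers,
                            np.where(ok, areas, 0.0))


def contact_wrench(femur_surface: trimesh.Trimesh,
                   tibia_surface: trimesh.Trimesh,
                   pose: BodyPose,
                   params: ContactParameters) -> ContactResult:
    """Elastic-foundation contact wrench of one compartment.

    Per-element pressure ``p = K_layer * d`` acts along the tibial element
    normal, pushing the tibia away from the femur; the wrench is the
    area-weighted sum.  Forces on the two bodies are equal and opposite by
    construction.
    """
    field = penetration_field(femur_surface, tibia_surface, pose)
    K = params.foundation_stiffness
    pressure = K * field.depths
    if params.max_pressure_cap is not None:
        pressure = np.minimum(pressure, params.max_pressure_cap)
    # force on tibia: away from the femur, i.e. against the tibial outward
    # normal (which points toward the femur across the joint space)
    f_el = -(pressure * field.areas)[:, None] * field.normals
    total_force = f_el.sum(axis=0)
    total_torque = np.cross(field.centers, f_el).sum(axis=0)
    in_contact = field.depths > 0
    return ContactResult(
        total_force=total_force,
        total_torque=total_torque,
        resultant_magnitude=float(np.linalg.norm(total_force)),
        max_pressure=float(pressure.max()) if len(pressure) else 0.0,
        contact_area=float(field.areas[in_contact].sum()),
        penetration_depths=field.depths,
    )
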
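"""Parametric synthetic right-knee generator.

Builds an idealized tibiofemoral joint that stands in for subject-specific
imaging geometry: two convex femoral condyle surfaces (sphere patches whose
centers sit on/near the femoral flexion axis) articulating on two shallow
concave tibial plateau dishes, plus the 16 ligament-bundle attachment
sites.  After placement, every attachment pair is scaled along its own
line so that the bundle length at the full-extension reference pose equals
the registry's reference length ``lr`` exactly; the reference pose is
declared to be full extension with the joint centered under zero load,
with femur and tibia frames coincident.

Frame convention (right knee): ``x`` anterior, ``y`` superior, ``z``
lateral; origin on the femoral flexion axis midway between the condyles.
The condylar anterior-posterior offset parameter shifts the lateral
condyle center off the flexion axis, which is the geometric mechanism for
the screw-home rotation during passive flexion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .cartilage_contact import ContactParameters, penetration_field
from .joint_coordinates import BodyPose
from .ligament_model import LigamentRegistry

__all__ = [
    "GeometryConfig",
    "KneeModel",
    "build_synthetic_knee",
    "place_attachments",
    "oriented_mesh",
    "rectangular_plate",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the synthetic knee geometry (all lengths in mm).

    Defaults are physiologically plausible magnitudes for an adult knee:
    distal femoral condyles of ~21-22 mm radius separated by ~45 mm,
    resting in shallow tibial dishes much flatter than the condyles
    (medial more conforming than lateral), with a small positive joint
    gap at the unloaded reference pose.
    """

    medial_condyle_radius: float = 22.0
    lateral_condyle_radius: float = 21.0
    intercondylar_spacing: float = 45.0       # condyle center-to-center
    condylar_ap_offset: float = 3.0           # lateral condyle posterior shift
    medial_dish_radius: float = 35.0
    lateral_dish_radius: float = 60.0
    dish_planform_radius: float = 16.0
    reference_gap: float = 0.05               # joint space at reference pose
    mesh_edge_length: float = 2.0
    vertex_jitter: float = 0.0                # mm std dev, off by default
    seed: int = 0
    mirror_left: bool = False

    def validate(self) -> None:
        problems = []
        for name in ("medial_condyle_radius", "lateral_condyle_radius",
                     "medial_dish_radius", "lateral_dish_radius",
                     "intercondylar_spacing", "dish_planform_radius",
                     "mesh_edge_length"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.medial_dish_radius <= self.medial_condyle_radius:
            problems.append("medial_dish_radius must exceed "
                            "medial_condyle_radius (conforming contact)")
        if self.lateral_dish_radius <= self.lateral_condyle_radius:
            problems.append("lateral_dish_radius must exceed "
                            "lateral_condyle_radius (conforming contact)")
        if self.dish_planform_radius >= min(self.medial_dish_radius,
                                            self.lateral_dish_radius):
            problems.append("dish_planform_radius must be smaller than the "
                            "dish radii")
        if self.reference_gap < 0:
            problems.append("reference_gap must be non-negative")
        if self.vertex_jitter < 0:
            problems.append("vertex_jitter must be non-negative")
        if self.mesh_edge_length > self.dish_planform_radius:
            problems.append("mesh_edge_length too coarse for the dish size")
        if problems:
            raise ValueError("invalid geometry config: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryConfig":
        return cls(**d)


def oriented_mesh(vertices, faces, outward_reference) -> trimesh.Trimesh:
    """Triangle mesh with winding fixed so normals follow a reference field.

    ``outward_reference`` is an (n_faces, 3) array (or a single vector) of
    desired outward directions; faces whose computed normal opposes it are
    flipped individually.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    mesh = trimesh.Trimesh(vertices, faces, process=False)
    ref = np.broadcast_to(np.asarray(outward_reference, dtype=float),
                          (len(faces), 3))
    wrong = np.einsum("ij,ij->i", mesh.face_normals, ref) < 0
    if wrong.any():
        faces = faces.copy()
        faces[wrong] = faces[wrong][:, ::-1]
        mesh = trimesh.Trimesh(vertices, faces, process=False)
    return mesh


def rectangular_plate(size_x: float, size_z: float, y: float,
                      edge_length: float, normal_up: bool = True,
                      center=(0.0, 0.0)) -> trimesh.Trimesh:
    """Flat rectangular open mesh at height ``y`` (useful for slab tests)."""
    nx = max(2, int(np.ceil(size_x / edge_length)) + 1)
    nz = max(2, int(np.ceil(size_z / edge_length)) + 1)
    xs = np.linspace(-size_x / 2, size_x / 2, nx) + center[0]
    zs = np.linspace(-size_z / 2, size_z / 2, nz) + center[1]
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    V = np.column_stack([X.ravel(), np.full(X.size, float(y)), Z.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(nz - 1):
            a = i * nz + j
            b = (i + 1) * nz + j
            c = (i + 1) * nz + j + 1
            d = i * nz + j + 1
            faces += [[a, b, c], [a, c, d]]
    ref = np.array([0.0, 1.0 if normal_up else -1.0, 0.0])
    return oriented_mesh(V, np.array(faces), ref)


def _condyle_band(center, radius, edge_length,
                  u_range=(-30.0, 115.0), v_range=(-35.0, 35.0)):
    """Convex sphere patch covering the articulating arc of one condyle.

    ``u`` sweeps the sagittal plane from straight-down (0 deg, extension
    contact) toward posterior (flexion contact); ``v`` tilts coronally.
    Outward normals point away from the sphere center.
    """
    center = np.asarray(center, dtype=float)
    u0, u1 = np.deg2rad(u_range)
    v0, v1 = np.deg2rad(v_range)
    nu = max(4, int(np.ceil(radius * (u1 - u0) / edge_length)) + 1)
    nv = max(4, int(np.ceil(radius * (v1 - v0) / edge_length)) + 1)
    u = np.linspace(u0, u1, nu)
    v = np.linspace(v0, v1, nv)
    U, Vv = np.meshgrid(u, v, indexing="ij")
    d = np.stack([-np.sin(U) * np.cos(Vv),
                  -np.cos(U) * np.cos(Vv),
                  np.sin(Vv)], axis=-1)
    verts = center + radius * d.reshape(-1, 3)
    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            b = (i + 1) * nv + j
            c = (i + 1) * nv + j + 1
            e = i * nv + j + 1
            faces += [[a, b, c], [a, c, e]]
    radial = verts[np.array(faces)].mean(axis=1) - center
    return oriented_mesh(verts, np.array(faces), radial)


def _plateau_dish(bottom_point, dish_radius, planform_radius, edge_length):
    """Shallow concave spherical dish; outward normals point up (to femur)."""
    bottom = np.asarray(bottom_point, dtype=float)
    D = bottom + np.array([0.0, dish_radius, 0.0])  # curvature center above
    phi_max = np.arcsin(planform_radius / dish_radius)
    n_r = max(3, int(np.ceil(dish_radius * phi_max / edge_length)))
    n_psi = max(8, int(np.ceil(np.pi * planform_radius / edge_length)))
    verts = [D + dish_radius * np.array([0.0, -1.0, 0.0])]
    ring_start = [None]
    for i in range(1, n_r + 1):
        phi = phi_max * i / n_r
        psi = np.linspace(0, 2 * np.pi, n_psi, endpoint=False)
        ring = D + dish_radius * np.column_stack([
            np.sin(phi) * np.cos(psi),
            np.full(n_psi, -np.cos(phi)),
            np.sin(phi) * np.sin(psi)])
        ring_start.append(len(verts))
        verts.extend(ring)
    verts = np.asarray(verts)
    faces = []
    for j in range(n_psi):                       # central fan
        faces.append([0, 1 + j, 1 + (j + 1) % n_psi])
    for i in range(1, n_r):                      # ring strips
        s0, s1 = ring_start[i], ring_start[i + 1]
        for j in range(n_psi):
            a, b = s0 + j, s0 + (j + 1) % n_psi
            c, e = s1 + j, s1 + (j + 1) % n_psi
            faces += [[a, c, e], [a, e, b]]
    centers = verts[np.array(faces)].mean(axis=1)
    up = D - centers                              # toward curvature center
    return oriented_mesh(verts, np.array(faces), up)


# anatomically-motivated attachment sites at the reference pose, femur and
# tibia frame coordinates in mm (x anterior, y superior, z lateral; joint
# line near y = -22).  Cruciates cross in the intercondylar notch,
# collaterals run epicondyle-to-fibular-head (LCL) / medial tibia (MCL),
# the OPL/POL/APL/capsular structures lie posteriorly.  Each pair is
# subsequently scaled along its line to the registry reference length.
_ATTACHMENT_SITES = {
    #        femur (x, y, z)        tibia (x, y, z)
    "ACLa": ((-11.0, -4.0, 7.0), (12.0, -22.0, 1.0)),
    "ACLp": ((-14.0, -7.0, 7.0), (15.0, -22.0, -2.0)),
    "PCLa": ((6.0, -4.0, -7.0), (-14.0, -25.0, -1.0)),
    "PCLp": ((3.0, -7.0, -7.0), (-17.0, -25.0, 2.0)),
    "LCLa": ((2.0, 2.0, 31.0), (-10.0, -65.0, 33.0)),
    "LCLp": ((-2.0, 2.0, 31.0), (-14.0, -65.0, 33.0)),
    "sMCLa": ((2.0, 3.0, -31.0), (14.0, -85.0, -25.0)),
    "sMCLp": ((-2.0, 3.0, -31.0), (10.0, -88.0, -25.0)),
    "dMCLa": ((2.0, 0.0, -30.0), (5.0, -26.0, -28.0)),
    "dMCLp": ((-2.0, 0.0, -30.0), (-5.0, -26.0, -28.0)),
    "OPLa": ((-19.0, 0.0, 14.0), (-14.0, -78.0, -12.0)),
    "OPLp": ((-21.0, -2.0, 12.0), (-16.0, -80.0, -14.0)),
    "mCAP": ((-19.0, 0.0, -14.0), (-17.0, -58.0, -16.0)),
    "lCAP": ((-19.0, 0.0, 14.0), (-17.0, -60.0, 16.0)),
    "POL": ((-14.0, 0.0, -28.0), (-14.0, -38.0, -24.0)),
    "APL": ((-19.0, 0.0, 22.0), (-14.0, -78.0, 26.0)),
}


def place_attachments(config: GeometryConfig,
                      registry: LigamentRegistry) -> LigamentRegistry:
    """Assign calibrated attachment points to every bundle.

    Sites start from the anatomic template, scaled with the intercondylar
    spacing in the mediolateral direction, then each femur/tibia pair is
    scaled along its own line about its midpoint so the reference-pose
    length (frames coincident) equals the bundle's reference length
    exactly.
    """
    config.validate()
    ml_scale = config.intercondylar_spacing / 45.0
    side = -1.0 if config.mirror_left else 1.0
    new_bundles = []
    for b in registry.bundles:
        if b.name not in _ATTACHMENT_SITES:
            raise ValueError(f"no attachment template for bundle {b.name}")
        pf, pt = (np.array(p) for p in _ATTACHMENT_SITES[b.name])
        pf[2] *= ml_scale * side
        pt[2] *= ml_scale * side
        d = pf - pt
        l_init = np.linalg.norm(d)
        if l_init < 1e-6:
            raise ValueError(f"{b.name}: degenerate attachment line")
        mid = 0.5 * (pf + pt)
        scale = b.reference_length_lr / l_init
        half = 0.5 * scale * d
        new_bundles.append(_dc_replace(b, femur_attachment=mid + half,
                                       tibia_attachment=mid - half))
    return LigamentRegistry(tuple(new_bundles), registry.resection_history)


@dataclass
class KneeModel:
    """Assembled tibiofemoral model: cartilage meshes, frames, ligaments."""

    femur_cartilage_medial: trimesh.Trimesh
    femur_cartilage_lateral: trimesh.Trimesh
    tibia_cartilage_medial: trimesh.Trimesh
    tibia_cartilage_lateral: trimesh.Trimesh
    femur_frame: BodyPose
    tibia_frame: BodyPose
    ligaments: LigamentRegistry
    contact: ContactParameters
    config: GeometryConfig | None = None

    @property
    def contact_pairs(self):
        """(label, femoral mesh, tibial mesh) per compartment."""
        return (("medial", self.femur_cartilage_medial,
                 self.tibia_cartilage_medial),
                ("lateral", self.femur_cartilage_lateral,
                 self.tibia_cartilage_lateral))

    def with_ligaments(self, registry: LigamentRegistry) -> "KneeModel":
        return _dc_replace(self, ligaments=registry)

    def save(self, directory) -> None:
        """Serialize as OBJ meshes + ligament CSV + YAML config."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for label, fem, tib in self.contact_pairs:
            fem.export(d / f"femur_cartilage_{label}.obj")
            tib.export(d / f"tibia_cartilage_{label}.obj")
        self.ligaments.to_csv(d / "ligaments.csv")
        meta = {
            "contact": {"layer_modulus_E": self.contact.layer_modulus_E,
                        "poisson_nu": self.contact.poisson_nu,
                        "layer_thickness_h": self.contact.layer_thickness_h,
                        "pressure_law": self.contact.pressure_law},
            "femur_frame": self.femur_frame.as_matrix().tolist(),
            "tibia_frame": self.tibia_frame.as_matrix().tolist(),
            "geometry": self.config.to_dict() if self.config else None,
        }
        with open(d / "model.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory) -> "KneeModel":
        d = Path(directory)
        with open(d / "model.yaml") as fh:
            meta = yaml.safe_load(fh)
        meshes = {}
        for label in ("medial", "lateral"):
            for body in ("femur", "tibia"):
                m = trimesh.load(d / f"{body}_cartilage_{label}.obj",
                                 process=False)
                meshes[f"{body}_{label}"] = m
        return cls(
            femur_cartilage_medial=meshes["femur_medial"],
            femur_cartilage_lateral=meshes["femur_lateral"],
            tibia_cartilage_medial=meshes["tibia_medial"],
            tibia_cartilage_lateral=meshes["tibia_lateral"],
            femur_frame=BodyPose.from_matrix(meta["femur_frame"], "femur"),
            tibia_frame=BodyPose.from_matrix(meta["tibia_frame"], "tibia"),
            ligaments=LigamentRegistry.from_csv(d / "ligaments.csv"),
            contact=ContactParameters(**meta["contact"]),
            config=(GeometryConfig.from_dict(meta["geometry"])
                    if meta.get("geometry") else None),
        )


def build_synthetic_knee(config: GeometryConfig | None = None,
                         contact: ContactParameters | None = None,
                         registry: LigamentRegistry | None = None) -> KneeModel:
    """Build the default synthetic right knee.

    Deterministic for a fixed config/seed.  The assembled model satisfies
    the reference-pose invariants: every active bundle's length equals its
    reference length, and the cartilage surfaces are separated by the
    (positive) reference gap before any load is applied.
    """
    config = config or GeometryConfig()
    config.validate()
    contact = contact or ContactParameters()
    registry = registry or LigamentRegistry.with_default_parameters()

    hs = 0.5 * config.intercondylar_spacing
    side = -1.0 if config.mirror_left else 1.0
    r_m, r_l = config.medial_condyle_radius, config.lateral_condyle_radius
    c_med = np.array([0.0, 0.0, -side * hs])
    c_lat = np.array([-config.condylar_ap_offset, 0.0, side * hs])

    fem_med = _condyle_band(c_med, r_m, config.mesh_edge_length)
    fem_lat = _condyle_band(c_lat, r_l, config.mesh_edge_length)

    g = config.reference_gap
    tib_med = _plateau_dish(c_med + [0.0, -(r_m + g), 0.0],
                            config.medial_dish_radius,
                            config.dish_planform_radius,
                            config.mesh_edge_length)
    tib_lat = _plateau_dish(c_lat + [0.0, -(r_l + g), 0.0],
                            config.lateral_dish_radius,
                            config.dish_planform_radius,
                            config.mesh_edge_length)

    if config.vertex_jitter > 0:
        rng = np.random.default_rng(config.seed)
        for m in (fem_med, fem_lat, tib_med, tib_lat):
            m.vertices = m.vertices + rng.normal(
                scale=config.vertex_jitter, size=m.vertices.shape)

    registry = place_attachments(config, registry)
    model = KneeModel(
        femur_cartilage_medial=fem_med,
        femur_cartilage_lateral=fem_lat,
        tibia_cartilage_medial=tib_med,
        tibia_cartilage_lateral=tib_lat,
        femur_frame=BodyPose.identity("femur"),
        tibia_frame=BodyPose.identity("tibia"),
        ligaments=registry,
        contact=contact,
        config=config,
    )

    if config.reference_gap > 0 and config.vertex_jitter == 0:
        ref_pose = BodyPose.identity()
        for label, fem, tib in model.contact_pairs:
            depths = penetration_field(fem, tib, ref_pose).depths
            if depths.max() > 0:
                raise ValueError(f"{label} compartment interpenetrates at "
                                 "the reference pose; check radii/gap")
    return model
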
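"""Grood-Suntay joint coordinate system for the tibiofemoral joint.

The clinical joint coordinate system consists of a flexion/extension axis
fixed to the femur, an internal/external rotation axis fixed to the tibia
(its long axis), and a floating varus/valgus axis perpendicular to both.
Translations are "clinical translations" resolved along those same three
(generally non-orthogonal) axes.

Body frames used throughout the package (right knee):

* ``x`` anterior, ``y`` superior (proximal), ``z`` lateral;
* femoral flexion axis = femoral ``z``; tibial long axis = tibial ``y``;
* the frames coincide at the full-extension reference pose.

Sign conventions follow the clinical right-knee convention: flexion(+)/
extension(-), varus(+)/valgus(-), external(+)/internal(-), medial(+)/
lateral(-), anterior(+)/posterior(-), superior(+)/inferior(-).  The
superoinferior translation is signed in the joint-opening sense of the
clinical convention (positive = distraction along the tibial long axis),
which is what makes the standard compressive load on that axis a
*negative* number in load tables.  With the axes above this makes the
relative rotation of the tibia with respect to the femur the intrinsic
Euler sequence

    R = Rz(-flexion) @ Rx(+varus) @ Ry(-external)

whose gimbal singularity sits at |varus| = 90 deg, far outside the
physiologic range.  A mirror flag converts the convention for left knees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "BodyPose",
    "GSCoordinates",
    "GimbalSingularityError",
    "gs_from_pose",
    "pose_from_gs",
    "gs_jacobian",
    "GS_COORD_NAMES",
]

#: canonical ordering of the six joint coordinates
GS_COORD_NAMES = ("flexion_deg", "varus_deg", "external_deg",
                  "medial_mm", "anterior_mm", "superior_mm")

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])

#: configurations with |varus| above this are treated as singular (deg)
SINGULARITY_LIMIT_DEG = 89.0


class GimbalSingularityError(ValueError):
    """Raised when a configuration is at/near the varus-valgus gimbal lock."""


@dataclass(frozen=True)
class BodyPose:
    """Rigid-body pose: rotation matrix plus translation in mm."""

    rotation: np.ndarray
    translation: np.ndarray
    frame_label: str = ""

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("pose contains non-finite entries")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation matrix is not orthonormal (residual > 1e-9)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is a reflection (det < 0)")

    @classmethod
    def identity(cls, frame_label: str = "") -> "BodyPose":
        return cls(np.eye(3), np.zeros(3), frame_label)

    def inverse(self) -> "BodyPose":
        return BodyPose(self.rotation.T, -self.rotation.T @ self.translation,
                        self.frame_label)

    def compose(self, other: "BodyPose") -> "BodyPose":
        """Return self @ other (apply ``other`` first)."""
        return BodyPose(self.rotation @ other.rotation,
                        self.rotation @ other.translation + self.translation,
                        self.frame_label)

    def transform_point(self, p) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float) + self.translation

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    @classmethod
    def from_matrix(cls, H, frame_label: str = "") -> "BodyPose":
        H = np.asarray(H, dtype=float).reshape(4, 4)
        return cls(H[:3, :3], H[:3, 3], frame_label)


@dataclass(frozen=True)
class GSCoordinates:
    """The six Grood-Suntay degrees of freedom of tibia relative to femur."""

    flexion_deg: float = 0.0
    varus_deg: float = 0.0
    external_deg: float = 0.0
    medial_mm: float = 0.0
    anterior_mm: float = 0.0
    superior_mm: float = 0.0

    def __post_init__(self):
        for name in GS_COORD_NAMES:
            object.__setattr__(self, name, float(getattr(self, name)))
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("joint coordinates must be finite")
        for name in ("flexion_deg", "varus_deg", "external_deg"):
            v = getattr(self, name)
            if not (-180.0 < v < 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180)")

    def as_array(self) -> np.ndarray:
        return np.array([self.flexion_deg, self.varus_deg, self.external_deg,
                         self.medial_mm, self.anterior_mm, self.superior_mm],
                        dtype=float)

    @classmethod
    def from_array(cls, q) -> "GSCoordinates":
        q = np.asarray(q, dtype=float).reshape(6)
        return cls(*q)

    def replace(self, **kw) -> "GSCoordinates":
        d = {n: getattr(self, n) for n in GS_COORD_NAMES}
        d.update(kw)
        return GSCoordinates(**d)


def _check_gimbal(varus_deg: float) -> None:
    if abs(varus_deg) > SINGULARITY_LIMIT_DEG:
        raise GimbalSingularityError(
            f"varus/valgus angle {varus_deg:.2f} deg is within 1 deg of the "
            "gimbal singularity at +/-90 deg")


def _joint_axes(R: np.ndarray):
    """Return (e1, e2, e3): femoral flexion axis, floating axis, tibial long
    axis, all expressed in the femur frame."""
    e1 = _EZ
    e3 = R @ _EY
    cross = np.cross(e3, e1)
    n = np.linalg.norm(cross)
    if n < np.cos(np.deg2rad(SINGULARITY_LIMIT_DEG)):
        raise GimbalSingularityError("floating axis undefined: tibial long "
                                     "axis parallel to femoral flexion axis")
    e2 = cross / n
    return e1, e2, e3


def pose_from_gs(gs: GSCoordinates, mirror: bool = False) -> BodyPose:
    """Pose of the tibia frame with respect to the femur frame.

    The rotation is the femur-fixed flexion rotation, followed by the
    varus/valgus rotation about the floating axis, followed by the
    tibia-fixed internal/external rotation.  Translations are resolved
    along the corresponding joint axes. ``mirror=True`` flips the
    medial/lateral-sensitive signs for a left knee.
    """
    _check_gimbal(gs.varus_deg)
    sv = -1.0 if mirror else 1.0
    ang = np.deg2rad([-gs.flexion_deg, sv * gs.varus_deg, -sv * gs.external_deg])
    R = Rotation.from_euler("ZXY", ang).as_matrix()
    e1, e2, e3 = _joint_axes(R)
    t = ((-sv * gs.medial_mm) * e1 + gs.anterior_mm * e2
         - gs.superior_mm * e3)          # superior(+) = distraction
    return BodyPose(R, t, "tibia_in_femur")


def gs_from_pose(femur_pose: BodyPose, tibia_pose: BodyPose,
                 mirror: bool = False) -> GSCoordinates:
    """Grood-Suntay coordinates of the tibia relative to the femur.

    Both poses are given in a common (world/lab) frame; only their relative
    pose matters.  Raises :class:`GimbalSingularityError` at varus/valgus
    angles within 1 deg of +/-90 deg instead of returning NaN.
    """
    rel = femur_pose.inverse().compose(tibia_pose)
    R, t = rel.rotation, rel.translation
    sv = -1.0 if mirror else 1.0

    # varus first, straight from the axis geometry: sin(varus) = e3 . e1
    sin_varus = np.clip(R[2, 1], -1.0, 1.0)
    varus = np.rad2deg(np.arcsin(sin_varus))
    _check_gimbal(varus * sv)

    psi = Rotation.from_matrix(R).as_euler("ZXY")
    flexion = -np.rad2deg(psi[0])
    external = -sv * np.rad2deg(psi[2])
    varus = sv * np.rad2deg(psi[1])

    e1, e2, e3 = _joint_axes(R)
    # oblique decomposition t = u1 e1 + u2 e2 + u3 e3
    u = np.linalg.solve(np.column_stack([e1, e2, e3]), t)
    return GSCoordinates(flexion_deg=flexion, varus_deg=varus,
                         external_deg=external, medial_mm=-sv * u[0],
                         anterior_mm=u[1], superior_mm=-u[2])


def gs_jacobian(gs: GSCoordinates) -> np.ndarray:
    """6x6 map from joint-coordinate rates to the spatial twist of the tibia.

    Column ``i`` is the twist ``(omega, v)`` (femur frame; rad/s and mm/s)
    produced by a unit rate of coordinate ``i`` in the order
    ``(flexion, varus, external, medial, anterior, superior)`` with the
    rotational rates in rad/s.  ``v`` is the velocity of the tibia-frame
    origin.  By the principle of virtual work the transpose maps a spatial
    wrench ``(moment about the tibia origin, force)`` to generalized forces
    on the six coordinates (N*mm per rad on rotations, N on translations).
    """
    _check_gimbal(gs.varus_deg)
    pose = pose_from_gs(gs)
    R = pose.rotation
    e1, e2, e3 = _joint_axes(R)
    cross_norm = np.linalg.norm(np.cross(e3, e1))

    # rotation-rate axes: femur-fixed, floating, tibia-fixed (with signs)
    omega_cols = np.zeros((3, 6))
    omega_cols[:, 0] = -e1
    omega_cols[:, 1] = e2
    omega_cols[:, 2] = -e3

    u1, u2, u3 = -gs.medial_mm, gs.anterior_mm, -gs.superior_mm
    v_cols = np.zeros((3, 6))
    P = np.eye(3) - np.outer(e2, e2)
    for i in range(3):
        w = omega_cols[:, i]
        de3 = np.cross(w, e3)          # e3 is tibia-fixed
        de2 = P @ np.cross(de3, e1) / cross_norm
        v_cols[:, i] = u2 * de2 + u3 * de3
    v_cols[:, 3] = -e1                 # medial(+) is along -e1 (right knee)
    v_cols[:, 4] = e2
    v_cols[:, 5] = -e3                 # superior(+) = distraction

    return np.vstack([omega_cols, v_cols])
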
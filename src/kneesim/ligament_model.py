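"""Nonlinear tension-only ligament bundles of the tibiofemoral joint.

Each of the 16 bundles is a straight-line spring between a femoral and a
tibial attachment point, with the classic Wismans/Blankevoort strain-force
law: zero force when slack, a quadratic "toe" region for small strain and a
linear region beyond,

    f(eps) = 0                          eps < 0
           = k * eps^2 / (4 * eps_l)    0 <= eps <= 2*eps_l
           = k * (eps - eps_l)          eps > 2*eps_l

where ``k`` is a stiffness with units of force (strain-based formulation)
and ``eps_l`` = 0.03 marks the end of the toe region.  The strain is
``eps = (l - l0)/l0`` with slack length ``l0 = lr/(eps_r + 1)`` derived
from a measured reference length ``lr`` and reference strain ``eps_r`` at
the full-extension reference pose.  Negative reference strain means the
bundle is slack at reference.

The default parameter set covers anterior/posterior fiber bundles of the
cruciates (ACL, PCL), collaterals (LCL, superficial and deep MCL), the
oblique popliteal ligament, posterior oblique and arcuate popliteal
ligaments and the medial/lateral posterior capsule.  No wrapping around
bone or soft tissue and no viscoelasticity are modeled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .joint_coordinates import BodyPose

__all__ = [
    "EPS_LINEAR_LIMIT",
    "LigamentBundle",
    "LigamentRegistry",
    "slack_length",
    "strain",
    "bundle_force",
    "ligament_wrench",
    "resect",
    "default_parameter_table",
    "RESECTION_GROUPS",
]

#: strain at the end of the quadratic toe region (dimensionless)
EPS_LINEAR_LIMIT = 0.03

#: (name, stiffness k [N], reference strain eps_r [fraction], reference length lr [mm])
_DEFAULT_PARAMETERS = (
    ("ACLa", 1000.0, 0.10, 31.8),
    ("ACLp", 1000.0, 0.03, 22.9),
    ("PCLa", 3000.0, -0.10, 32.4),
    ("PCLp", 1500.0, -0.03, 31.1),
    ("LCLa", 2250.0, -0.25, 74.4),
    ("LCLp", 2250.0, 0.08, 74.5),
    ("sMCLa", 4000.0, 0.04, 93.4),
    ("sMCLp", 1500.0, 0.04, 94.4),
    ("dMCLa", 1500.0, 0.02, 29.7),
    ("dMCLp", 2000.0, -0.07, 32.8),
    ("OPLa", 1250.0, 0.06, 83.2),
    ("OPLp", 1250.0, 0.06, 85.5),
    ("mCAP", 2500.0, 0.05, 58.9),
    ("lCAP", 2500.0, 0.05, 60.9),
    ("POL", 2000.0, 0.05, 39.5),
    ("APL", 1500.0, 0.04, 80.8),
)

BUNDLE_NAMES = tuple(row[0] for row in _DEFAULT_PARAMETERS)

#: ligament groups removed together in the sequential resection protocol
RESECTION_GROUPS = {
    "ACL": ("ACLa", "ACLp"),
    "PCL": ("PCLa", "PCLp"),
    "LCL": ("LCLa", "LCLp"),
    "MCL": ("sMCLa", "sMCLp", "dMCLa", "dMCLp"),
}


def slack_length(lr: float, er: float) -> float:
    """Slack length l0 = lr / (er + 1) from reference length and strain."""
    if lr <= 0:
        raise ValueError(f"reference length must be positive, got {lr}")
    if er <= -1:
        raise ValueError(f"reference strain must exceed -1, got {er}")
    return lr / (er + 1.0)


def strain(l, l0: float):
    """Engineering strain (l - l0)/l0 of a bundle of slack length l0."""
    if l0 <= 0:
        raise ValueError(f"slack length must be positive, got {l0}")
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("ligament length cannot be negative")
    out = (l - l0) / l0
    return out if out.ndim else float(out)


def bundle_force(eps, k: float, eps_l: float = EPS_LINEAR_LIMIT):
    """Tension-only piecewise force law; returns force in N (scalar or array)."""
    if k <= 0:
        raise ValueError(f"stiffness must be positive, got {k}")
    if eps_l <= 0:
        raise ValueError(f"linear-limit strain must be positive, got {eps_l}")
    eps = np.asarray(eps, dtype=float)
    toe = 0.25 * k * eps**2 / eps_l
    lin = k * (eps - eps_l)
    out = np.where(eps < 0, 0.0, np.where(eps <= 2 * eps_l, toe, lin))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LigamentBundle:
    """One ligament fiber bundle: parameters plus attachment points.

    Attachments are 3-vectors in mm, each expressed in its own body frame
    (femur frame for ``femur_attachment``, tibia frame for
    ``tibia_attachment``).
    """

    name: str
    femur_attachment: np.ndarray
    tibia_attachment: np.ndarray
    stiffness_k: float
    reference_strain: float
    reference_length_lr: float
    linear_limit: float = EPS_LINEAR_LIMIT
    active: bool = True

    def __post_init__(self):
        object.__setattr__(self, "femur_attachment",
                           np.asarray(self.femur_attachment, dtype=float).reshape(3))
        object.__setattr__(self, "tibia_attachment",
                           np.asarray(self.tibia_attachment, dtype=float).reshape(3))
        if self.stiffness_k <= 0:
            raise ValueError(f"{self.name}: stiffness must be positive")
        if self.reference_length_lr <= 0:
            raise ValueError(f"{self.name}: reference length must be positive")
        if self.reference_strain <= -1:
            raise ValueError(f"{self.name}: reference strain must exceed -1")

    @property
    def slack_length_l0(self) -> float:
        return slack_length(self.reference_length_lr, self.reference_strain)

    def length(self, relative_pose: BodyPose) -> float:
        """Current straight-line length for a tibia-in-femur pose."""
        p_t = relative_pose.transform_point(self.tibia_attachment)
        return float(np.linalg.norm(self.femur_attachment - p_t))

    def force_magnitude(self, relative_pose: BodyPose) -> float:
        eps = strain(self.length(relative_pose), self.slack_length_l0)
        return bundle_force(eps, self.stiffness_k, self.linear_limit)


def ligament_wrench(bundle: LigamentBundle, relative_pose: BodyPose):
    """Equal and opposite attachment-point forces of one bundle.

    Returns ``(force_on_femur, force_on_tibia, application_point_tibia)``
    with forces in N and the tibial application point in femur-frame mm.
    The force acts along the straight line between the attachments; slack
    bundles transmit nothing.  Raises on coincident attachment points.
    """
    p_f = bundle.femur_attachment
    p_t = relative_pose.transform_point(bundle.tibia_attachment)
    d = p_f - p_t
    l = np.linalg.norm(d)
    if l < 1e-9:
        raise ValueError(f"{bundle.name}: attachment points coincide "
                         "(zero-length ligament)")
    f_mag = bundle_force(strain(l, bundle.slack_length_l0),
                         bundle.stiffness_k, bundle.linear_limit)
    f_on_tibia = f_mag * d / l          # tension pulls tibia toward femur point
    return -f_on_tibia, f_on_tibia, p_t


@dataclass(frozen=True)
class LigamentRegistry:
    """The full, ordered set of 16 uniquely named ligament bundles."""

    bundles: tuple
    resection_history: tuple = ()

    def __post_init__(self):
        names = [b.name for b in self.bundles]
        if len(names) != len(set(names)):
            raise ValueError("duplicate bundle names in registry")
        if set(names) != set(BUNDLE_NAMES):
            missing = set(BUNDLE_NAMES) - set(names)
            extra = set(names) - set(BUNDLE_NAMES)
            raise ValueError(f"registry must hold the 16 canonical bundles; "
                             f"missing={sorted(missing)} extra={sorted(extra)}")

    def __iter__(self):
        return iter(self.bundles)

    def __getitem__(self, name: str) -> LigamentBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def active_bundles(self) -> tuple:
        return tuple(b for b in self.bundles if b.active)

    @classmethod
    def with_default_parameters(cls, attachments=None) -> "LigamentRegistry":
        """Registry from the built-in parameter table.

        ``attachments`` optionally maps bundle name to a pair of 3-vectors
        ``(femur_attachment, tibia_attachment)``; placeholders at the
        origin +/- 1 mm are used otherwise (attachments are normally
        assigned by the synthetic-knee generator).
        """
        bundles = []
        for name, k, er, lr in _DEFAULT_PARAMETERS:
            if attachments and name in attachments:
                pf, pt = attachments[name]
            else:
                pf, pt = np.zeros(3), np.array([0.0, -lr, 0.0])
            bundles.append(LigamentBundle(name, pf, pt, k, er, lr))
        return cls(tuple(bundles))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bundles:
            rows.append({
                "name": b.name, "k_N": b.stiffness_k,
                "eps_r_percent": 100.0 * b.reference_strain,
                "lr_mm": b.reference_length_lr,
                "l0_mm": b.slack_length_l0,
                "fx_mm": b.femur_attachment[0], "fy_mm": b.femur_attachment[1],
                "fz_mm": b.femur_attachment[2],
                "tx_mm": b.tibia_attachment[0], "ty_mm": b.tibia_attachment[1],
                "tz_mm": b.tibia_attachment[2],
                "active": b.active,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LigamentRegistry":
        df = pd.read_csv(path)
        bundles = []
        for _, r in df.iterrows():
            bundles.append(LigamentBundle(
                r["name"],
                [r["fx_mm"], r["fy_mm"], r["fz_mm"]],
                [r["tx_mm"], r["ty_mm"], r["tz_mm"]],
                float(r["k_N"]), float(r["eps_r_percent"]) / 100.0,
                float(r["lr_mm"]), active=bool(r.get("active", True))))
        return cls(tuple(bundles))


def resect(registry: LigamentRegistry, group: str) -> LigamentRegistry:
    """Deactivate a ligament group (ACL, PCL, LCL or MCL); idempotent.

    Mirrors the sequential sectioning protocol of cadaver testing: the MCL
    group covers superficial and deep bundles, while the posterior
    structures (OPL, POL, APL, capsule) are separate and never cut here.
    """
    if group not in RESECTION_GROUPS:
        raise ValueError(f"unknown resection group {group!r}; "
                         f"expected one of {sorted(RESECTION_GROUPS)}")
    names = RESECTION_GROUPS[group]
    bundles = tuple(replace(b, active=False) if b.name in names else b
                    for b in registry.bundles)
    history = registry.resection_history
    if group not in history:
        history = history + (group,)
    return LigamentRegistry(bundles, history)


def default_parameter_table() -> pd.DataFrame:
    """The built-in per-bundle parameter table (k, eps_r, lr)."""
    return pd.DataFrame(
        [(n, k, 100 * er, lr) for n, k, er, lr in _DEFAULT_PARAMETERS],
        columns=["name", "k_N", "eps_r_percent", "lr_mm"])
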
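"""Quasi-static equilibrium of the 5-DOF tibiofemoral joint.

The flexion angle is prescribed; the remaining five Grood-Suntay
coordinates (varus/valgus, external/internal rotation and the three
clinical translations) settle into static equilibrium of ligament,
cartilage-contact and externally applied generalized forces.  Time only
parameterizes the load schedule - there is no inertia, damping or
gravity, so each sample is an independent root-finding problem solved
with a damped Newton iteration (finite-difference Jacobian) and a
least-squares fallback, warm-started along the motion for continuation.

Internal units are N, mm and N*mm; the laxity torques of the standard
protocol (Nm) are converted on entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.optimize import least_squares

from .cartilage_contact import ContactResult, contact_wrench
from .joint_coordinates import (GimbalSingularityError, GSCoordinates,
                                gs_jacobian, pose_from_gs)
from .ligament_model import ligament_wrench

__all__ = [
    "LoadCase",
    "EquilibriumState",
    "KinematicsTrace",
    "LaxityResult",
    "generalized_residual",
    "solve_equilibrium",
    "run_passive_flexion",
    "run_laxity_test",
    "passive_flexion_angle",
    "FREE_COORDS",
    "LAXITY_PROTOCOL",
]

#: the five equilibrium coordinates, in residual order
FREE_COORDS = ("varus_deg", "external_deg", "medial_mm", "anterior_mm",
               "superior_mm")

#: standard laxity protocol: driven coordinate and signed load (+/-)
LAXITY_PROTOCOL = {
    "AP": {"coordinate": "anterior_mm", "load": 40.0, "unit": "N",
           "field": "ap_force"},
    "VV": {"coordinate": "varus_deg", "load": 5.0, "unit": "Nm",
           "field": "vv_torque"},
    "IE": {"coordinate": "external_deg", "load": 2.5, "unit": "Nm",
           "field": "ie_torque"},
}

PASSIVE_PERIOD_S = 25.0
PASSIVE_PEAK_DEG = 90.0
LAXITY_ANGLES_DEG = (30.0, 60.0, 90.0)
COMPRESSIVE_LOAD_N = -50.0     # superior(+)/inferior(-) axis


def passive_flexion_angle(t: float | np.ndarray) -> float | np.ndarray:
    """Prescribed flexion (deg): sine cycle 0 -> 90 -> 0 deg, period 25 s."""
    return 0.5 * PASSIVE_PEAK_DEG * (
        1.0 - np.cos(2.0 * np.pi * np.asarray(t, dtype=float)
                     / PASSIVE_PERIOD_S))


@dataclass(frozen=True)
class LoadCase:
    """One load case: flexion schedule plus applied loads per joint axis.

    Torques in Nm, forces in N, signs per the clinical convention
    (varus+, external+, medial+, anterior+, superior+).  The defaults of
    the named constructors reproduce the standard protocol: passive
    flexion with a 50 N compressive load only, laxity tests adding
    +/-40 N AP, +/-5 Nm varus/valgus or +/-2.5 Nm external/internal at
    fixed flexion angles of 30/60/90 deg.
    """

    label: str = "PassiveFlexion"
    flexion_schedule: str = "sine"            # "sine" or "fixed"
    fixed_angles_deg: tuple = LAXITY_ANGLES_DEG
    vv_torque_Nm: float = 0.0
    ie_torque_Nm: float = 0.0
    ml_force_N: float = 0.0
    ap_force_N: float = 0.0
    si_force_N: float = COMPRESSIVE_LOAD_N

    @classmethod
    def passive_flexion(cls) -> "LoadCase":
        return cls(label="PassiveFlexion", flexion_schedule="sine")

    @classmethod
    def laxity(cls, test: str, sign: float = 1.0) -> "LoadCase":
        if test not in LAXITY_PROTOCOL:
            raise ValueError(f"unknown laxity test {test!r}")
        spec = LAXITY_PROTOCOL[test]
        kw = {"label": f"{test}-Laxity", "flexion_schedule": "fixed"}
        value = float(np.sign(sign) or 1.0) * spec["load"]
        key = spec["field"] + ("_Nm" if spec["unit"] == "Nm" else "_N")
        kw[key] = value
        return cls(**kw)

    def generalized_applied(self) -> np.ndarray:
        """Applied loads as generalized forces on the five free coordinates
        (N*mm on rotations, N on translations)."""
        return np.array([self.vv_torque_Nm * 1e3, self.ie_torque_Nm * 1e3,
                         self.ml_force_N, self.ap_force_N, self.si_force_N])


@dataclass
class EquilibriumState:
    """Solution of one quasi-static solve."""

    gs: GSCoordinates
    residual: np.ndarray          # (5,) generalized forces, N*mm / N
    residual_norm: float          # scaled max-abs (1.0 == at tolerance)
    bundle_forces: dict           # name -> N (active bundles)
    contact: ContactResult
    converged: bool
    iterations: int
    indeterminate: bool = False
    message: str = ""

    @property
    def total_ligament_force(self) -> float:
        return float(sum(self.bundle_forces.values()))


@dataclass
class KinematicsTrace:
    """Time-stamped sequence of equilibrium states."""

    times_s: np.ndarray
    flexion_deg: np.ndarray
    states: list
    complete: bool = True
    message: str = ""

    def __len__(self):
        return len(self.states)

    def coordinate(self, name: str) -> np.ndarray:
        return np.array([getattr(s.gs, name) for s in self.states])

    def bundle_force(self, name: str) -> np.ndarray:
        return np.array([s.bundle_forces.get(name, 0.0) for s in self.states])

    def to_frame(self):
        import pandas as pd
        n = len(self.states)
        data = {"time_s": self.times_s[:n], "flexion_deg": self.flexion_deg[:n]}
        for coord in ("varus_deg", "external_deg", "medial_mm",
                      "anterior_mm", "superior_mm"):
            data[coord] = self.coordinate(coord)
        names = sorted({k for s in self.states for k in s.bundle_forces})
        for nm in names:
            data[f"force_{nm}_N"] = self.bundle_force(nm)
        data["contact_force_N"] = [s.contact.resultant_magnitude
                                   for s in self.states]
        data["max_pressure_MPa"] = [s.contact.max_pressure
                                    for s in self.states]
        data["contact_area_mm2"] = [s.contact.contact_area
                                    for s in self.states]
        data["converged"] = [s.converged for s in self.states]
        return pd.DataFrame(data)


@dataclass
class LaxityResult:
    """Per-angle loaded/passive equilibria of one laxity test."""

    test: str
    records: list        # dicts: angle, passive/plus/minus states, loads

    @property
    def driven_coordinate(self) -> str:
        return LAXITY_PROTOCOL[self.test]["coordinate"]

    def range_at(self, angle: float) -> float:
        """|position(+load) - position(-load)| of the driven coordinate;
        NaN when either loaded leg did not converge."""
        for r in self.records:
            if r["angle_deg"] == angle:
                if not (r["plus"].converged and r["minus"].converged):
                    return float("nan")
                c = self.driven_coordinate
                return abs(getattr(r["plus"].gs, c)
                           - getattr(r["minus"].gs, c))
        raise KeyError(f"no record at {angle} deg")

    @property
    def angles(self):
        return [r["angle_deg"] for r in self.records]


def _model_wrench(model, gs: GSCoordinates):
    """Total ligament + contact wrench on the tibia.

    Returns (moment about tibia origin, force, bundle force dict, summed
    ContactResult), everything in the femur frame.
    """
    pose = pose_from_gs(gs, mirror=bool(getattr(model.config, "mirror_left",
                                                False) if model.config else False))
    t = pose.translation
    f_total = np.zeros(3)
    m_total = np.zeros(3)
    bundle_forces = {}
    for b in model.ligaments.active_bundles:
        _, f_tib, p_t = ligament_wrench(b, pose)
        f_total += f_tib
        m_total += np.cross(p_t - t, f_tib)
        bundle_forces[b.name] = float(np.linalg.norm(f_tib))
    contact_total = ContactResult.zero()
    for _, fem, tib in model.contact_pairs:
        c = contact_wrench(fem, tib, pose, model.contact)
        contact_total = contact_total + c
    f_total += contact_total.total_force
    m_total += (contact_total.total_torque
                - np.cross(t, contact_total.total_force))
    return m_total, f_total, bundle_forces, contact_total


def generalized_residual(q_free, flexion_deg: float, model,
                         loads: LoadCase) -> np.ndarray:
    """Generalized-force residual on (varus, external, medial, anterior,
    superior) at prescribed flexion; N*mm for rotations, N for translations.
    Zero residual means static equilibrium of ligament, contact and
    applied loads."""
    r, _ = _residual_with_state(q_free, flexion_deg, model, loads)
    return r


def _residual_with_state(q_free, flexion_deg, model, loads):
    q_free = np.asarray(q_free, dtype=float)
    gs = GSCoordinates(flexion_deg, *q_free)
    m, f, bundle_forces, contact = _model_wrench(model, gs)
    J = gs_jacobian(gs)
    Q = J.T @ np.concatenate([m, f])
    Q5 = Q[1:] + loads.generalized_applied()
    return Q5, (gs, bundle_forces, contact)


# residual scaling: torques (N*mm) vs forces (N); tolerances 10 N*mm / 0.1 N
_TOL_TORQUE = 10.0
_TOL_FORCE = 0.1


def _scale_vec(tol_force, tol_torque):
    return np.array([1.0 / tol_torque, 1.0 / tol_torque,
                     1.0 / tol_force, 1.0 / tol_force, 1.0 / tol_force])


def solve_equilibrium(flexion_deg: float, loads: LoadCase, model,
                      q0=None, free=FREE_COORDS,
                      tol_force: float = _TOL_FORCE,
                      tol_torque: float = _TOL_TORQUE,
                      max_iter: int = 200) -> EquilibriumState:
    """Solve the five free coordinates for static equilibrium.

    ``q0`` is the warm start (5-vector in FREE_COORDS order; zeros by
    default); ``free`` restricts which coordinates are released (the rest
    stay at their ``q0`` values), which is useful for reduced toy
    problems.  Convergence requires every torque residual below
    ``tol_torque`` (N*mm) and every force residual below ``tol_force``
    (N).  Non-convergence - e.g. an unstable joint after ligament
    resection - is reported via ``converged=False``, never an exception.
    """
    q = np.zeros(5) if q0 is None else np.asarray(q0, dtype=float).copy()
    mask = np.array([c in free for c in FREE_COORDS])
    if not mask.any():
        raise ValueError("at least one coordinate must be free")
    w = _scale_vec(tol_force, tol_torque)

    def masked_residual(x):
        qq = q.copy()
        qq[mask] = x
        try:
            r, aux = _residual_with_state(qq, flexion_deg, model, loads)
        except (GimbalSingularityError, ValueError):
            # off-workspace trial configuration: steer the search away
            return np.full(int(mask.sum()), 1e9), None, qq
        return r[mask], aux, qq

    def scaled(r):
        return r * w[mask]

    x = q[mask].copy()
    r, aux, qq = masked_residual(x)
    best = (np.abs(scaled(r)).max(), x.copy(), r, aux)
    n_iter = 0
    fd_step = 1e-3
    indeterminate = False
    message = ""

    if best[0] < 1.0:
        # already at equilibrium: check it is a determinate one
        J = _fd_jacobian(masked_residual, x, r, fd_step)
        if np.abs(J).max() < 1e-6:
            indeterminate = True
            message = ("zero residual with zero stiffness: equilibrium "
                       "indeterminate (no contact and no taut ligaments?)")
    else:
        for outer in range(3):
            for _ in range(1, max_iter + 1):
                n_iter += 1
                J = _fd_jacobian(masked_residual, x, r, fd_step)
                Js = (w[mask])[:, None] * J
                rs = scaled(r)
                try:
                    step, *_ = np.linalg.lstsq(Js, -rs, rcond=None)
                except np.linalg.LinAlgError:
                    break
                # damped acceptance on the scaled norm
                lam, improved = 1.0, False
                base = np.linalg.norm(rs)
                for _ in range(10):
                    xt = x + lam * step
                    rt, auxt, qt = masked_residual(xt)
                    if np.linalg.norm(scaled(rt)) < base:
                        x, r, aux = xt, rt, auxt
                        improved = True
                        break
                    lam *= 0.5
                if not improved:
                    break
                if np.abs(scaled(r)).max() < best[0]:
                    best = (np.abs(scaled(r)).max(), x.copy(), r, aux)
                if best[0] < 1.0 or n_iter >= max_iter:
                    break
            if best[0] < 1.0 or n_iter >= max_iter:
                break
            # Newton stalled: minimize 0.5*||r||^2 from the best point,
            # then (if it helped) give Newton another round from there
            def fun(xx):
                rr, _, _ = masked_residual(xx)
                return scaled(rr)
            before = best[0]
            try:
                sol = least_squares(fun, best[1], method="lm",
                                    max_nfev=60 * mask.sum())
                rf, auxf, _ = masked_residual(sol.x)
                if np.abs(scaled(rf)).max() < best[0]:
                    best = (np.abs(scaled(rf)).max(), sol.x.copy(), rf, auxf)
            except Exception as exc:   # pragma: no cover - diagnostic path
                message = f"fallback least-squares failed: {exc}"
            x, r, aux = best[1].copy(), best[2], best[3]
            if best[0] < 1.0 or best[0] >= 0.95 * before:
                break

    norm, x, r, aux = best
    q[mask] = x
    gs, bundle_forces, contact = aux
    converged = bool(norm < 1.0)
    if not converged and not message:
        message = (f"not converged after {n_iter} iterations "
                   f"(scaled residual {norm:.3g}); the configuration may "
                   "be unstable")
    r_full = np.full(5, np.nan)
    r_full[mask] = r
    return EquilibriumState(gs=gs, residual=r_full, residual_norm=float(norm),
                            bundle_forces=bundle_forces, contact=contact,
                            converged=converged, iterations=n_iter,
                            indeterminate=indeterminate, message=message)


def _fd_jacobian(masked_residual, x, r0, step):
    n = len(x)
    J = np.zeros((len(r0), n))
    for i in range(n):
        xp = x.copy()
        xp[i] += step
        rp, _, _ = masked_residual(xp)
        J[:, i] = (rp - r0) / step
    return J


def run_passive_flexion(model, n_samples: int = 51,
                        loads: LoadCase | None = None) -> KinematicsTrace:
    """Quasi-static passive flexion over one full 25 s sine cycle.

    Samples the schedule uniformly in time, solving each flexion angle
    with a warm start from the previous equilibrium (continuation).  The
    run stops at the first non-converged sample, returning the partial
    trace with a diagnostic message.
    """
    loads = loads or LoadCase.passive_flexion()
    times = np.linspace(0.0, PASSIVE_PERIOD_S, int(n_samples))
    flexion = passive_flexion_angle(times)
    states = []
    q = np.zeros(5)
    for i, (t, a) in enumerate(zip(times, flexion)):
        st = solve_equilibrium(a, loads, model, q0=q)
        states.append(st)
        if not st.converged:
            return KinematicsTrace(times, flexion, states, complete=False,
                                   message=(f"sample {i} (t={t:.2f} s, "
                                            f"flexion {a:.1f} deg) did not "
                                            f"converge: {st.message}"))
        q = st.gs.as_array()[1:]
    return KinematicsTrace(times, flexion, states)


def _march_to_angle(model, loads, target_deg, q_start, step_deg=5.0):
    """Continuation from extension to a target flexion angle."""
    q = q_start.copy()
    a = 0.0
    last = None
    angles = list(np.arange(step_deg, target_deg, step_deg)) + [target_deg]
    for a in angles:
        last = solve_equilibrium(a, loads, model, q0=q)
        if not last.converged:
            return last, q
        q = last.gs.as_array()[1:]
    return last, q


def run_laxity_test(model, test: str,
                    angles=LAXITY_ANGLES_DEG,
                    load_scale: float = 1.0) -> LaxityResult:
    """Laxity protocol: at each fixed flexion angle solve the passive
    state, then the +load and -load equilibria (both warm-started from
    passive).  Legs are labeled by signed load; a non-converged leg is
    flagged per-leg and surfaces as a missing range, not a crash."""
    if test not in LAXITY_PROTOCOL:
        raise ValueError(f"unknown laxity test {test!r}; "
                         f"expected one of {sorted(LAXITY_PROTOCOL)}")
    passive_loads = LoadCase(label=f"{test}-passive",
                             flexion_schedule="fixed")
    records = []
    q = np.zeros(5)
    for angle in sorted(angles):
        passive, q_at = _march_to_angle(model, passive_loads, angle, q)
        if passive.converged:
            q = q_at
        rec = {"angle_deg": float(angle), "passive": passive}
        for sign, key in ((+1.0, "plus"), (-1.0, "minus")):
            lc = LoadCase.laxity(test, sign)
            lc = _scale_load(lc, test, load_scale)
            q_leg = passive.gs.as_array()[1:]
            st = solve_equilibrium(angle, lc, model, q0=q_leg)
            if not st.converged and passive.converged:
                # continuation in load from the passive state
                st = None
                for frac in (0.25, 0.5, 0.75, 1.0):
                    st = solve_equilibrium(
                        angle, _scale_load(lc, test, frac) if frac != 1.0
                        else lc, model, q0=q_leg)
                    if not st.converged:
                        break
                    q_leg = st.gs.as_array()[1:]
            rec[key] = st
            rec[f"load_{key}"] = sign * LAXITY_PROTOCOL[test]["load"] * load_scale
        records.append(rec)
    return LaxityResult(test=test, records=records)


def _scale_load(lc: LoadCase, test: str, scale: float) -> LoadCase:
    if scale == 1.0:
        return lc
    f = LAXITY_PROTOCOL[test]["field"]
    if LAXITY_PROTOCOL[test]["unit"] == "Nm":
        return _dc_replace(lc, **{f + "_Nm": getattr(lc, f + "_Nm") * scale})
    return _dc_replace(lc, **{f + "_N": getattr(lc, f + "_N") * scale})
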
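"""Quasi-static solver: residual assembly, equilibrium, protocols."""

import dataclasses

import numpy as np
import pytest

from kneesim.cartilage_contact import ContactParameters
from kneesim.equilibrium_solver import (FREE_COORDS, LoadCase,
                                        generalized_residual,
                                        passive_flexion_angle,
                                        run_laxity_test, run_passive_flexion,
                                        solve_equilibrium)
from kneesim.joint_coordinates import BodyPose, GSCoordinates, pose_from_gs
from kneesim.ligament_model import LigamentRegistry, bundle_force, strain
from kneesim.synthetic_knee import (GeometryConfig, KneeModel,
                                    build_synthetic_knee, rectangular_plate)


# --- load cases ------------------------------------------------------------

def test_load_case_defaults_match_protocol_table():
    p = LoadCase.passive_flexion()
    assert (p.vv_torque_Nm, p.ie_torque_Nm, p.ml_force_N, p.ap_force_N) \
        == (0.0, 0.0, 0.0, 0.0)
    assert p.si_force_N == -50.0
    ap = LoadCase.laxity("AP", +1)
    assert ap.ap_force_N == 40.0 and ap.si_force_N == -50.0
    vv = LoadCase.laxity("VV", -1)
    assert vv.vv_torque_Nm == -5.0
    ie = LoadCase.laxity("IE", +1)
    assert ie.ie_torque_Nm == 2.5
    with pytest.raises(ValueError):
        LoadCase.laxity("ML")


def test_passive_flexion_schedule_is_0_90_0_sine():
    t = np.linspace(0, 25, 51)
    a = passive_flexion_angle(t)
    assert np.allclose(a, 45.0 * (1 - np.cos(2 * np.pi * t / 25.0)),
                       atol=1e-12)
    assert a[0] == pytest.approx(0.0, abs=1e-12)
    assert a[25] == pytest.approx(90.0, abs=1e-9)
    assert a[-1] == pytest.approx(0.0, abs=1e-9)


# --- residual --------------------------------------------------------------

def test_symmetric_model_has_zero_offplane_residual():
    """With mirror symmetry and no transverse loads the varus, axial-
    rotation and mediolateral rows vanish at the centered configuration."""
    from conftest import make_symmetric_model
    model = make_symmetric_model()
    loads = LoadCase.passive_flexion()
    r = generalized_residual(np.zeros(5), 0.0, model, loads)
    # rows: (VV Nmm, IE Nmm, ML N, AP N, SI N)
    assert abs(r[0]) < 1e-6
    assert abs(r[1]) < 1e-6
    assert abs(r[2]) < 1e-9
    # sagittal-plane rows need not vanish
    assert abs(r[4]) > 1.0


def test_applied_ap_force_superposes_linearly(default_knee):
    loads = LoadCase.passive_flexion()
    q = np.array([1.0, -2.0, 0.5, 1.0, -0.5])
    r0 = generalized_residual(q, 15.0, default_knee, loads)
    r1 = generalized_residual(
        q, 15.0, default_knee,
        dataclasses.replace(loads, ap_force_N=loads.ap_force_N + 10.0))
    delta = r1 - r0
    assert delta[3] == pytest.approx(10.0, abs=1e-9)
    assert np.allclose(np.delete(delta, 3), 0.0, atol=1e-9)


def _ligament_energy(model, q_free, flexion):
    """Independent total elastic energy of the taut bundles (piecewise
    integral of the force law over length)."""
    gs = GSCoordinates(flexion, *q_free)
    pose = pose_from_gs(gs)
    U = 0.0
    for b in model.ligaments.active_bundles:
        l0 = b.slack_length_l0
        eps = strain(b.length(pose), l0)
        el, k = b.linear_limit, b.stiffness_k
        if eps <= 0:
            continue
        if eps <= 2 * el:
            U += l0 * k * eps ** 3 / (12 * el)
        else:
            U += l0 * (k * (2 * el) ** 3 / (12 * el)
                       + 0.5 * k * ((eps - el) ** 2 - el ** 2))
    return U


def test_residual_is_energy_gradient_for_ligaments_only(default_knee):
    """Contact-free configuration: the generalized ligament forces must be
    minus the gradient of the total elastic energy."""
    model = dataclasses.replace(
        default_knee,
        tibia_cartilage_medial=rectangular_plate(5, 5, -200.0, 2.0),
        tibia_cartilage_lateral=rectangular_plate(5, 5, -200.0, 2.0))
    loads = LoadCase(label="none", si_force_N=0.0)
    q = np.array([2.0, -4.0, 1.0, 2.0, -1.0])
    flexion = 20.0
    r = generalized_residual(q, flexion, model, loads)
    h = 1e-5
    for i, name in enumerate(FREE_COORDS):
        qp, qm = q.copy(), q.copy()
        qp[i] += h
        qm[i] -= h
        dU = (_ligament_energy(model, qp, flexion)
              - _ligament_energy(model, qm, flexion)) / (2 * h)
        # rotational rows are per radian; the FD above is per degree
        if name.endswith("_deg"):
            dU *= np.rad2deg(1.0)
        assert r[i] == pytest.approx(-dU, rel=1e-4, abs=1e-3)


# --- solve_equilibrium -----------------------------------------------------

def _toy_vertical_contact():
    """Plates + no ligaments: a single vertical elastic-foundation contact
    with an analytic load-penetration law F = K * A * d."""
    tib = rectangular_plate(20.0, 20.0, 0.0, 2.0, normal_up=True)
    fem = rectangular_plate(40.0, 40.0, 0.0, 2.0, normal_up=False)
    reg = LigamentRegistry.with_default_parameters()
    reg = LigamentRegistry(tuple(dataclasses.replace(b, active=False)
                                 for b in reg))
    return KneeModel(femur_cartilage_medial=fem,
                     femur_cartilage_lateral=fem.copy(),
                     tibia_cartilage_medial=tib,
                     tibia_cartilage_lateral=tib.copy(),
                     femur_frame=BodyPose.identity("femur"),
                     tibia_frame=BodyPose.identity("tibia"),
                     ligaments=reg, contact=ContactParameters())


def test_single_vertical_contact_matches_analytic_penetration():
    model = _toy_vertical_contact()
    loads = LoadCase(label="press", si_force_N=-50.0)
    st = solve_equilibrium(0.0, loads, model, free=("superior_mm",),
                           q0=np.array([0, 0, 0, 0, -0.01]))
    assert st.converged
    # two identical 20x20 plate pairs resist the 50 N compressive load
    K = model.contact.foundation_stiffness
    expected_depth = 50.0 / (K * 2 * 400.0)
    assert -st.gs.superior_mm == pytest.approx(expected_depth, rel=0.01)
    assert st.contact.resultant_magnitude == pytest.approx(50.0, abs=0.1)


def test_separated_unloaded_model_flags_indeterminate():
    model = _toy_vertical_contact()
    loads = LoadCase(label="free", si_force_N=0.0)
    st = solve_equilibrium(0.0, loads, model,
                           q0=np.array([0, 0, 0, 0, 5.0]))  # separated
    assert st.converged and st.indeterminate
    assert "indeterminate" in st.message


def test_equilibrium_basin_of_attraction(default_knee):
    loads = LoadCase.passive_flexion()
    st = solve_equilibrium(30.0, loads, default_knee,
                           q0=np.array([1.0, -5.0, 0.0, 1.0, 0.0]))
    assert st.converged
    q = st.gs.as_array()[1:]
    for dq in (np.array([0.5, 0.5, 0.5, 0.5, 0.5]),
               np.array([-0.5, 0.5, -0.5, 0.5, -0.5])):
        st2 = solve_equilibrium(30.0, loads, default_knee, q0=q + dq)
        assert st2.converged
        assert np.abs(st2.gs.as_array()[1:] - q).max() < 0.05


def test_converged_states_satisfy_tolerances(passive_trace):
    for s in passive_trace.states:
        assert s.converged
        assert s.residual_norm < 1.0
        assert np.abs(s.residual[:2]).max() < 10.0     # N*mm
        assert np.abs(s.residual[2:]).max() < 0.1      # N
        assert all(f >= 0 for f in s.bundle_forces.values())
        assert s.contact.resultant_magnitude >= 0


# --- protocols -------------------------------------------------------------

def test_passive_trace_schedule_and_time_reversal(passive_trace):
    tr = passive_trace
    assert len(tr) == 51
    assert np.all(np.diff(tr.times_s) > 0)
    assert np.allclose(tr.flexion_deg,
                       45 * (1 - np.cos(2 * np.pi * tr.times_s / 25)))
    # no history dependence: flexion and extension halves coincide
    for c in ("varus_deg", "external_deg", "medial_mm", "anterior_mm",
              "superior_mm"):
        v = tr.coordinate(c)
        assert np.abs(v - v[::-1]).max() < 0.05


def test_zero_magnitude_laxity_returns_passive_position(default_knee):
    res = run_laxity_test(default_knee, "AP", angles=(30.0,),
                          load_scale=0.0)
    rec = res.records[0]
    assert res.range_at(30.0) == pytest.approx(0.0, abs=1e-6)
    assert rec["plus"].gs.anterior_mm == pytest.approx(
        rec["passive"].gs.anterior_mm, abs=1e-6)


def test_doubling_ap_load_does_not_decrease_range(default_knee,
                                                  laxity_results):
    base = laxity_results["AP"].range_at(30.0)
    double = run_laxity_test(default_knee, "AP", angles=(30.0,),
                             load_scale=2.0)
    r2 = double.range_at(30.0)
    if not np.isnan(r2):
        assert r2 >= base - 1e-6


def test_laxity_ranges_nonnegative(laxity_results):
    for res in laxity_results.values():
        for angle in res.angles:
            r = res.range_at(angle)
            assert np.isnan(r) or r >= 0.0
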
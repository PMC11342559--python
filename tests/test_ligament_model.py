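"""Ligament strain-force law, registry and resection protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneesim.joint_coordinates import BodyPose, GSCoordinates, pose_from_gs
from kneesim.ligament_model import (EPS_LINEAR_LIMIT, LigamentBundle,
                                    LigamentRegistry, bundle_force,
                                    ligament_wrench, resect, slack_length,
                                    strain)


# --- slack length (hand evaluations of l0 = lr / (1 + eps_r)) -------------

@pytest.mark.parametrize("lr, er, expected", [
    (31.8, 0.10, 28.909090909090907),   # taut anterior cruciate bundle
    (32.4, -0.10, 36.0),                # slack posterior cruciate bundle
    (50.0, 0.0, 50.0),                  # zero reference strain => l0 = lr
])
def test_slack_length_hand_values(lr, er, expected):
    assert slack_length(lr, er) == pytest.approx(expected, abs=1e-12)


def test_slack_length_domain_errors():
    with pytest.raises(ValueError):
        slack_length(30.0, -1.0)
    with pytest.raises(ValueError):
        slack_length(-1.0, 0.1)


# --- strain ----------------------------------------------------------------

def test_strain_basic_values():
    assert strain(10.0, 10.0) == 0.0
    assert strain(10.5, 10.0) == pytest.approx(0.05, abs=1e-15)
    with pytest.raises(ValueError):
        strain(10.0, 0.0)


def test_strain_at_reference_length_recovers_reference_strain():
    """Composing the strain and slack-length definitions must return the
    registry's reference strain at l = lr, for every bundle."""
    reg = LigamentRegistry.with_default_parameters()
    for b in reg:
        eps = strain(b.reference_length_lr, b.slack_length_l0)
        assert eps == pytest.approx(b.reference_strain, abs=1e-12)


# --- piecewise force law ---------------------------------------------------

@pytest.mark.parametrize("eps, k, expected", [
    (-0.02, 1000.0, 0.0),      # slack branch
    (0.03, 1000.0, 7.5),       # toe: k*eps^2/(4*eps_l)
    (0.06, 1000.0, 30.0),      # toe/linear junction from either branch
    (0.10, 1000.0, 70.0),      # linear: k*(eps - eps_l)
])
def test_force_branch_values(eps, k, expected):
    assert bundle_force(eps, k) == pytest.approx(expected, abs=1e-12)


def test_force_continuity_at_branch_points():
    """Value and slope agree at eps = 0 and eps = 2*eps_l for every
    stiffness in the default table (C1 continuity of the law)."""
    reg = LigamentRegistry.with_default_parameters()
    el = EPS_LINEAR_LIMIT
    for b in reg:
        k = b.stiffness_k
        # value continuity at both branch points (implementation)
        assert abs(bundle_force(0.0, k) - 0.0) < 1e-9
        assert abs(bundle_force(2 * el, k)
                   - bundle_force(2 * el + 1e-15, k)) < 1e-9
        # slope continuity from the branch formulas themselves:
        # d/de [k e^2 / (4 el)] = k e / (2 el); d/de [k (e - el)] = k
        assert abs(k * 0.0 / (2 * el) - 0.0) < 1e-9          # at eps = 0
        assert abs(k * (2 * el) / (2 * el) - k) < 1e-9       # at eps = 2 el
        # and the implementation's local secants converge to those slopes
        h = 1e-7
        sec_toe = (bundle_force(2 * el, k) - bundle_force(2 * el - h, k)) / h
        sec_lin = (bundle_force(2 * el + h, k) - bundle_force(2 * el, k)) / h
        assert sec_toe == pytest.approx(k, rel=1e-5)
        assert sec_lin == pytest.approx(k, rel=1e-5)


@settings(deadline=None, max_examples=200)
@given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5),
       st.sampled_from([1000.0, 1500.0, 2250.0, 4000.0]))
def test_force_monotone_nondecreasing(e1, e2, k):
    lo, hi = sorted((e1, e2))
    assert bundle_force(hi, k) >= bundle_force(lo, k)


def test_force_nonnegative_vectorized():
    eps = np.linspace(-0.3, 0.3, 1001)
    f = bundle_force(eps, 2000.0)
    assert np.all(f >= 0)


# --- ligament wrench -------------------------------------------------------

def _test_bundle(**kw):
    defaults = dict(name="ACLa", femur_attachment=[0, 0, 0],
                    tibia_attachment=[0, -30.0, 0], stiffness_k=1000.0,
                    reference_strain=0.0, reference_length_lr=30.0)
    defaults.update(kw)
    return LigamentBundle(**defaults)


def test_slack_bundle_transmits_nothing():
    b = _test_bundle()
    pose = pose_from_gs(GSCoordinates(superior_mm=-5.0))  # shortens to 25 mm
    f_fem, f_tib, _ = ligament_wrench(b, pose)
    assert np.allclose(f_fem, 0) and np.allclose(f_tib, 0)


def test_stretched_bundle_force_along_attachment_line():
    # stretch to eps = 0.10 with k = 1000 => 70 N pulling tibia superiorly
    b = _test_bundle()
    pose = pose_from_gs(GSCoordinates(superior_mm=3.0))   # length 33 mm
    f_fem, f_tib, p_t = ligament_wrench(b, pose)
    assert np.linalg.norm(f_tib) == pytest.approx(70.0, rel=1e-12)
    direction = (b.femur_attachment - p_t)
    direction /= np.linalg.norm(direction)
    assert np.allclose(f_tib, 70.0 * direction, atol=1e-9)


def test_action_reaction_for_random_poses():
    rng = np.random.default_rng(11)
    b = _test_bundle(reference_strain=0.05)
    for _ in range(50):
        gs = GSCoordinates(*rng.uniform(-20, 20, 3), *rng.uniform(-8, 8, 3))
        f_fem, f_tib, _ = ligament_wrench(b, pose_from_gs(gs))
        assert np.allclose(f_fem + f_tib, 0, atol=1e-12)


def test_coincident_attachments_rejected():
    b = _test_bundle(tibia_attachment=[0, 0, 0])
    with pytest.raises(ValueError):
        ligament_wrench(b, BodyPose.identity())


# --- registry and resection ------------------------------------------------

def test_registry_has_16_unique_bundles_with_positive_parameters():
    reg = LigamentRegistry.with_default_parameters()
    assert len(reg.bundles) == 16
    assert len({b.name for b in reg}) == 16
    for b in reg:
        assert b.stiffness_k > 0 and b.reference_length_lr > 0
        assert b.reference_strain > -1
        # slack length identity holds exactly
        assert b.slack_length_l0 * (1 + b.reference_strain) == pytest.approx(
            b.reference_length_lr, abs=1e-12)


def test_registry_spot_values():
    """Independent spot checks of the default parameter table."""
    reg = LigamentRegistry.with_default_parameters()
    acla = reg["ACLa"]
    assert (acla.stiffness_k, acla.reference_strain,
            acla.reference_length_lr) == (1000.0, 0.10, 31.8)
    dmclp = reg["dMCLp"]
    assert (dmclp.stiffness_k, dmclp.reference_strain,
            dmclp.reference_length_lr) == (2000.0, -0.07, 32.8)
    lcla = reg["LCLa"]
    assert lcla.reference_strain == -0.25


def test_resection_counts_and_idempotence():
    reg = LigamentRegistry.with_default_parameters()
    cut = resect(reg, "ACL")
    assert len(cut.active_bundles) == 14
    again = resect(cut, "ACL")
    assert [b.active for b in again] == [b.active for b in cut]
    assert again.resection_history == ("ACL",)


def test_full_resection_sequence_leaves_posterior_structures():
    reg = LigamentRegistry.with_default_parameters()
    for group in ("ACL", "PCL", "LCL", "MCL"):
        reg = resect(reg, group)
    active = {b.name for b in reg.active_bundles}
    assert active == {"OPLa", "OPLp", "mCAP", "lCAP", "POL", "APL"}
    assert reg.resection_history == ("ACL", "PCL", "LCL", "MCL")


def test_unknown_resection_group_rejected():
    reg = LigamentRegistry.with_default_parameters()
    with pytest.raises(ValueError):
        resect(reg, "patella")


def test_registry_csv_round_trip(tmp_path):
    reg = resect(LigamentRegistry.with_default_parameters(), "PCL")
    path = tmp_path / "ligaments.csv"
    reg.to_csv(path)
    back = LigamentRegistry.from_csv(path)
    for a, b in zip(reg, back):
        assert a.name == b.name and a.active == b.active
        assert a.stiffness_k == b.stiffness_k
        assert a.reference_strain == pytest.approx(b.reference_strain)
        assert np.allclose(a.femur_attachment, b.femur_attachment)
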
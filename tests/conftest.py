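"""Shared fixtures: the default synthetic knee and its protocol runs.

The passive-flexion trace and the three laxity batteries are the
expensive computations of the suite; they are solved once per session
and shared between the module tests and the acceptance tests.
"""

import dataclasses

import numpy as np
import pytest

from kneesim.equilibrium_solver import run_laxity_test, run_passive_flexion
from kneesim.ligament_model import LigamentRegistry, resect
from kneesim.synthetic_knee import (GeometryConfig, build_synthetic_knee,
                                    rectangular_plate)


def make_symmetric_model(condylar_ap_offset=0.0):
    """Mirror-symmetric toy knee: symmetric articular geometry and a
    ligament registry whose medial side mirrors the lateral one (bundles
    without a lateral partner are deactivated, cruciates centered on the
    midline).  Useful for symmetry/causality tests."""
    cfg = GeometryConfig(medial_condyle_radius=22.0,
                         lateral_condyle_radius=22.0,
                         medial_dish_radius=40.0, lateral_dish_radius=40.0,
                         condylar_ap_offset=condylar_ap_offset)
    model = build_synthetic_knee(cfg)
    pairs = {"sMCLa": "LCLa", "sMCLp": "LCLp", "mCAP": "lCAP",
             "POL": "APL", "dMCLa": None, "dMCLp": None,
             "OPLa": None, "OPLp": None}
    reg = model.ligaments
    mirrored = []
    for b in reg:
        src = pairs.get(b.name)
        if src is None and b.name in pairs:
            mirrored.append(dataclasses.replace(b, active=False))
        elif src is not None:
            lat = reg[src]
            mirrored.append(dataclasses.replace(
                b,
                femur_attachment=lat.femur_attachment * [1, 1, -1],
                tibia_attachment=lat.tibia_attachment * [1, 1, -1],
                stiffness_k=lat.stiffness_k,
                reference_strain=lat.reference_strain,
                reference_length_lr=lat.reference_length_lr))
        elif b.name in ("ACLa", "ACLp", "PCLa", "PCLp"):
            mirrored.append(dataclasses.replace(
                b, femur_attachment=b.femur_attachment * [1, 1, 0],
                tibia_attachment=b.tibia_attachment * [1, 1, 0]))
        else:
            mirrored.append(b)
    return dataclasses.replace(
        model, ligaments=LigamentRegistry(tuple(mirrored)))


@pytest.fixture(scope="session")
def default_knee():
    return build_synthetic_knee()


@pytest.fixture(scope="session")
def passive_trace(default_knee):
    return run_passive_flexion(default_knee, n_samples=51)


@pytest.fixture(scope="session")
def laxity_results(default_knee):
    return {test: run_laxity_test(default_knee, test)
            for test in ("AP", "VV", "IE")}


@pytest.fixture(scope="session")
def acl_resected_ap_laxity(default_knee):
    model = default_knee.with_ligaments(resect(default_knee.ligaments, "ACL"))
    return run_laxity_test(model, "AP", angles=(30.0,))


@pytest.fixture
def slab_pair():
    """Overlapping parallel plates: tibial 20x20 mm at y=0 (normals up),
    femoral 40x40 mm at y=-0.5 (normals down) => uniform 0.5 mm overlap."""
    tib = rectangular_plate(20.0, 20.0, 0.0, edge_length=2.0, normal_up=True)
    fem = rectangular_plate(40.0, 40.0, -0.5, edge_length=2.0, normal_up=False)
    return fem, tib


def rng(seed=0):
    return np.random.default_rng(seed)
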
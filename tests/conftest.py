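"""Shared fixtures: small test anatomies and cached expensive simulations.

Expensive artifacts (EP solutions, beats, personalization runs) are
session-scoped so unit tests and end-to-end checks reuse them.
"""

import numpy as np
import pytest

from cardiotwin import (AnatomyConfig, EPParameters, HemoParameters,
                        MechParameters, Stimulus, StimulusProtocol,
                        build_biventricular_mesh, build_torso, compute_ecg,
                        extract_features, generate_fibers, simulate_beat,
                        simulate_ep, sinus_protocol)
from cardiotwin.personalize import (ClinicalTargets, EPPersonalization,
                                    MechanicsFit)


SMALL_BIV_CONFIG = AnatomyConfig(
    lv_radii=(15.0, 15.0, 28.0), lv_wall_thickness=7.0,
    rv_radii=(24.0, 20.0, 26.0), rv_center_offset=(-10.0, 5.0, 2.0),
    edge_length=3.5, fast_layer_thickness=1.0)

LV_ONLY_CONFIG = AnatomyConfig(
    lv_radii=(14.0, 14.0, 22.0), lv_wall_thickness=7.0,
    include_rv=False, edge_length=4.5, fast_layer_thickness=1.0)


@pytest.fixture(scope="session")
def small_biv_mesh():
    return build_biventricular_mesh(SMALL_BIV_CONFIG, seed=2)


@pytest.fixture(scope="session")
def small_biv_fibers(small_biv_mesh):
    return generate_fibers(small_biv_mesh)


@pytest.fixture(scope="session")
def small_torso(small_biv_mesh):
    return build_torso(small_biv_mesh)


@pytest.fixture(scope="session")
def sinus_solution_full(small_biv_mesh, small_biv_fibers):
    """Sinus-activated monodomain run long enough to cover repolarization."""
    params = EPParameters()
    protocol = sinus_protocol(small_biv_mesh)
    duration = 170.0 + params.apd_estimate + 80.0
    sol = simulate_ep(small_biv_mesh, small_biv_fibers, params, protocol,
                      duration=duration, dt=0.1)
    return params, sol


@pytest.fixture(scope="session")
def sinus_trace(sinus_solution_full, small_biv_mesh, small_biv_fibers,
                small_torso):
    params, sol = sinus_solution_full
    return compute_ecg(sol, small_biv_mesh, small_biv_fibers, params,
                       small_torso)


@pytest.fixture(scope="session")
def lv_mesh():
    return build_biventricular_mesh(LV_ONLY_CONFIG, seed=3)


@pytest.fixture(scope="session")
def lv_fibers(lv_mesh):
    return generate_fibers(lv_mesh)


@pytest.fixture(scope="session")
def lv_ep_solution(lv_mesh, lv_fibers):
    """Apex-paced activation of the LV-only mesh (no septal His sites)."""
    apex = np.flatnonzero(lv_mesh.nodes[:, 2] < lv_mesh.nodes[:, 2].min() + 6)
    protocol = StimulusProtocol((Stimulus(apex, 0.0, 2.0, 1.0),), "apex")
    return simulate_ep(lv_mesh, lv_fibers, EPParameters(), protocol,
                       duration=420.0, dt=0.1)


@pytest.fixture(scope="session")
def hemo():
    return HemoParameters(cycle_length=700.0)


@pytest.fixture(scope="session")
def base_beat(lv_mesh, lv_fibers, lv_ep_solution, hemo):
    """One full default-parameter beat: (states, loops)."""
    return simulate_beat(lv_mesh, lv_fibers, lv_ep_solution,
                         MechParameters(), hemo, dt=2.5, n_cycles=1)


@pytest.fixture(scope="session")
def ep_recovery(small_biv_mesh, small_biv_fibers, small_torso):
    """Self-consistency EP personalization: targets generated by the forward
    model at known parameters, fitted from the population defaults."""
    truth = EPParameters(c_myo=320.0, c_lv=1600.0, c_rv=2200.0,
                         tau_close=170.0)
    protocol = sinus_protocol(small_biv_mesh)
    sol = simulate_ep(small_biv_mesh, small_biv_fibers, truth, protocol,
                      duration=170.0 + truth.apd_estimate + 80.0, dt=0.1)
    feats = extract_features(compute_ecg(sol, small_biv_mesh,
                                         small_biv_fibers, truth,
                                         small_torso))
    targets = ClinicalTargets(m_qrsd=feats.qrsd, m_ea=feats.ea,
                              m_qt=feats.qtd)
    model = EPPersonalization(targets, small_biv_mesh, small_biv_fibers,
                              small_torso)
    return truth, targets, model.fit()


@pytest.fixture(scope="session")
def mech_recovery(lv_mesh, lv_fibers, lv_ep_solution, hemo):
    """Self-consistency (E, sigma0) estimation against a forward beat."""
    e_true, s_true = 450.0, 380.0
    _, loops = simulate_beat(lv_mesh, lv_fibers, lv_ep_solution,
                             MechParameters(young_modulus=e_true,
                                            sigma0=s_true),
                             hemo, dt=2.5)
    s = loops["LV"].summary()
    targets = ClinicalTargets(ef=s["EF_percent"], sv=s["SV_ml"],
                              edv=s["EDV_ml"], esv=s["ESV_ml"],
                              edp=s["EDP_mmHg"], esp=s["ESP_mmHg"])
    model = MechanicsFit(targets, lv_mesh, lv_fibers, lv_ep_solution, hemo,
                         dt=2.5)
    result = model.fit(maxfev=16)
    return (e_true, s_true), targets, result
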
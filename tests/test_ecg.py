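"""Torso model, pseudo-ECG and feature extraction."""

import numpy as np
import pytest

from cardiotwin import (ECGFeatures, EPParameters, Stimulus, StimulusProtocol,
                        TorsoConfig, build_torso, compute_ecg,
                        extract_features, simulate_ep)
from cardiotwin.ecg import ECGTrace, LEAD_NAMES
from cardiotwin.ep import EPSolution
from cardiotwin.fibers import uniform_fibers
from cardiotwin.geometry import box_mesh


def test_electrodes_on_torso_surface(small_biv_mesh):
    torso = build_torso(small_biv_mesh)
    assert len(torso.electrodes) == 10
    for name, pos in torso.electrodes.items():
        assert abs(torso.surface_residual(pos)) < 1e-6, name


def test_torso_build_deterministic(small_biv_mesh):
    t1 = build_torso(small_biv_mesh)
    t2 = build_torso(small_biv_mesh)
    for name in t1.electrodes:
        assert np.array_equal(t1.electrodes[name], t2.electrodes[name])


def test_heart_must_fit_inside_torso(small_biv_mesh):
    with pytest.raises(ValueError, match="torso"):
        build_torso(small_biv_mesh, TorsoConfig(semi_axes=(20.0, 20.0, 20.0),
                                                center=(0.0, 0.0, 0.0)))


def test_uniform_potential_gives_zero_leads(small_biv_mesh, small_biv_fibers):
    mesh = small_biv_mesh
    n = mesh.n_nodes
    sol = EPSolution(times=np.arange(0.0, 10.0),
                     u=np.ones((10, n)) * 0.7,
                     activation=np.zeros(n), repolarization=np.full(n, 5.0))
    trace = compute_ecg(sol, mesh, small_biv_fibers, EPParameters(),
                        build_torso(mesh))
    assert np.allclose(trace.as_array(), 0.0, atol=1e-12)


def test_wavefront_toward_la_gives_positive_lead_i():
    """A depolarization wave travelling leftward (toward the LA electrode)
    produces a positive deflection in lead I (dipole sign convention)."""
    mesh = box_mesh(3, 3, 20, dx=1.0, origin=(0.0, 0.0, -10.0))
    # rotate bar onto the x axis: built along z, so swap axes
    mesh.nodes = mesh.nodes[:, [2, 0, 1]]
    fib = uniform_fibers(mesh, [1.0, 0.0, 0.0])
    p = EPParameters(c_myo=800.0, c_lv=1652.0, c_rv=1652.0)
    stim = np.flatnonzero(mesh.nodes[:, 0] < -8.0)
    sol = simulate_ep(mesh, fib, p,
                      StimulusProtocol((Stimulus(stim, 0, 2.0, 1.0),), "p"),
                      duration=40.0, dt=0.1)
    trace = compute_ecg(sol, mesh, fib, p, build_torso(mesh))
    lead_i = trace.leads["I"]
    assert lead_i.max() > 0
    assert np.trapezoid(lead_i) > 0
    assert lead_i.max() > abs(lead_i.min())


def test_einthoven_identity(sinus_trace):
    resid = (sinus_trace.leads["I"] + sinus_trace.leads["III"]
             - sinus_trace.leads["II"])
    scale = np.ptp(sinus_trace.leads["II"])
    assert np.max(np.abs(resid)) < 1e-9 * scale


def test_stride_too_coarse_rejected(small_biv_mesh, small_biv_fibers,
                                    sinus_solution_full):
    params, sol = sinus_solution_full
    coarse = EPSolution(times=sol.times[::4], u=sol.u[::4],
                        activation=sol.activation,
                        repolarization=sol.repolarization)
    with pytest.raises(ValueError, match="stride"):
        compute_ecg(coarse, small_biv_mesh, small_biv_fibers, params,
                    build_torso(small_biv_mesh))


def _synthetic_trace(i_pulse, avf_pulse, dt=1.0, n=400):
    t = np.arange(n) * dt
    zero = np.zeros(n)
    leads = {name: zero.copy() for name in LEAD_NAMES}
    leads["I"] = i_pulse
    leads["aVF"] = avf_pulse
    # keep the limb-lead algebra consistent: II = I/2 + aVF, III = aVF - I/2
    leads["II"] = 0.5 * i_pulse + avf_pulse
    leads["III"] = avf_pulse - 0.5 * i_pulse
    return ECGTrace(times=t, leads=leads)


def _pulse(n, t0, t1, dt=1.0):
    t = np.arange(n) * dt
    out = np.zeros(n)
    mask = (t >= t0) & (t <= t1)
    out[mask] = np.sin(np.pi * (t[mask] - t0) / (t1 - t0)) ** 2
    return out


def test_qrsd_on_constructed_pulse():
    n = 400
    trace = _synthetic_trace(_pulse(n, 0.0, 100.0), np.zeros(n))
    feats = extract_features(trace)
    assert feats.qrsd == pytest.approx(100.0, abs=2 * trace.sample_interval)
    assert np.isnan(feats.qtd)


def test_axis_conventions():
    n = 400
    # all QRS area in lead I, none in aVF -> axis 0 deg
    f0 = extract_features(_synthetic_trace(_pulse(n, 0, 80), np.zeros(n)))
    assert f0.ea == pytest.approx(0.0, abs=1.0)
    # equal areas -> 45 deg
    f45 = extract_features(_synthetic_trace(_pulse(n, 0, 80),
                                            _pulse(n, 0, 80)))
    assert f45.ea == pytest.approx(45.0, abs=1.0)
    # rotating the dipole content by 90 deg rotates the axis by 90 deg
    f90 = extract_features(_synthetic_trace(np.zeros(n), _pulse(n, 0, 80)))
    assert f90.ea - f0.ea == pytest.approx(90.0, abs=1.0)


def test_features_invariant_to_scale_and_shift(sinus_trace):
    base = extract_features(sinus_trace)
    scaled = ECGTrace(times=sinus_trace.times,
                      leads={k: 7.3 * v for k, v in sinus_trace.leads.items()})
    f2 = extract_features(scaled)
    assert f2.qrsd == base.qrsd and f2.qtd == base.qtd
    assert f2.ea == pytest.approx(base.ea, abs=1e-9)
    shift = 30
    shifted = ECGTrace(
        times=sinus_trace.times,
        leads={k: np.concatenate([np.zeros(shift), v[:-shift]])
               for k, v in sinus_trace.leads.items()})
    f3 = extract_features(shifted)
    # the unshifted recording starts exactly at stimulus onset, so shifting
    # can expose a few ms of onset that were clipped at the boundary
    assert f3.qrsd == pytest.approx(base.qrsd,
                                    abs=5 * sinus_trace.sample_interval)
    assert f3.ea == pytest.approx(base.ea, abs=2.0)


def test_flat_trace_raises():
    n = 100
    zero = np.zeros(n)
    trace = ECGTrace(times=np.arange(n, dtype=float),
                     leads={name: zero for name in LEAD_NAMES})
    with pytest.raises(ValueError, match="no QRS"):
        extract_features(trace)


def test_torso_scaling_preserves_features(small_biv_mesh, small_biv_fibers,
                                          sinus_solution_full, sinus_trace):
    """Scaling the torso changes lead amplitudes but not timing features."""
    params, sol = sinus_solution_full
    big = build_torso(small_biv_mesh,
                      TorsoConfig(semi_axes=(400.0, 300.0, 640.0),
                                  center=(-70.0, -90.0, 0.0)))
    trace2 = compute_ecg(sol, small_biv_mesh, small_biv_fibers, params, big)
    f1 = extract_features(sinus_trace)
    f2 = extract_features(trace2)
    dt = sinus_trace.sample_interval
    assert f2.qrsd == pytest.approx(f1.qrsd, abs=3 * dt)
    assert f2.qtd == pytest.approx(f1.qtd, abs=5 * dt)
    assert f2.ea == pytest.approx(f1.ea, abs=5.0)
    # amplitudes shrink with distance
    assert np.ptp(trace2.leads["II"]) < np.ptp(sinus_trace.leads["II"])


def test_qt_increases_with_tau_close(small_biv_mesh, small_biv_fibers,
                                     small_torso):
    from cardiotwin import sinus_protocol

    protocol = sinus_protocol(small_biv_mesh)
    qts = []
    for tc in (130.0, 180.0):
        p = EPParameters(tau_close=tc)
        sol = simulate_ep(small_biv_mesh, small_biv_fibers, p, protocol,
                          duration=170.0 + p.apd_estimate + 80.0, dt=0.1)
        trace = compute_ecg(sol, small_biv_mesh, small_biv_fibers, p,
                            small_torso)
        qts.append(extract_features(trace).qtd)
    assert qts[1] > qts[0] + 40.0  # slope ~ ln(tau_out/(4 tau_in)) ~ 1.6


def test_feature_invariants():
    with pytest.raises(ValueError):
        ECGFeatures(qrsd=120.0, qtd=100.0, ea=10.0)
    with pytest.raises(ValueError):
        ECGFeatures(qrsd=100.0, qtd=400.0, ea=250.0)
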
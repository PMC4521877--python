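"""Torso model, pseudo-ECG synthesis and feature extraction.

The default forward model is the infinite-homogeneous-medium pseudo-ECG:
the extracellular potential at an electrode is the volume sum of the
current-dipole field of each element,

    phi(e, t) = -sum_el  V_el (D grad u) . grad_x(1/|x_e - x_el|),

which captures the timing features (QRS duration, QT interval, electrical
axis) that global personalization targets; those features are insensitive
to torso conductivity heterogeneity, which is why a bounded-torso boundary
element solver is not required here.

Coordinate conventions: x = patient's left, y = anterior, z = cranial.
The electrical axis is reported in clinical convention: 0 deg along lead I
(leftward), positive rotating toward +aVF (inferior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fem
from .ep import assemble_diffusivity

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
CHEST_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")
LEAD_NAMES = LIMB_LEADS + CHEST_LEADS

# electrode placement on the torso ellipsoid: (azimuth deg from +x in the
# xy-plane, fractional height zeta in [-1, 1])
_ELECTRODE_PARAMS = {
    "RA": (170.0, 0.55), "LA": (10.0, 0.55),
    "LL": (45.0, -0.75), "RL": (135.0, -0.75),
    "V1": (100.0, 0.05), "V2": (80.0, 0.05), "V3": (62.0, 0.02),
    "V4": (45.0, 0.0), "V5": (25.0, 0.0), "V6": (5.0, 0.0),
}


@dataclass(frozen=True)
class TorsoConfig:
    semi_axes: tuple = (200.0, 150.0, 320.0)  # mm
    center: tuple = (-35.0, -45.0, 0.0)       # heart sits left-anterior


@dataclass
class TorsoModel:
    center: np.ndarray
    semi_axes: np.ndarray
    electrodes: dict  # name -> xyz (mm), on the torso surface

    def surface_residual(self, point):
        q = (np.asarray(point) - self.center) / self.semi_axes
        return float(q @ q - 1.0)


def build_torso(mesh, config=None):
    """Parametric ellipsoidal torso containing the heart, with the ten
    standard electrodes at fixed fractional surface coordinates."""
    config = config or TorsoConfig()
    center = np.asarray(config.center, dtype=float)
    semi = np.asarray(config.semi_axes, dtype=float)
    q = (mesh.nodes - center) / semi
    worst = np.max(np.einsum("ij,ij->i", q, q))
    if worst >= 1.0:
        raise ValueError(
            f"heart extends outside the torso (max normalized radius "
            f"{np.sqrt(worst):.2f}); enlarge the torso semi-axes")
    electrodes = {}
    for name, (az, zeta) in _ELECTRODE_PARAMS.items():
        rho = np.sqrt(max(0.0, 1.0 - zeta ** 2))
        a = np.deg2rad(az)
        electrodes[name] = center + semi * np.array(
            [rho * np.cos(a), rho * np.sin(a), zeta])
    return TorsoModel(center=center, semi_axes=semi, electrodes=electrodes)


@dataclass
class ECGTrace:
    """12-lead time series on a common time base (arbitrary mV-scale)."""

    times: np.ndarray             # ms
    leads: dict                   # name -> (nt,) array

    @property
    def sample_interval(self):
        return float(self.times[1] - self.times[0])

    def as_array(self, names=LEAD_NAMES):
        return np.stack([self.leads[n] for n in names])

    def to_csv(self, path):
        import pandas as pd
        df = pd.DataFrame({"time_ms": self.times,
                           **{n: self.leads[n] for n in LEAD_NAMES}})
        with open(path, "w") as fh:
            fh.write("# cardiotwin ECG trace; time in ms, leads in "
                     "arbitrary mV-scale units\n")
            df.to_csv(fh, index=False)


@dataclass(frozen=True)
class ECGFeatures:
    qrsd: float          # ms
    qtd: float           # ms (nan if repolarization not simulated)
    ea: float            # degrees, frontal plane

    def __post_init__(self):
        if np.isfinite(self.qtd) and not 0 < self.qrsd < self.qtd:
            raise ValueError("requires 0 < QRSd < QTd")
        if not -180.0 < self.ea <= 180.0:
            raise ValueError("electrical axis must lie in (-180, 180]")


def compute_ecg(solution, mesh, fiber_field, params, torso):
    """Pseudo-ECG at the 12 leads from a monodomain solution.

    Requires the solution to be sampled at <= 2 ms stride so the QRS
    deflections are resolved.
    """
    if len(solution.times) > 1 and solution.times[1] - solution.times[0] > 2.0 + 1e-9:
        raise ValueError("EPSolution stride too coarse for ECG (need <= 2 ms)")
    vols, grads = _fem.shape_gradients(mesh.nodes, mesh.tets)
    D = assemble_diffusivity(mesh, fiber_field, params) / 1000.0  # mm^2/ms
    cents = mesh.element_centroids()
    names = list(torso.electrodes)
    W = np.empty((len(names), mesh.n_elements, 3))
    for i, name in enumerate(names):
        xe = torso.electrodes[name]
        r = xe - cents
        rn = np.linalg.norm(r, axis=1)
        if rn.min() < 1e-6:
            raise ValueError(f"electrode {name} lies inside the myocardium")
        W[i] = vols[:, None] * r / rn[:, None] ** 3
    # per-element D grad(u) for all recorded times
    gU = np.einsum("eki,tek->tei", grads, solution.u[:, mesh.tets])
    J = np.einsum("eab,teb->tea", D, gU)
    phi = {n: -np.einsum("tea,ea->t", J, W[i]) for i, n in enumerate(names)}

    wct = (phi["RA"] + phi["LA"] + phi["LL"]) / 3.0
    leads = {
        "I": phi["LA"] - phi["RA"],
        "II": phi["LL"] - phi["RA"],
        "III": phi["LL"] - phi["LA"],
        "aVR": phi["RA"] - 0.5 * (phi["LA"] + phi["LL"]),
        "aVL": phi["LA"] - 0.5 * (phi["RA"] + phi["LL"]),
        "aVF": phi["LL"] - 0.5 * (phi["RA"] + phi["LA"]),
    }
    for v in CHEST_LEADS:
        leads[v] = phi[v] - wct
    return ECGTrace(times=solution.times.copy(), leads=leads)


def _activity_groups(active, times, gap_ms):
    """Contiguous activity bursts separated by quiet gaps > gap_ms."""
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        return []
    dt = times[1] - times[0]
    gap = max(1, int(round(gap_ms / dt)))
    splits = np.flatnonzero(np.diff(idx) > gap)
    return np.split(idx, splits + 1)


def extract_features(trace, threshold_frac=0.05, gap_ms=50.0,
                     t_wave_frac=0.1, t_wave_floor=0.005):
    """QRS duration, QT duration and electrical axis from a 12-lead trace.

    The QRS complex is the first activity burst of the RMS spatial velocity
    (root-mean-square over leads of dV/dt) above ``threshold_frac`` of its
    peak.  The T wave is much slower than the QRS, so its end is detected
    with a threshold relative to the post-QRS velocity peak
    (``t_wave_frac``); a post-QRS peak below ``t_wave_floor`` of the global
    peak means repolarization was not simulated and QT is NaN.  The axis is
    atan2 of the net aVF and lead-I areas over the QRS window.
    """
    arr = trace.as_array()
    dt = trace.sample_interval
    vel = np.gradient(arr, dt, axis=1)
    rms = np.sqrt((vel ** 2).mean(axis=0))
    if rms.max() <= 0 or np.ptp(arr) < 1e-12:
        raise ValueError("no QRS detected (flat trace)")
    # smooth over ~3 samples to suppress single-sample spikes
    kernel = np.ones(3) / 3.0
    rms = np.convolve(rms, kernel, mode="same")
    active = rms > threshold_frac * rms.max()
    groups = _activity_groups(active, trace.times, gap_ms)
    if not groups:
        raise ValueError("no QRS detected")
    qrs = groups[0]
    t_on, t_off = trace.times[qrs[0]], trace.times[qrs[-1]]
    qrsd = t_off - t_on
    # T-wave end from the post-QRS segment with its own adaptive threshold
    qtd = np.nan
    post_start = qrs[-1] + max(1, int(round(gap_ms / dt)))
    post = rms[post_start:]
    if len(post) and post.max() > t_wave_floor * rms.max():
        above = np.flatnonzero(post > t_wave_frac * post.max())
        qtd = trace.times[post_start + above[-1]] - t_on
    win = slice(qrs[0], qrs[-1] + 1)
    area_i = np.trapezoid(trace.leads["I"][win], dx=dt)
    area_avf = np.trapezoid(trace.leads["aVF"][win], dx=dt)
    ea = float(np.degrees(np.arctan2(area_avf, area_i)))
    if ea <= -180.0:
        ea += 360.0
    return ECGFeatures(qrsd=float(qrsd), qtd=float(qtd), ea=ea)
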
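"""Lumped intra-cardiac hemodynamics.

Afterload is a 3-element Windkessel per artery (characteristic resistance
Rc in series with a peripheral resistance Rp / compliance C pair referenced
to a remote pressure Pr).  Preload is a constant atrial pressure plus a
timed half-sinusoid contraction bump.  The four cardiac phases (filling,
isovolumetric contraction, ejection, isovolumetric relaxation) are switched
by pressure/flow conditions, and the ventricular pressure during the
isovolumetric phases is found by a prediction-correction (bracketed root
finding) on the mechanical volume response.

Units: pressures in mmHg, volumes in mm^3 at this module's level (ml at
reporting interfaces), flow in mm^3/s, resistances in mmHg*s/mm^3 and
compliance in mm^3/mmHg.  Printed resistance tables usually omit the time
unit; the per-second convention is the only one that closes the ODE with
flows in mm^3/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Phase(Enum):
    FILLING = "FILLING"
    ISO_CONTRACTION = "ISO_CONTRACTION"
    EJECTION = "EJECTION"
    ISO_RELAXATION = "ISO_RELAXATION"


_PHASE_ORDER = [Phase.FILLING, Phase.ISO_CONTRACTION, Phase.EJECTION,
                Phase.ISO_RELAXATION]


@dataclass(frozen=True)
class WindkesselParameters:
    """3-element Windkessel afterload (defaults: systemic/aortic cohort means)."""

    C: float = 2269.0       # mm^3/mmHg
    Rp: float = 3.64e-4     # mmHg*s/mm^3
    Rc: float = 4.72e-5     # mmHg*s/mm^3
    Pr: float = 52.0        # mmHg

    def __post_init__(self):
        if min(self.C, self.Rp, self.Rc) <= 0 or self.Pr <= 0:
            raise ValueError("Windkessel parameters must be positive")

    @classmethod
    def pulmonary_defaults(cls):
        return cls(C=2757.0, Rp=1.51e-4, Rc=2.91e-5, Pr=15.0)

    def steady_pressure(self, Q):
        """Asymptotic proximal pressure under constant flow Q (mm^3/s)."""
        return self.Pr + (self.Rc + self.Rp) * Q


def wk3_step(p_prox, p_distal, Q, dt, wk, scheme="semi-implicit"):
    """Advance the Windkessel state one step of ``dt`` seconds.

    State equation  C dp_distal/dt = Q - (p_distal - Pr)/Rp ;
    output equation p_prox = p_distal + Rc * Q.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = wk.Rp * wk.C
    if scheme == "explicit":
        p_distal = p_distal + dt * (Q / wk.C - (p_distal - wk.Pr) / tau)
    else:  # unconditionally stable semi-implicit (exact for constant Q)
        target = wk.Pr + wk.Rp * Q
        p_distal = target + (p_distal - target) * np.exp(-dt / tau)
    return p_distal + wk.Rc * Q, p_distal


@dataclass(frozen=True)
class AtrialModel:
    """Constant baseline atrial pressure plus a half-sinusoid contraction
    bump (a documented surrogate for a full lumped atrium)."""

    baseline: float = 8.0          # mmHg
    bump_amplitude: float = 4.0    # mmHg
    bump_onset: float = -120.0     # ms relative to cycle end (late diastole)
    bump_duration: float = 100.0   # ms

    def __post_init__(self):
        if self.baseline < 0 or self.bump_amplitude < 0:
            raise ValueError("atrial pressures must be >= 0")

    def pressure(self, t, cycle_length):
        t_mod = np.mod(t, cycle_length)
        onset = np.mod(self.bump_onset, cycle_length)
        phase = (t_mod - onset) / self.bump_duration
        bump = np.where((phase >= 0) & (phase <= 1),
                        np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
        return self.baseline + self.bump_amplitude * bump


@dataclass(frozen=True)
class HemoParameters:
    """Everything the beat simulation needs on the circulation side."""

    wk: WindkesselParameters = field(default_factory=WindkesselParameters)
    atrium: AtrialModel = field(default_factory=AtrialModel)
    cycle_length: float = 800.0    # ms
    filling_resistance: float = 5e-5  # mmHg*s/mm^3, mitral inflow


def phase_machine(p_v, p_atrium, p_art, dVdt, phase):
    """Valve-logic transition between the four cardiac phases.

    FILLING -> ISO_CONTRACTION when ventricular pressure rises above atrial;
    ISO_CONTRACTION -> EJECTION when it reaches arterial pressure;
    EJECTION -> ISO_RELAXATION when forward flow would reverse (dV/dt >= 0);
    ISO_RELAXATION -> FILLING when pressure falls below atrial.
    """
    if phase == Phase.FILLING and p_v > p_atrium:
        return Phase.ISO_CONTRACTION
    if phase == Phase.ISO_CONTRACTION and p_v >= p_art:
        return Phase.EJECTION
    if phase == Phase.EJECTION and dVdt >= 0:
        return Phase.ISO_RELAXATION
    if phase == Phase.ISO_RELAXATION and p_v < p_atrium:
        return Phase.FILLING
    return phase


def isovolumetric_pressure(volume_of_pressure, target_volume, bracket,
                           rel_tol=0.002, max_iter=60):
    """Cavity pressure that holds the volume at ``target_volume``.

    ``volume_of_pressure`` is the mechanics response (callable, mmHg -> mm^3
    or ml, monotone increasing).  Bracketed bisection/secant via brentq;
    raises if the bracket does not contain the root.
    """
    from scipy.optimize import brentq

    lo, hi = bracket
    f_lo = volume_of_pressure(lo) - target_volume
    f_hi = volume_of_pressure(hi) - target_volume
    if f_lo * f_hi > 0:
        raise ValueError(
            f"pressure bracket [{lo}, {hi}] mmHg does not contain the "
            f"isovolumetric root (residuals {f_lo:.3g}, {f_hi:.3g})")
    p = brentq(lambda q: volume_of_pressure(q) - target_volume, lo, hi,
               xtol=1e-4, rtol=1e-10, maxiter=max_iter)
    v = volume_of_pressure(p)
    if abs(v - target_volume) / abs(target_volume) > max(rel_tol, 0.01):
        raise ValueError("isovolumetric correction did not reach 1% accuracy")
    return p


@dataclass
class PVLoop:
    """Ventricular pressure-volume trajectory and its clinical scalars."""

    times: np.ndarray        # ms
    pressure: np.ndarray     # mmHg
    volume: np.ndarray       # ml
    phase: np.ndarray        # array of Phase values

    def _first_transition(self, a, b):
        ph = self.phase
        for i in range(1, len(ph)):
            if ph[i - 1] == a and ph[i] == b:
                return i
        return None

    @property
    def edv(self):
        i = self._first_transition(Phase.FILLING, Phase.ISO_CONTRACTION)
        return float(self.volume[:i + 1].max() if i is not None
                     else self.volume.max())

    @property
    def esv(self):
        i = self._first_transition(Phase.EJECTION, Phase.ISO_RELAXATION)
        return float(self.volume[i] if i is not None else self.volume.min())

    @property
    def sv(self):
        return self.edv - self.esv

    @property
    def ef(self):
        return 100.0 * self.sv / self.edv

    @property
    def edp(self):
        i = self._first_transition(Phase.FILLING, Phase.ISO_CONTRACTION)
        return float(self.pressure[i - 1] if i else self.pressure[0])

    @property
    def esp(self):
        i = self._first_transition(Phase.EJECTION, Phase.ISO_RELAXATION)
        return float(self.pressure[i] if i is not None else self.pressure.max())

    def summary(self):
        return {"EDV_ml": self.edv, "ESV_ml": self.esv, "SV_ml": self.sv,
                "EF_percent": self.ef, "EDP_mmHg": self.edp,
                "ESP_mmHg": self.esp}

    def phase_sequence(self):
        """Distinct phases in traversal order (consecutive repeats merged)."""
        seq = []
        for ph in self.phase:
            if not seq or seq[-1] != ph:
                seq.append(ph)
        return seq

    def to_csv(self, path):
        import pandas as pd
        df = pd.DataFrame({"time_ms": self.times, "p_mmHg": self.pressure,
                           "v_ml": self.volume,
                           "phase": [p.value for p in self.phase]})
        with open(path, "w") as fh:
            fh.write("# cardiotwin PV loop; time ms, pressure mmHg, volume ml\n")
            df.to_csv(fh, index=False)


def periodic_windkessel_response(wk, flow_samples, dt):
    """Periodic proximal-pressure response to one cycle of sampled flow.

    ``flow_samples`` is Q (mm^3/s) sampled uniformly over one cycle at
    spacing ``dt`` seconds.  The distal-pressure ODE is linear, so the
    periodic orbit is computed in closed form from the one-step recurrence
    p_{n+1} = a p_n + (1 - a) (Pr + Rp Q_n) with a = exp(-dt/(Rp C)).
    Returns p_prox at the sample times.
    """
    Q = np.asarray(flow_samples, dtype=float)
    n = len(Q)
    a = np.exp(-dt / (wk.Rp * wk.C))
    b = (1.0 - a) * (wk.Pr + wk.Rp * Q)
    # homogeneous powers a^k for k = 0..n
    powers = a ** np.arange(n + 1)
    # particular solution with p_0 = 0:  s_n = sum_k a^(n-1-k) b_k
    acc = np.cumsum(b / powers[1:n + 1])
    s = np.concatenate([[0.0], powers[1:n + 1] * acc])
    p0 = s[n] / (1.0 - powers[n])
    p_distal = powers[:n] * p0 + s[:n]
    return p_distal + wk.Rc * Q


def simulate_windkessel(wk, flow_fn, cycle_length_s, dt=1e-3, n_cycles=12,
                        p0=None):
    """Periodic Windkessel response to a flow waveform Q(t) (mm^3/s).

    Runs ``n_cycles`` and returns (t, p_prox, p_distal) of the final cycle.
    """
    p_distal = wk.Pr if p0 is None else p0
    n = int(round(cycle_length_s / dt))
    t_loc = np.arange(n) * dt
    p_prox_cycle = np.empty(n)
    p_dist_cycle = np.empty(n)
    for cyc in range(n_cycles):
        for i, tl in enumerate(t_loc):
            Q = flow_fn(tl)
            p_prox, p_distal = wk3_step(None, p_distal, Q, dt, wk)
            p_prox_cycle[i] = p_prox
            p_dist_cycle[i] = p_distal
    return t_loc, p_prox_cycle, p_dist_cycle
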
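"""Inverse-problem personalization of the heart model.

Three fitting loops, each exposed as a model object whose ``fit()`` returns
a results object with the estimates, per-target residuals and diagnostics:

* :class:`EPPersonalization` — the three-step electrophysiology loop:
  (1) myocardial diffusivity c_myo from the QRS duration, exploiting the
  square-root diffusivity/velocity law for a derivative-free multiplicative
  secant; (2) the fast-layer diffusivities (c_lv, c_rv) from the electrical
  axis with a short Nelder-Mead search; (3) tau_close directly from the QT
  interval through the closed-form APD slope.  The steps iterate until the
  QRS and axis tolerances are met.
* :class:`WindkesselFit` — least-squares fit of the 3-element Windkessel
  (C, Rp, Rc, Pr) to an arterial pressure cycle given the flow waveform.
* :class:`MechanicsFit` — derivative-free minimization over (E, sigma0) of
  the normalized squared mismatch in EF/SV/EDV/ESV/EDP/ESP against a full
  beat simulation.

A trust-region/simplex derivative-free optimizer stands in for the
NEWUOA-class method; the loop logic, not the optimizer, is the substance.
Module-level ``personalize_ep`` / ``personalize_windkessel`` /
``personalize_mechanics`` are thin functional wrappers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.optimize import minimize

from . import ecg as ecg_mod
from . import ep as ep_mod
from .hemodynamics import WindkesselParameters, periodic_windkessel_response
from .mechanics import MechParameters, simulate_beat


@dataclass
class ClinicalTargets:
    """Measured quantities a model can be fitted to; any field may be None."""

    m_qrsd: float | None = None    # ms
    m_ea: float | None = None      # degrees
    m_qt: float | None = None      # ms
    ef: float | None = None        # %
    sv: float | None = None        # ml
    edv: float | None = None       # ml
    esv: float | None = None       # ml
    edp: float | None = None       # mmHg
    esp: float | None = None       # mmHg
    pressure_samples: np.ndarray | None = None  # (n, 2): t_s, p_mmHg
    flow_samples: np.ndarray | None = None      # (n, 2): t_s, Q_mm3_per_s

    def __post_init__(self):
        if all(v is not None for v in (self.ef, self.sv, self.edv)):
            if abs(self.ef - 100.0 * self.sv / self.edv) > 5.0:
                raise ValueError(
                    "inconsistent targets: EF differs from 100*SV/EDV by "
                    "more than 5 points")

    def to_json(self, path):
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        for k in ("pressure_samples", "flow_samples"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k])
        return cls(**d)


def _wrap_angle(a):
    return (a + 180.0) % 360.0 - 180.0


class PersonalizationResult:
    """Common results surface: estimates, residuals, diagnostics, summary."""

    def __init__(self, params, residuals, n_iter, converged, history=None,
                 n_forward=0, title="personalization"):
        self.params = params
        self.residuals = dict(residuals)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self.history = list(history or [])
        self.n_forward = int(n_forward)
        self.title = title

    def summary(self):
        lines = [f"{self.title} results",
                 "=" * (len(self.title) + 8),
                 f"converged: {self.converged}   outer iterations: "
                 f"{self.n_iter}   forward runs: {self.n_forward}", ""]
        lines.append(f"{'parameter':<22}{'estimate':>14}")
        for k, v in asdict(self.params).items():
            if isinstance(v, (int, float)):
                lines.append(f"{k:<22}{v:>14.6g}")
        lines.append("")
        lines.append(f"{'target':<22}{'residual':>14}")
        for k, v in self.residuals.items():
            lines.append(f"{k:<22}{v:>14.4g}")
        return "\n".join(lines)

    def to_json(self, path):
        out = {"params": asdict(self.params), "residuals": self.residuals,
               "n_iter": self.n_iter, "converged": self.converged,
               "n_forward": self.n_forward}
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# EP three-step loop

class EPPersonalization:
    """Fit (c_myo, c_lv, c_rv, tau_close) to QRSd / EA / QT targets."""

    def __init__(self, targets, mesh, fiber_field, torso=None,
                 base_params=None, protocol=None,
                 tol_qrs=5.0, tol_ea=10.0, max_outer=5,
                 qrs_run_ms=170.0, ep_dt=0.1,
                 c_myo_bounds=(60.0, 4000.0), c_fast_bounds=(300.0, 8000.0)):
        if targets.m_qrsd is None:
            raise ValueError("EP personalization needs a QRS-duration target")
        self.targets = targets
        self.mesh = mesh
        self.fibers = fiber_field
        self.torso = torso or ecg_mod.build_torso(mesh)
        self.params = base_params or ep_mod.EPParameters()
        self.protocol = protocol or ep_mod.sinus_protocol(mesh)
        self.tol_qrs = tol_qrs
        self.tol_ea = tol_ea
        self.max_outer = max_outer
        self.qrs_run_ms = qrs_run_ms
        self.ep_dt = ep_dt
        self.c_myo_bounds = c_myo_bounds
        self.c_fast_bounds = c_fast_bounds
        self.n_forward = 0

    # forward model ---------------------------------------------------------

    def _features(self, params, full=False):
        """Simulate and extract ECG features (QRS-only run unless ``full``)."""
        if full:
            duration = self.qrs_run_ms + params.apd_estimate + 80.0
        else:
            duration = self.qrs_run_ms
        sol = ep_mod.simulate_ep(self.mesh, self.fibers, params,
                                 self.protocol, duration=duration,
                                 dt=self.ep_dt)
        trace = ecg_mod.compute_ecg(sol, self.mesh, self.fibers, params,
                                    self.torso)
        self.n_forward += 1
        return ecg_mod.extract_features(trace)

    # fitting steps ---------------------------------------------------------

    def _clip_fast(self, p):
        lo, hi = self.c_fast_bounds
        c_lv = float(np.clip(p.c_lv, max(lo, p.c_myo), hi))
        c_rv = float(np.clip(p.c_rv, max(lo, p.c_myo), hi))
        return replace(p, c_lv=c_lv, c_rv=c_rv)

    def _step1_qrs(self, p):
        """Multiplicative secant on c_myo using QRSd ~ 1/sqrt(c_myo)."""
        m = self.targets.m_qrsd
        feats = self._features(p)
        for _ in range(4):
            if abs(feats.qrsd - m) <= self.tol_qrs:
                break
            c_new = p.c_myo * (feats.qrsd / m) ** 2
            c_new = float(np.clip(c_new, *self.c_myo_bounds))
            if abs(c_new - p.c_myo) / p.c_myo < 1e-3:
                break
            p = self._clip_fast(replace(p, c_myo=c_new))
            feats = self._features(p)
        return p, feats

    def _step2_axis(self, p, maxfev=14):
        """Nelder-Mead on (log c_lv, log c_rv) against the absolute EA error."""
        m = self.targets.m_ea
        if m is None:
            return p
        f0 = self._features(p)
        if abs(_wrap_angle(f0.ea - m)) <= 0.5 * self.tol_ea:
            return p  # axis already captured

        def objective(x):
            q = self._clip_fast(replace(p, c_lv=float(np.exp(x[0])),
                                        c_rv=float(np.exp(x[1]))))
            f = self._features(q)
            return abs(_wrap_angle(f.ea - m))

        x0 = np.log([p.c_lv, p.c_rv])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 0.05,
                                "fatol": 0.5 * self.tol_ea,
                                "initial_simplex": np.array(
                                    [x0, x0 + [0.5, 0.0], x0 + [0.0, 0.5]])})
        return self._clip_fast(replace(p, c_lv=float(np.exp(res.x[0])),
                                       c_rv=float(np.exp(res.x[1]))))

    def _step3_qt(self, p):
        """Direct tau_close update from the QT mismatch via the APD slope."""
        m = self.targets.m_qt
        if m is None:
            return p, None
        feats = self._features(p, full=True)
        if not np.isfinite(feats.qtd):
            raise ValueError("no T wave detected in the full-length forward "
                             "run; cannot fit the QT target")
        if abs(feats.qtd - m) < 5.0:
            return p, feats  # QT already captured
        slope = np.log(p.tau_out / (4.0 * p.tau_in))
        tau = p.tau_close + (m - feats.qtd) / slope
        p = replace(p, tau_close=float(np.clip(tau, 40.0, 500.0)))
        feats = self._features(p, full=True)  # verification run
        return p, feats

    def fit(self):
        p = self.params
        t = self.targets
        history = []
        converged = False
        feats_full = None
        for outer in range(1, self.max_outer + 1):
            p, feats = self._step1_qrs(p)
            p = self._step2_axis(p)
            p, feats_full = self._step3_qt(p)
            feats = feats_full or self._features(p)
            d_qrs = feats.qrsd - t.m_qrsd
            d_ea = _wrap_angle(feats.ea - t.m_ea) if t.m_ea is not None else 0.0
            history.append({"outer": outer, "qrsd": feats.qrsd,
                            "ea": feats.ea, "qtd": feats.qtd})
            if abs(d_qrs) <= self.tol_qrs and abs(d_ea) <= self.tol_ea:
                converged = True
                break
        residuals = {"qrsd_ms": feats.qrsd - t.m_qrsd}
        if t.m_ea is not None:
            residuals["ea_deg"] = _wrap_angle(feats.ea - t.m_ea)
        if t.m_qt is not None and feats_full is not None:
            residuals["qtd_ms"] = feats_full.qtd - t.m_qt
        return PersonalizationResult(
            p, residuals, n_iter=outer, converged=converged, history=history,
            n_forward=self.n_forward, title="EP personalization")


# ---------------------------------------------------------------------------
# Windkessel estimation

class WindkesselFit:
    """Fit (C, Rp, Rc, Pr) to a measured arterial pressure cycle.

    Needs at least one full cycle of pressure and flow samples on a common
    uniform time grid (seconds).  The fast closed-form periodic response of
    the linear Windkessel serves as the forward model.
    """

    def __init__(self, pressure_samples, flow_samples, wk0=None):
        pressure_samples = np.asarray(pressure_samples, dtype=float)
        flow_samples = np.asarray(flow_samples, dtype=float)
        if pressure_samples.ndim != 2 or flow_samples.ndim != 2:
            raise ValueError("samples must be (n, 2) arrays of (t, value)")
        t = pressure_samples[:, 0]
        if len(t) < 8:
            raise ValueError("need at least one well-sampled cycle")
        self.dt = float(t[1] - t[0])
        if not np.allclose(np.diff(t), self.dt, rtol=1e-3):
            raise ValueError("samples must be uniformly spaced in time")
        self.p_meas = pressure_samples[:, 1]
        self.Q = np.interp(t, flow_samples[:, 0], flow_samples[:, 1])
        if np.allclose(self.Q, 0.0):
            raise ValueError("degenerate flow waveform (identically zero)")
        self.wk0 = wk0 or self._initial_guess()

    def _initial_guess(self):
        pr0 = max(1.0, 0.7 * self.p_meas.min())
        q_mean = max(self.Q.mean(), 1e-9)
        r_tot = max((self.p_meas.mean() - pr0) / q_mean, 1e-8)
        return WindkesselParameters(C=1500.0, Rp=0.9 * r_tot, Rc=0.1 * r_tot,
                                    Pr=pr0)

    def predict(self, wk):
        return periodic_windkessel_response(wk, self.Q, self.dt)

    def fit(self, maxfev=600):
        p0 = self.wk0

        def unpack(x):
            return WindkesselParameters(C=float(np.exp(x[0])),
                                        Rp=float(np.exp(x[1])),
                                        Rc=float(np.exp(x[2])),
                                        Pr=float(np.exp(x[3])))

        def objective(x):
            try:
                wk = unpack(x)
            except ValueError:
                return 1e6
            resid = self.predict(wk) - self.p_meas
            return float(np.sqrt(np.mean(resid ** 2)))

        x0 = np.log([p0.C, p0.Rp, p0.Rc, p0.Pr])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-5,
                                "fatol": 1e-8})
        wk = unpack(res.x)
        rmse = objective(res.x)
        return PersonalizationResult(
            wk, {"pressure_rmse_mmHg": rmse}, n_iter=res.nit,
            converged=bool(res.success or rmse < 1.0),
            n_forward=res.nfev, title="Windkessel estimation")


# ---------------------------------------------------------------------------
# mechanics (E, sigma0) estimation

_MECH_KEYS = (("ef", "EF_percent"), ("sv", "SV_ml"), ("edv", "EDV_ml"),
              ("esv", "ESV_ml"), ("edp", "EDP_mmHg"), ("esp", "ESP_mmHg"))


class MechanicsFit:
    """Fit LV stiffness E and maximum active stress sigma0 to volumetric and
    pressure targets via repeated beat simulations."""

    def __init__(self, targets, mesh, fiber_field, ep_solution, hemo,
                 base_params=None, bounds=((100.0, 3000.0), (0.0, 900.0)),
                 weights=None, dt=2.5, n_cycles=1):
        present = [k for k, _ in _MECH_KEYS if getattr(targets, k) is not None]
        if not present:
            raise ValueError("mechanics personalization needs at least one "
                             "of EF/SV/EDV/ESV/EDP/ESP")
        self.targets = targets
        self.present = present
        self.mesh = mesh
        self.fibers = fiber_field
        self.ep_solution = ep_solution
        self.hemo = hemo
        self.base = base_params or MechParameters()
        self.bounds = bounds
        self.weights = weights or {}
        self.dt = dt
        self.n_cycles = n_cycles
        self.n_forward = 0
        self.history = []

    def forward(self, E, sigma0):
        mech = replace(self.base, young_modulus=float(E),
                       sigma0=float(sigma0))
        _, loops = simulate_beat(self.mesh, self.fibers, self.ep_solution,
                                 mech, self.hemo, dt=self.dt,
                                 n_cycles=self.n_cycles)
        self.n_forward += 1
        return loops["LV"].summary()

    def objective(self, E, sigma0):
        comp = self.forward(E, sigma0)
        total = 0.0
        for key, loop_key in _MECH_KEYS:
            meas = getattr(self.targets, key)
            if meas is None:
                continue
            w = self.weights.get(key, 1.0)
            total += w * ((comp[loop_key] - meas) / meas) ** 2
        self.history.append({"E": E, "sigma0": sigma0, "objective": total,
                             **comp})
        return total

    def fit(self, maxfev=26, x0=None):
        (e_lo, e_hi), (s_lo, s_hi) = self.bounds
        if x0 is None:
            x0 = (self.base.young_modulus, self.base.sigma0)

        def clip(x):
            return (float(np.clip(np.exp(x[0]), e_lo, e_hi)),
                    float(np.clip(x[1], s_lo, s_hi)))

        def fun(x):
            E, s = clip(x)
            return self.objective(E, s)

        z0 = np.array([np.log(np.clip(x0[0], e_lo, e_hi)),
                       np.clip(x0[1], s_lo, s_hi)])
        simplex = np.array([z0, z0 + [0.35, 0.0], z0 + [0.0, max(60.0, 0.3 * (z0[1] + 1.0))]])
        res = minimize(fun, z0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-3,
                                "fatol": 1e-5, "initial_simplex": simplex})
        E, s = clip(res.x)
        best = min(self.history, key=lambda h: h["objective"])
        E, s = best["E"], best["sigma0"]
        mech = replace(self.base, young_modulus=E, sigma0=s)
        residuals = {}
        for key, loop_key in _MECH_KEYS:
            meas = getattr(self.targets, key)
            if meas is not None:
                residuals[key] = best[loop_key] - meas
        return PersonalizationResult(
            mech, residuals, n_iter=res.nit,
            converged=bool(res.success or best["objective"] < 1e-3),
            history=self.history, n_forward=self.n_forward,
            title="mechanics (E, sigma) estimation")


# ---------------------------------------------------------------------------
# functional wrappers over the model objects

def personalize_ep(targets, mesh, fiber_field, torso=None, **kwargs):
    """Three-step EP personalization; returns (EPParameters, outer iters)."""
    model = EPPersonalization(targets, mesh, fiber_field, torso, **kwargs)
    result = model.fit()
    return result.params, result.n_iter


def personalize_windkessel(pressure_samples, flow_samples, wk0=None,
                           maxfev=600):
    """Windkessel least-squares estimation; returns WindkesselParameters."""
    result = WindkesselFit(pressure_samples, flow_samples, wk0).fit(maxfev)
    return result.params


def personalize_mechanics(targets, mesh, fiber_field, ep_solution, hemo,
                          bounds=((100.0, 3000.0), (0.0, 900.0)), **kwargs):
    """(E, sigma0) estimation against EF/SV/EDV/ESV/EDP/ESP targets."""
    model = MechanicsFit(targets, mesh, fiber_field, ep_solution, hemo,
                         bounds=bounds, **kwargs)
    return model.fit().params
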
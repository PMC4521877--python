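"""Monodomain Mitchell-Schaeffer electrophysiology.

The two-variable M-S cell model (normalized potential u, gate h) is coupled
to anisotropic diffusion on the tetrahedral anatomy.  Time stepping is
IMEX: the stiff diffusion operator is treated implicitly (P1 FEM, lumped
mass, one sparse factorization reused for all steps) and the reaction
explicitly, which requires dt <= tau_in/3 for the fast inward current.

A note on units: the per-tag conductivities c_myo/c_lv/c_rv are the
along-fiber diffusivities of the normalized monodomain equation, in mm^2/s
as conventionally printed; the solver converts to mm^2/ms internally.
Cross-fiber diffusivity is smaller by the anisotropy ratio (9 by default,
i.e. a conduction velocity three times faster along fibers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from . import _fem
from .geometry import LV_SEPTUM, RV_SEPTUM


@dataclass(frozen=True)
class EPParameters:
    """Mitchell-Schaeffer parameters plus tissue diffusivities.

    tau_close is the personalized repolarization constant (sets the action
    potential duration, APD ~ tau_close * ln(tau_out/(4 tau_in))); the other
    three time constants keep their standard values.
    """

    tau_in: float = 0.3        # ms
    tau_out: float = 6.0       # ms
    tau_open: float = 120.0    # ms
    tau_close: float = 150.0   # ms, personalized
    u_gate: float = 0.13
    c_myo: float = 413.0       # mm^2/s, cohort-mean myocardial diffusivity
    c_lv: float = 1600.0       # mm^2/s, LV sub-endocardial fast layer
    c_rv: float = 2200.0       # mm^2/s, RV sub-endocardial fast layer
    anisotropy_ratio: float = 9.0

    def __post_init__(self):
        if min(self.tau_in, self.tau_out, self.tau_open, self.tau_close) <= 0:
            raise ValueError("all M-S time constants must be positive")
        if not 0 < self.u_gate < 1:
            raise ValueError("u_gate must lie in (0, 1)")
        if min(self.c_myo, self.c_lv, self.c_rv) <= 0:
            raise ValueError("conductivities must be positive")
        if min(self.c_lv, self.c_rv) < self.c_myo:
            raise ValueError("fast-layer conductivities must be >= c_myo")
        if self.anisotropy_ratio < 1:
            raise ValueError("anisotropy_ratio must be >= 1")

    @property
    def apd_estimate(self):
        """Closed-form M-S action potential duration (ms)."""
        return self.tau_close * np.log(self.tau_out / (4.0 * self.tau_in))


@dataclass(frozen=True)
class Stimulus:
    node_set: np.ndarray
    onset: float = 0.0       # ms
    duration: float = 2.0    # ms
    amplitude: float = 0.8   # 1/ms added to du/dt

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")
        if len(np.atleast_1d(self.node_set)) == 0:
            raise ValueError("stimulus node set is empty")


@dataclass(frozen=True)
class StimulusProtocol:
    stimuli: tuple
    name: str = "custom"


def his_node_sets(mesh, upper_fraction=1.0 / 3.0):
    """Septal His-bundle initiation sites: nodes on the upper third of the
    LV and RV septal endocardial surfaces (configurable fraction)."""
    sets = []
    for label in (LV_SEPTUM, RV_SEPTUM):
        nodes = mesh.surface_nodes([label])
        if len(nodes) == 0:
            continue
        z = mesh.nodes[nodes, 2]
        z_cut = z.max() - upper_fraction * (z.max() - z.min())
        sets.append(nodes[z >= z_cut])
    if not sets:
        raise ValueError("mesh has no septal surfaces for His initiation")
    return sets


def sinus_protocol(mesh, onset=0.0, duration=2.0, amplitude=0.8):
    """Normal activation: simultaneous LV and RV septal His stimulation."""
    stimuli = tuple(Stimulus(ns, onset, duration, amplitude)
                    for ns in his_node_sets(mesh))
    return StimulusProtocol(stimuli, name="SINUS")


def _nearest_node(mesh, point):
    return int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(point), axis=1)))


def crt_biv_protocol(mesh, lv_lead, rv_lead, lv_rv_delay=20.0,
                     duration=2.0, amplitude=0.8):
    """Biventricular pacing: LV lead first, RV lead after the LV-RV delay
    (20 ms by default)."""
    lv = np.array([_nearest_node(mesh, lv_lead)])
    rv = np.array([_nearest_node(mesh, rv_lead)])
    return StimulusProtocol((Stimulus(lv, 0.0, duration, amplitude),
                             Stimulus(rv, lv_rv_delay, duration, amplitude)),
                            name="CRT_BIV")


def crt_rv_only_protocol(mesh, rv_lead, duration=2.0, amplitude=0.8):
    rv = np.array([_nearest_node(mesh, rv_lead)])
    return StimulusProtocol((Stimulus(rv, 0.0, duration, amplitude),),
                            name="CRT_RV_ONLY")


def crt_lv_triggered_protocol(mesh, lv_lead, trigger_delay=40.0,
                              duration=2.0, amplitude=0.8):
    """LV-triggered pacing (DDT-like): intrinsic septal activation plus an
    LV lead stimulus fired ``trigger_delay`` ms after sensed onset."""
    lv = np.array([_nearest_node(mesh, lv_lead)])
    stimuli = tuple(Stimulus(ns, 0.0, duration, amplitude)
                    for ns in his_node_sets(mesh))
    stimuli += (Stimulus(lv, trigger_delay, duration, amplitude),)
    return StimulusProtocol(stimuli, name="CRT_LV_TRIGGERED")


# ---------------------------------------------------------------------------
# cell model

def ms_cell_step(state, dt, params, stim=0.0):
    """One explicit step of the 0-D Mitchell-Schaeffer cell model.

    du/dt = h u^2 (1-u)/tau_in - u/tau_out + J_stim
    dh/dt = (1-h)/tau_open  if u < u_gate  else  -h/tau_close
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u, h = state
    u = np.asarray(u, dtype=float)
    h = np.asarray(h, dtype=float)
    du = h * u * u * (1.0 - u) / params.tau_in - u / params.tau_out + stim
    dh = np.where(u < params.u_gate,
                  (1.0 - h) / params.tau_open,
                  -h / params.tau_close)
    return u + dt * du, h + dt * dh


# ---------------------------------------------------------------------------
# tissue model

def assemble_diffusivity(mesh, fiber_field, params):
    """Per-element diffusion tensors D = c (f f^T + (I - f f^T)/r), mm^2/s.

    c is the along-fiber diffusivity selected by element tag; r the
    anisotropy ratio (eigenvalues are (c, c/r, c/r)).
    """
    f = np.asarray(fiber_field.fibers, dtype=float)
    if len(f) != mesh.n_elements:
        raise ValueError("fiber field does not match mesh element count")
    norms = np.linalg.norm(f, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError(f"missing fiber on element {int(np.argmin(norms))}")
    c = np.choose(mesh.element_tags,
                  [params.c_myo, params.c_lv, params.c_rv]).astype(float)
    r = params.anisotropy_ratio
    ff = np.einsum("ei,ej->eij", f, f)
    eye = np.eye(3)[None, :, :]
    return c[:, None, None] * (ff + (eye - ff) / r)


@dataclass
class EPSolution:
    """Space-time monodomain solution with derived timing maps."""

    times: np.ndarray            # ms, recorded sample times
    u: np.ndarray                # (nt, n_nodes) normalized potential
    activation: np.ndarray       # ms per node (nan if never activated)
    repolarization: np.ndarray   # ms per node (nan if never repolarized)
    h: np.ndarray | None = None
    protocol_name: str = ""

    def element_activation(self, mesh):
        return np.nanmean(self.activation[mesh.tets], axis=1)

    def element_repolarization(self, mesh):
        return np.nanmean(self.repolarization[mesh.tets], axis=1)

    @property
    def total_activation_time(self):
        a = self.activation[np.isfinite(self.activation)]
        return float(a.max() - a.min()) if len(a) else np.nan


def simulate_ep(mesh, fiber_field, params, protocol, duration,
                dt=0.1, record_stride=1.0, store_h=False,
                activation_threshold=0.5):
    """Solve the monodomain reaction-diffusion problem.

    No-flux boundaries; activation time is the first upward crossing of the
    threshold, repolarization the last downward crossing (both linearly
    interpolated in time).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    max_dt = params.tau_in / 3.0
    if dt > max_dt + 1e-12:
        raise ValueError(
            f"dt = {dt} ms unstable for the explicit reaction; "
            f"maximal stable dt = {max_dt:.4g} ms (tau_in/3)")
    n = mesh.n_nodes
    D = assemble_diffusivity(mesh, fiber_field, params) / 1000.0  # mm^2/ms
    K = _fem.assemble_stiffness(mesh.nodes, mesh.tets, D)
    M = _fem.lumped_mass(mesh.nodes, mesh.tets)
    A = diags(M) + dt * K
    lu = splu(A.tocsc())

    u = np.zeros(n)
    h = np.ones(n)
    thr = activation_threshold
    activation = np.full(n, np.nan)
    repolarization = np.full(n, np.nan)
    n_steps = int(round(duration / dt))
    stride_steps = max(1, int(round(record_stride / dt)))
    rec_t, rec_u, rec_h = [], [], []

    stim_sets = [(np.atleast_1d(s.node_set), s.onset, s.onset + s.duration,
                  s.amplitude) for s in protocol.stimuli]

    t = 0.0
    for step in range(n_steps + 1):
        if step % stride_steps == 0:
            rec_t.append(t)
            rec_u.append(u.copy())
            if store_h:
                rec_h.append(h.copy())
        if step == n_steps:
            break
        # explicit reaction + stimulus
        du = h * u * u * (1.0 - u) / params.tau_in - u / params.tau_out
        for nodes, t0, t1, amp in stim_sets:
            if t0 <= t < t1:
                # saturating stimulus: pushes toward u = 1 without overshoot
                du[nodes] += amp * np.maximum(1.0 - u[nodes], 0.0)
        h = h + dt * np.where(u < params.u_gate,
                              (1.0 - h) / params.tau_open,
                              -h / params.tau_close)
        u_star = u + dt * du
        u_new = lu.solve(M * u_star)
        # P1 diffusion on coarse unstructured meshes is not monotone (obtuse
        # and sliver elements); clamp at the resting state so the maximum
        # principle's lower bound holds exactly
        np.maximum(u_new, 0.0, out=u_new)
        # threshold crossings, linearly interpolated
        up = (u < thr) & (u_new >= thr) & np.isnan(activation)
        if np.any(up):
            frac = (thr - u[up]) / (u_new[up] - u[up])
            activation[up] = t + frac * dt
        down = (u >= thr) & (u_new < thr)
        if np.any(down):
            frac = (thr - u[down]) / (u_new[down] - u[down])
            repolarization[down] = t + frac * dt
        u = u_new
        t += dt

    return EPSolution(times=np.array(rec_t), u=np.array(rec_u),
                      activation=activation, repolarization=repolarization,
                      h=np.array(rec_h) if store_h else None,
                      protocol_name=protocol.name)


def conduction_velocity(mesh, solution, direction, band=None):
    """CV (mm/ms) from a least-squares fit of activation time vs distance
    along ``direction``; optionally restricted to nodes inside ``band``
    (a boolean mask)."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    s = mesh.nodes @ d
    act = solution.activation
    mask = np.isfinite(act)
    if band is not None:
        mask &= band
    if mask.sum() < 3:
        raise ValueError("too few activated nodes for a CV fit")
    # discard the wave initiation and the far boundary (10-90% window)
    lo, hi = np.percentile(s[mask], [15, 85])
    mask &= (s >= lo) & (s <= hi)
    slope = np.polyfit(s[mask], act[mask], 1)[0]
    if slope <= 0:
        raise ValueError("activation does not propagate along this direction")
    return 1.0 / slope
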
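"""Cardiac biomechanics: co-rotational passive elasticity + active fiber stress.

The tissue follows a two-element Hill arrangement: an isotropic linear
elastic passive element (Young's modulus E, Poisson ratio 0.48 for
quasi-incompressibility) evaluated in a per-element rotated frame (polar
decomposition of the deformation gradient, so rigid rotations produce no
strain), in parallel with an active stress along the local fiber.  The
active stress rises exponentially after the element's activation time at
rate k_atp toward the maximum active stress sigma0, and decays at rate k_rs
after repolarization.

The beat simulation couples this to the lumped hemodynamics: a pressure
load on the endocardial faces whose value is dictated by the cardiac phase
(atrial pressure during filling, the isovolumetric prediction-correction
during the isovolumetric phases, and the Windkessel coupling during
ejection).  Time integration is a damped backward-Euler velocity update;
within a step the tangent factorization is reused for all pressure trials,
so each trial costs one triangular solve.

Units: mm, ms, kPa, mN, mg (1 kPa * mm^2 = 1 mN; density 1.06 mg/mm^3).
Pressures cross the interface in mmHg (1 mmHg = 0.133322 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import _fem, geometry
from .hemodynamics import HemoParameters, Phase, PVLoop, phase_machine, wk3_step

MMHG_TO_KPA = 0.1333224


@dataclass(frozen=True)
class MechParameters:
    """Passive + active tissue parameters (cohort-mean defaults)."""

    young_modulus: float = 590.0    # kPa
    poisson: float = 0.48
    sigma0: float = 295.0           # kPa, maximum active fiber stress
    k_atp: float = 0.02             # 1/ms, contraction rise rate
    k_rs: float = 0.02              # 1/ms, release decay rate
    density: float = 1.06           # mg/mm^3
    valve_spring_stiffness: float = 30.0        # mN/mm per base-ring node
    pericardium_penalty_stiffness: float = 30.0  # mN/mm per epicardial node
    rayleigh_alpha: float = 0.1     # 1/ms, mass-proportional damping
    rayleigh_beta: float = 0.02     # ms, stiffness-proportional damping

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 < self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.sigma0 < 0 or self.k_atp <= 0 or self.k_rs <= 0:
            raise ValueError("active-stress parameters out of range")


@dataclass
class MechState:
    """Snapshot of the mechanical state."""

    time: float                    # ms
    displacements: np.ndarray      # (n, 3) mm
    velocities: np.ndarray         # (n, 3) mm/ms
    active_stress: np.ndarray      # (m,) kPa


def active_stress(t, t_act, t_rep, params):
    """Active fiber stress (kPa) of the exponential rise/decay law.

    Zero before activation; sigma0 (1 - exp(-k_atp (t - t_act))) while the
    element is depolarized; value-continuous exponential decay with rate
    k_rs after repolarization.  Total function of its inputs (arrays OK).
    """
    t = np.asarray(t, dtype=float)
    t_act = np.asarray(t_act, dtype=float)
    t_rep = np.asarray(t_rep, dtype=float)
    s0, ka, kr = params.sigma0, params.k_atp, params.k_rs
    active = np.isfinite(t_act)
    # never-activated elements (infinite activation time) stay passive; an
    # infinite repolarization time means "still contracting".  Substitute
    # finite sentinels before any arithmetic so no inf - inf is formed.
    ta = np.where(active, t_act, 0.0)
    tr = np.where(np.isfinite(t_rep), t_rep, 1e12)
    rise = s0 * -np.expm1(-ka * np.maximum(t - ta, 0.0))
    peak = s0 * -np.expm1(-ka * np.maximum(tr - ta, 0.0))
    decay = peak * np.exp(-kr * np.maximum(t - tr, 0.0))
    out = np.where(t < ta, 0.0, np.where(t <= tr, rise, decay))
    return np.where(active, out, 0.0)


def _isotropic_C(E, nu):
    """6x6 isotropic elasticity matrix (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


def _element_stiffness(vols, grads, E, nu):
    """(m, 12, 12) linear tetrahedral stiffness matrices."""
    m = len(vols)
    B = np.zeros((m, 6, 12))
    for k in range(4):
        g = grads[:, k, :]
        c = 3 * k
        B[:, 0, c] = g[:, 0]
        B[:, 1, c + 1] = g[:, 1]
        B[:, 2, c + 2] = g[:, 2]
        B[:, 3, c] = g[:, 1]; B[:, 3, c + 1] = g[:, 0]
        B[:, 4, c + 1] = g[:, 2]; B[:, 4, c + 2] = g[:, 1]
        B[:, 5, c] = g[:, 2]; B[:, 5, c + 2] = g[:, 0]
    C = _isotropic_C(E, nu)
    return np.einsum("eai,ab,ebj,e->eij", B, C, B, vols)


def _polar_rotations(F):
    """Batched rotation factors of deformation gradients (det(R) = +1)."""
    U, _, Vt = np.linalg.svd(F)
    R = U @ Vt
    det = np.linalg.det(R)
    flip = det < 0
    if np.any(flip):
        U = U.copy()
        U[flip, :, 2] *= -1.0
        R[flip] = U[flip] @ Vt[flip]
    return R


class CorotationalModel:
    """Assembled co-rotational elasticity on a tetrahedral mesh."""

    def __init__(self, mesh, params):
        self.mesh = mesh
        self.params = params
        self.vols, self.grads = _fem.shape_gradients(mesh.nodes, mesh.tets)
        self.Ke = _element_stiffness(self.vols, self.grads,
                                     params.young_modulus, params.poisson)
        a = mesh.nodes[mesh.tets[:, 0]]
        self.Dm_inv = np.linalg.inv(
            np.stack([mesh.nodes[mesh.tets[:, k]] - a for k in (1, 2, 3)],
                     axis=2))
        self.x_ref = mesh.nodes[mesh.tets].reshape(-1, 12)
        t = mesh.tets
        idx = (3 * t[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        self._rows = np.repeat(idx, 12, axis=1).ravel()
        self._cols = np.tile(idx, (1, 12)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def rotations(self, coords, strict=True):
        """Per-element rotation factors.

        With ``strict`` a non-positive det(F) raises (the contract of the
        standalone passive-force operator); without it the sign-corrected
        SVD yields a proper rotation even for momentarily inverted sliver
        elements, whose co-rotational force then pushes them back
        (invertible-FEM treatment used inside the beat loop).
        """
        a = coords[self.mesh.tets[:, 0]]
        Ds = np.stack([coords[self.mesh.tets[:, k]] - a for k in (1, 2, 3)],
                      axis=2)
        F = Ds @ self.Dm_inv
        if strict:
            det = np.linalg.det(F)
            if np.any(det <= 0):
                bad = int(np.argmin(det))
                raise RuntimeError(f"inverted element {bad} (det F <= 0)")
        return _polar_rotations(F)

    def internal_force(self, coords, R=None):
        """Co-rotational elastic nodal forces (n, 3), mN."""
        if R is None:
            R = self.rotations(coords)
        x = coords[self.mesh.tets].reshape(-1, 4, 3)
        # pull back to the unrotated frame: q = R^T x - x_ref
        q = np.einsum("eba,ekb->eka", R, x).reshape(-1, 12) - self.x_ref
        fe = np.einsum("eij,ej->ei", self.Ke, q).reshape(-1, 4, 3)
        fe = np.einsum("eab,ekb->eka", R, fe)
        f = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(f, self.mesh.tets.ravel(), fe.reshape(-1, 3))
        return f

    def elastic_energy(self, coords):
        R = self.rotations(coords)
        x = coords[self.mesh.tets].reshape(-1, 4, 3)
        q = np.einsum("eba,ekb->eka", R, x).reshape(-1, 12) - self.x_ref
        return 0.5 * float(np.einsum("ei,eij,ej->", q, self.Ke, q))

    def tangent(self, R):
        """Assemble the rotated stiffness sum_e (I4 x R) Ke (I4 x R)^T."""
        K5 = self.Ke.reshape(-1, 4, 3, 4, 3)
        Krot = np.einsum("eac,eicjd,ebd->eiajb", R, K5, R).reshape(-1, 144)
        K = sp.coo_matrix((Krot.ravel(), (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof))
        return K.tocsr()


def passive_force(mesh, displacements, params):
    """Assembled co-rotational passive nodal force vector for a displacement
    field (zero for any rigid motion)."""
    model = CorotationalModel(mesh, params)
    return model.internal_force(mesh.nodes + np.asarray(displacements))


# ---------------------------------------------------------------------------
# cavity volume on deformed coordinates

def _chamber_faces(mesh, chamber):
    labels = {"LV": [geometry.LV_ENDO, geometry.LV_SEPTUM],
              "RV": [geometry.RV_ENDO, geometry.RV_SEPTUM]}[chamber]
    sel = np.isin(mesh.surface_labels, labels)
    if not np.any(sel):
        raise ValueError(f"mesh has no {chamber} endocardial surface")
    faces = mesh.boundary_faces[sel][:, ::-1]  # orient out of the cavity
    rim = geometry._open_rim_edges(faces)
    return faces, rim


def _cavity_volume_ml(coords, faces, rim):
    if len(rim):
        centroid = coords[np.unique(rim)].mean(axis=0)
        pts = np.vstack([coords, centroid])
        cap = np.column_stack([rim[:, 1], rim[:, 0],
                               np.full(len(rim), len(pts) - 1)])
        all_faces = np.vstack([faces, cap])
    else:
        pts, all_faces = coords, faces
    return abs(geometry.surface_volume(pts, all_faces)) / 1000.0


def _pressure_load(coords, faces, n_nodes):
    """Nodal force per unit cavity pressure (1 kPa), follower load on the
    current endocardial geometry."""
    a, b, c = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    # faces are oriented out of the cavity: area normal points into the wall
    N = 0.5 * np.cross(b - a, c - a)
    f = np.zeros((n_nodes, 3))
    for k in range(3):
        np.add.at(f, faces[:, k], N / 3.0)
    return f


# ---------------------------------------------------------------------------
# coupled beat

class BeatSimulator:
    """Electromechanics of one or more beats, coupled to the lumped
    circulation.  The input anatomy is taken as the end-diastolic state
    (no unloading step); the pericardial bag is the end-diastolic
    epicardium."""

    def __init__(self, mesh, fiber_field, ep_solution, mech, hemo,
                 dt=2.0, chambers=("LV",), hemo_rv=None, refactor_every=5):
        if dt <= 0:
            raise ValueError("dt must be positive")
        # the tangent factorization is refreshed every `refactor_every`
        # steps (quasi-Newton): the co-rotational stiffness drifts slowly,
        # while the force residual is evaluated exactly at every step
        self.refactor_every = max(1, int(refactor_every))
        self._lu = None
        self._lu_age = 0
        self.mesh = mesh
        self.mech = mech
        self.dt = dt
        self.model = CorotationalModel(mesh, mech)
        self.fibers = fiber_field.fibers
        self.n = mesh.n_nodes
        vols = self.model.vols
        mass = np.zeros(self.n)
        np.add.at(mass, mesh.tets.ravel(),
                  np.repeat(mech.density * vols / 4.0, 4))
        self.M = np.repeat(mass, 3)

        self.chambers = {}
        hemo_map = {"LV": hemo, "RV": hemo_rv or hemo}
        for name in chambers:
            faces, rim = _chamber_faces(mesh, name)
            self.chambers[name] = {"faces": faces, "rim": rim,
                                   "hemo": hemo_map[name]}
        self.cycle_length = hemo.cycle_length

        # element activation/repolarization times
        if ep_solution is not None:
            self.t_act = ep_solution.element_activation(mesh)
            t_rep = ep_solution.element_repolarization(mesh)
            # elements that never repolarized in the EP run: fall back to
            # activation + the cell model's APD estimate is unavailable here,
            # so keep them active until the recording ended
            fallback = ep_solution.times[-1]
            self.t_rep = np.where(np.isfinite(t_rep), t_rep, fallback)
        else:
            self.t_act = np.full(mesh.n_elements, np.inf)
            self.t_rep = np.full(mesh.n_elements, np.inf)

        # boundary attachments
        valve_nodes = np.concatenate(
            [v for v in mesh.valve_annulus_node_sets.values()]) \
            if mesh.valve_annulus_node_sets else np.array([], int)
        if len(valve_nodes) == 0:
            valve_nodes = mesh.surface_nodes([geometry.BASE])
        self.valve_nodes = np.unique(valve_nodes)
        epi_faces = mesh.boundary_faces[mesh.surface_labels == geometry.EPI]
        self.epi_nodes = np.unique(epi_faces)
        normals = np.zeros((self.n, 3))
        fn = np.cross(mesh.nodes[epi_faces[:, 1]] - mesh.nodes[epi_faces[:, 0]],
                      mesh.nodes[epi_faces[:, 2]] - mesh.nodes[epi_faces[:, 0]])
        for k in range(3):
            np.add.at(normals, epi_faces[:, k], fn)
        nn = np.linalg.norm(normals[self.epi_nodes], axis=1, keepdims=True)
        self.epi_normals = normals[self.epi_nodes] / np.maximum(nn, 1e-30)

    # -- force terms -------------------------------------------------------

    def _active_internal(self, t, R):
        sa = active_stress(t, self.t_act, self.t_rep, self.mech)
        if not np.any(sa > 0):
            return np.zeros((self.n, 3)), sa
        V = self.model.vols
        g = self.model.grads                       # (m,4,3)
        fdotg = np.einsum("ea,eka->ek", self.fibers, g)
        fe = (V * sa)[:, None, None] * fdotg[:, :, None] \
            * np.einsum("eab,eb->ea", R, self.fibers)[:, None, :]
        f = np.zeros((self.n, 3))
        np.add.at(f, self.mesh.tets.ravel(), fe.reshape(-1, 3))
        return f, sa

    def _constraint_force(self, coords):
        """Valve-annulus springs + one-sided pericardial penalty."""
        mech = self.mech
        f = np.zeros((self.n, 3))
        dv = coords[self.valve_nodes] - self.mesh.nodes[self.valve_nodes]
        f[self.valve_nodes] -= mech.valve_spring_stiffness * dv
        d = np.einsum("ij,ij->i",
                      coords[self.epi_nodes] - self.mesh.nodes[self.epi_nodes],
                      self.epi_normals)
        out = d > 0
        f[self.epi_nodes[out]] -= (mech.pericardium_penalty_stiffness
                                   * d[out, None] * self.epi_normals[out])
        return f

    def _constraint_stiffness_diag(self, coords):
        k = np.zeros(self.n)
        k[self.valve_nodes] += self.mech.valve_spring_stiffness
        d = np.einsum("ij,ij->i",
                      coords[self.epi_nodes] - self.mesh.nodes[self.epi_nodes],
                      self.epi_normals)
        k[self.epi_nodes[d > 0]] += self.mech.pericardium_penalty_stiffness
        return np.repeat(k, 3)

    def volume(self, coords, chamber="LV"):
        ch = self.chambers[chamber]
        return _cavity_volume_ml(coords, ch["faces"], ch["rim"])

    # -- time stepping -----------------------------------------------------

    def _prepare_step(self, t, coords, vel):
        """Factorize the step operator; return a solver for trial pressures."""
        mech, dt = self.mech, self.dt
        R = self.model.rotations(coords, strict=False)
        if self._lu is None or self._lu_age >= self.refactor_every:
            K = self.model.tangent(R)
            K = K + sp.diags(self._constraint_stiffness_diag(coords))
            A = (sp.diags(self.M * (1.0 + dt * mech.rayleigh_alpha))
                 + (dt * mech.rayleigh_beta + dt * dt) * K)
            self._lu = splu(A.tocsc())
            self._lu_age = 0
        self._lu_age += 1
        lu = self._lu
        f_act, sa = self._active_internal(t, R)
        f0 = (-self.model.internal_force(coords, R) - f_act
              + self._constraint_force(coords))
        loads = {name: _pressure_load(coords, ch["faces"], self.n)
                 for name, ch in self.chambers.items()}

        def trial(pressures_mmhg):
            f = f0.copy()
            for name, p in pressures_mmhg.items():
                f += (p * MMHG_TO_KPA) * loads[name]
            rhs = self.M * vel.ravel() + dt * f.ravel()
            v_new = lu.solve(rhs).reshape(-1, 3)
            return coords + dt * v_new, v_new

        return trial, sa

    def volume_response(self, t, coords, vel, chamber="LV"):
        """Quasi-static volume-of-pressure callable for the current step
        (used by the isovolumetric prediction-correction)."""
        trial, _ = self._prepare_step(t, coords, vel)

        def vol(p):
            x, _ = trial({chamber: p})
            return self.volume(x, chamber)

        return vol

    def _solve_iso(self, trial, chamber, p_guess, v_target):
        """Secant iteration for the isovolumetric pressure of this step."""
        p0 = p_guess
        x, v = trial({chamber: p0})
        v0 = self.volume(x, chamber)
        if abs(v0 - v_target) / v_target < 1e-4:
            return p0, x, v, v0
        p1 = p0 + max(1.0, 0.02 * abs(p0))
        for _ in range(8):
            x1, vel1 = trial({chamber: p1})
            v1 = self.volume(x1, chamber)
            if abs(v1 - v_target) / v_target < 1e-4 or v1 == v0:
                return p1, x1, vel1, v1
            p0, v0, p1 = p1, v1, p1 + (v_target - v1) * (p1 - p0) / (v1 - v0)
        x1, vel1 = trial({chamber: p1})
        return p1, x1, vel1, self.volume(x1, chamber)

    def run(self, n_cycles=1, record_stride=10, p_art0=None):
        """Simulate ``n_cycles`` beats; returns (states, loops dict)."""
        mesh = self.mesh
        dt = self.dt
        coords = mesh.nodes.copy()
        vel = np.zeros_like(coords)
        T = self.cycle_length * n_cycles
        n_steps = int(round(T / dt))

        st = {}
        for name, ch in self.chambers.items():
            wk = ch["hemo"].wk
            st[name] = {
                "phase": Phase.FILLING,
                "p": ch["hemo"].atrium.pressure(0.0, self.cycle_length),
                "p_distal": wk.Pr * 1.4 if p_art0 is None else p_art0,
                "v": self.volume(coords, name),
                "v_target": None,
            }
        rec = {name: {"t": [], "p": [], "v": [], "phase": []}
               for name in self.chambers}
        states = []

        soft_disp = 2.0   # mm/step: rebuild the tangent beyond this motion
        hard_disp = 25.0  # mm/step: divergence even with a fresh tangent

        for step in range(n_steps):
            t = step * dt
            for attempt in (0, 1):
                coords_new, vel_new, pressures, sa = self._advance(
                    t, coords, vel, st)
                fresh = self._lu_age == 1  # factorized within this step
                disp = np.abs(vel_new).max() * dt
                if np.isfinite(disp) and (disp < soft_disp
                                          or (fresh and disp < hard_disp)):
                    break
                # stale tangent drifted too far: rebuild it at this state
                self._lu = None
                if attempt == 1:
                    raise RuntimeError(
                        f"implicit step diverged at t = {t:.1f} ms even with "
                        f"a fresh tangent (max step motion {disp:.2g} mm); "
                        f"reduce dt or increase damping")
            coords, vel = coords_new, vel_new

            # bookkeeping, Windkessel state and phase transitions
            self._update_states(t, coords, pressures, sa, st, rec)

            if step % record_stride == 0:
                states.append(MechState(time=t + dt,
                                        displacements=coords - mesh.nodes,
                                        velocities=vel.copy(),
                                        active_stress=sa))

        loops = {name: PVLoop(times=np.array(r["t"]),
                              pressure=np.array(r["p"]),
                              volume=np.array(r["v"]),
                              phase=np.array(r["phase"], dtype=object))
                 for name, r in rec.items()}
        return states, loops

    def _advance(self, t, coords, vel, st):
        """Resolve chamber pressures for the current phases and take one
        implicit step; returns the candidate state."""
        trial, sa = self._prepare_step(t, coords, vel)
        dt = self.dt
        pressures = {}
        for name, s in st.items():
            hemo = self.chambers[name]["hemo"]
            wk = hemo.wk
            p_at = hemo.atrium.pressure(t, self.cycle_length)
            if s["phase"] == Phase.FILLING:
                pressures[name] = p_at
            elif s["phase"] in (Phase.ISO_CONTRACTION, Phase.ISO_RELAXATION):
                p, _, _, _ = self._solve_iso(trial, name, s["p"],
                                             s["v_target"])
                pressures[name] = p
            else:  # EJECTION: p = p_distal + Rc * Q(p)
                p = max(s["p"], s["p_distal"])
                for _ in range(4):
                    x_t, _ = trial({**pressures, name: p})
                    q = (s["v"] - self.volume(x_t, name)) * 1000.0 \
                        / (dt / 1000.0)  # ml/ms -> mm^3/s
                    p_new = s["p_distal"] + wk.Rc * q
                    if abs(p_new - p) < 0.05:
                        p = p_new
                        break
                    p = 0.5 * (p + p_new)
                pressures[name] = p
        coords_new, vel_new = trial(pressures)
        return coords_new, vel_new, pressures, sa

    def _update_states(self, t, coords, pressures, sa, st, rec):
        """Windkessel update, phase transitions and recording after a step."""
        dt = self.dt
        for name, s in st.items():
            hemo = self.chambers[name]["hemo"]
            wk = hemo.wk
            p_at = hemo.atrium.pressure(t, self.cycle_length)
            v_new = self.volume(coords, name)
            dvdt = (v_new - s["v"]) / dt
            q_out = max(0.0, -dvdt) * 1000.0  # mm^3/s, ejected flow
            q_wk = q_out if s["phase"] == Phase.EJECTION else 0.0
            _, s["p_distal"] = wk3_step(None, s["p_distal"], q_wk,
                                        dt / 1000.0, wk)
            p_v = pressures[name]
            # during filling the wall holds atrial pressure by construction;
            # the onset of contraction shows up as a shrinking cavity, which
            # means the ventricular pressure has exceeded the atrial one
            if s["phase"] == Phase.FILLING and dvdt < -1e-6 \
                    and np.any(sa > 0.01 * self.mech.sigma0):
                p_probe = p_at + 1.0
            else:
                p_probe = p_v
            new_phase = phase_machine(p_probe, p_at, s["p_distal"],
                                      dvdt if s["phase"] == Phase.EJECTION
                                      else -q_out, s["phase"])
            if new_phase != s["phase"]:
                if new_phase in (Phase.ISO_CONTRACTION, Phase.ISO_RELAXATION):
                    s["v_target"] = (s["v"] if new_phase == Phase.ISO_CONTRACTION
                                     else v_new)
                s["phase"] = new_phase
            s["p"] = p_v
            s["v"] = v_new
            rec[name]["t"].append(t + dt)
            rec[name]["p"].append(p_v)
            rec[name]["v"].append(v_new)
            rec[name]["phase"].append(s["phase"])


def simulate_beat(mesh, fiber_field, ep_solution, mech, hemo,
                  dt=2.0, n_cycles=1, chambers=("LV",), hemo_rv=None,
                  record_stride=10):
    """Convenience wrapper: build a :class:`BeatSimulator` and run it.

    Returns ``(states, loops)`` where ``loops`` maps chamber name to its
    :class:`~cardiotwin.hemodynamics.PVLoop`.
    """
    sim = BeatSimulator(mesh, fiber_field, ep_solution, mech, hemo,
                        dt=dt, chambers=chambers, hemo_rv=hemo_rv)
    return sim.run(n_cycles=n_cycles, record_stride=record_stride)
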
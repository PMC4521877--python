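"""Rule-based myocardial fiber architecture.

The fiber elevation angle varies linearly with the transmural Laplace
coordinate: in the LV from -60 deg at the epicardium through 0 deg at
mid-wall to +60 deg at the endocardium, in the RV from -80 deg to +80 deg.
The fiber is the local circumferential direction rotated by the elevation
angle within the wall tangent plane, so it stays orthogonal to the
transmural direction by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _fem
from .geometry import LV, RV

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FiberRule:
    """Endpoint elevation angles (degrees) of the linear transmural law."""

    lv_endo_angle: float = 60.0
    lv_epi_angle: float = -60.0
    rv_endo_angle: float = 80.0
    rv_epi_angle: float = -80.0

    def __post_init__(self):
        for a in (self.lv_endo_angle, self.lv_epi_angle,
                  self.rv_endo_angle, self.rv_epi_angle):
            if not -90.0 < a < 90.0:
                raise ValueError("elevation angles must lie in (-90, 90) deg")

    def angle(self, depth, ventricle):
        """Elevation angle (deg) at transmural depth (0 = epi, 1 = endo)."""
        depth = np.asarray(depth, dtype=float)
        lv = self.lv_epi_angle + depth * (self.lv_endo_angle - self.lv_epi_angle)
        rv = self.rv_epi_angle + depth * (self.rv_endo_angle - self.rv_epi_angle)
        return np.where(np.asarray(ventricle) == RV, rv, lv)


@dataclass
class FiberField:
    """Per-element unit fiber directions and their elevation angles."""

    fibers: np.ndarray          # (m, 3) unit vectors
    angles: np.ndarray          # (m,) degrees
    n_apex_fallback: int = 0    # elements where the tangent frame degenerated


def generate_fibers(mesh, rule=None):
    """Generate the per-element fiber field on a labeled mesh.

    Requires ``mesh.nodal_depth`` (transmural Laplace coordinate) and
    ``mesh.long_axis``; deterministic given mesh + rule.
    """
    rule = rule or FiberRule()
    _, grads = _fem.shape_gradients(mesh.nodes, mesh.tets)
    # transmural direction: gradient of the nodal depth field
    g = np.einsum("eki,ek->ei", grads, mesh.nodal_depth[mesh.tets])
    gn = np.linalg.norm(g, axis=1)
    ok = gn > 1e-8
    t_hat = np.zeros_like(g)
    t_hat[ok] = g[ok] / gn[ok, None]
    # fall back to a radial direction orthogonal to the long axis where the
    # depth gradient vanishes (can happen in the apex cap)
    la = mesh.long_axis / np.linalg.norm(mesh.long_axis)
    cents = mesh.element_centroids()
    radial = cents - np.outer(cents @ la, la)
    rn = np.linalg.norm(radial, axis=1)
    fallback = ~ok | (np.linalg.norm(np.cross(la, t_hat), axis=1) < 1e-6)
    use_radial = fallback & (rn > 1e-8)
    t_hat[use_radial] = radial[use_radial] / rn[use_radial, None]
    still_bad = fallback & ~use_radial
    if np.any(still_bad):
        t_hat[still_bad] = np.array([1.0, 0.0, 0.0])
    if np.any(fallback):
        log.info("fiber frame fallback at %d apex element(s)",
                 int(fallback.sum()))

    circ = np.cross(la, t_hat)
    circ /= np.maximum(np.linalg.norm(circ, axis=1, keepdims=True), 1e-30)
    longi = np.cross(t_hat, circ)

    angles = rule.angle(mesh.transmural_depth, mesh.element_ventricle)
    rad = np.deg2rad(angles)
    fibers = np.cos(rad)[:, None] * circ + np.sin(rad)[:, None] * longi
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    return FiberField(fibers=fibers, angles=angles,
                      n_apex_fallback=int(fallback.sum()))


def uniform_fibers(mesh, direction):
    """Constant fiber field (for slabs and test geometries)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    m = mesh.n_elements
    return FiberField(fibers=np.tile(d, (m, 1)), angles=np.zeros(m))
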
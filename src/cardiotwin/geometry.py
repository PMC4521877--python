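"""Synthetic bi-ventricular anatomy: generation, labeling, tagging, measuring.

The anatomy is parametric: the left ventricle is a truncated thick-walled
ellipsoid, the right ventricle a crescent formed by an offset ellipsoidal
cavity wrapped around the LV epicardium with a thin free wall (3 mm by
default).  The construction samples the analytic surfaces, tetrahedralizes
the combined point cloud with Delaunay, and keeps elements whose centroid
lies inside the implicit myocardium, so boundary facets lie on the analytic
surfaces.

Conventions: lengths in mm, the long axis is +z with the apex at -z and the
truncation (base) plane orthogonal to z.  Volumes are reported in ml at the
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy.spatial import Delaunay, cKDTree

from . import _fem
from ._vtk import read_vtk, write_vtk

# surface labels
LV_ENDO, RV_ENDO, LV_SEPTUM, RV_SEPTUM, EPI, BASE = 0, 1, 2, 3, 4, 5
SURFACE_NAMES = {LV_ENDO: "LV_ENDO", RV_ENDO: "RV_ENDO", LV_SEPTUM: "LV_SEPTUM",
                 RV_SEPTUM: "RV_SEPTUM", EPI: "EPI", BASE: "BASE"}
# element tags
MYO, LV_FAST_LAYER, RV_FAST_LAYER = 0, 1, 2
# ventricle ownership for the fiber rule
LV, RV = 0, 1


@dataclass(frozen=True)
class AnatomyConfig:
    """Parameters of the synthetic bi-ventricular anatomy (all lengths mm)."""

    lv_radii: tuple = (20.0, 20.0, 40.0)   # LV endocardial semi-axes
    lv_wall_thickness: float = 9.0
    rv_radii: tuple = (31.0, 26.0, 36.0)   # RV cavity (endocardial) semi-axes
    rv_center_offset: tuple = (-12.0, 7.0, 2.0)  # RV right-anterior
    rv_wall_thickness: float = 3.0         # standard thin RV free wall
    base_truncation: float = 0.75          # fraction of upper epi half removed
    fast_layer_thickness: float = 1.0      # sub-endocardial Purkinje-like layer
    edge_length: float = 3.0               # target element edge length
    include_rv: bool = True

    def __post_init__(self):
        lengths = (*self.lv_radii, self.lv_wall_thickness, *self.rv_radii,
                   self.rv_wall_thickness, self.fast_layer_thickness,
                   self.edge_length)
        if any(v <= 0 for v in lengths):
            raise ValueError("all anatomy lengths must be positive")
        if self.fast_layer_thickness >= self.min_wall_thickness:
            raise ValueError("fast-layer thickness must be smaller than the "
                             "thinnest wall")
        if not 0.0 <= self.base_truncation < 1.0:
            raise ValueError("base_truncation must be in [0, 1)")

    @property
    def lv_epi_radii(self):
        t = self.lv_wall_thickness
        return tuple(r + t for r in self.lv_radii)

    @property
    def min_wall_thickness(self):
        return min(self.lv_wall_thickness,
                   self.rv_wall_thickness if self.include_rv else np.inf)

    @property
    def base_z(self):
        """z of the truncation plane (base_truncation = fraction of the
        upper epicardial semi-axis removed; 0 keeps the closed ellipsoid)."""
        return self.lv_epi_radii[2] * (1.0 - self.base_truncation)


class TetMesh:
    """Plain tetrahedral mesh: the minimum the PDE solvers need."""

    def __init__(self, nodes, tets, element_tags=None):
        self.nodes = np.asarray(nodes, dtype=float)
        self.tets = np.asarray(tets, dtype=int)
        self.element_tags = (np.zeros(len(self.tets), dtype=int)
                             if element_tags is None else np.asarray(element_tags))

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.tets)

    def element_centroids(self):
        return self.nodes[self.tets].mean(axis=1)


@dataclass
class BiventricularMesh(TetMesh):
    """Labeled bi-ventricular tetrahedral anatomy."""

    def __init__(self, nodes, tets, boundary_faces, surface_labels,
                 element_tags, element_ventricle, transmural_depth,
                 nodal_depth, long_axis, valve_annulus_node_sets, base_z,
                 config=None):
        super().__init__(nodes, tets, element_tags)
        self.boundary_faces = np.asarray(boundary_faces, dtype=int)
        self.surface_labels = np.asarray(surface_labels, dtype=int)
        self.element_ventricle = np.asarray(element_ventricle, dtype=int)
        self.transmural_depth = np.asarray(transmural_depth, dtype=float)
        self.nodal_depth = np.asarray(nodal_depth, dtype=float)
        self.long_axis = np.asarray(long_axis, dtype=float)
        self.valve_annulus_node_sets = valve_annulus_node_sets
        self.base_z = float(base_z)
        self.config = config

    def facet_centroids(self, labels=None):
        faces = self.boundary_faces
        if labels is not None:
            faces = faces[np.isin(self.surface_labels, labels)]
        return self.nodes[faces].mean(axis=1)

    def surface_nodes(self, labels):
        faces = self.boundary_faces[np.isin(self.surface_labels, labels)]
        return np.unique(faces)

    def endo_distance(self, points, side):
        """Exact distance from ``points`` to the endocardial facet triangles."""
        labels = [LV_ENDO, LV_SEPTUM] if side == LV else [RV_ENDO, RV_SEPTUM]
        faces = self.boundary_faces[np.isin(self.surface_labels, labels)]
        if len(faces) == 0:
            return np.full(len(points), np.inf)
        return _min_distance_to_triangles(points, self.nodes, faces)

    def save(self, path):
        write_vtk(path, self.nodes, self.tets,
                  point_data={"transmural_depth": self.nodal_depth},
                  cell_data={"element_tag": self.element_tags,
                             "ventricle": self.element_ventricle,
                             "depth": self.transmural_depth},
                  title="cardiotwin biventricular mesh; units mm")


# ---------------------------------------------------------------------------
# implicit surfaces

def ellipsoid_signed_distance(points, center, semi_axes, return_projection=False):
    """Exact Euclidean signed distance to an ellipsoid surface (<0 inside).

    Uses the standard projection parameterization x_i = a_i^2 q_i/(a_i^2+L)
    and solves for L by vectorized bisection.
    """
    q = np.atleast_2d(points) - np.asarray(center, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    val = np.sum((q / a) ** 2, axis=1) - 1.0
    a2 = a ** 2
    lo = np.full(len(q), -a2.min() * (1 - 1e-12))
    hi = np.full(len(q), (np.linalg.norm(q, axis=1) + a.max()) * a.max())
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        f = np.sum((a * q / (a2 + mid[:, None])) ** 2, axis=1) - 1.0
        gt = f > 0
        lo = np.where(gt, mid, lo)
        hi = np.where(gt, hi, mid)
    L = 0.5 * (lo + hi)
    proj = a2 * q / (a2 + L[:, None])
    dist = np.linalg.norm(q - proj, axis=1) * np.sign(val)
    # the exact center projects onto the nearest pole of the shortest axis
    at_center = np.linalg.norm(q, axis=1) < 1e-12
    if np.any(at_center):
        k = int(np.argmin(a))
        dist[at_center] = -a[k]
        proj[at_center] = 0.0
        proj[at_center, k] = a[k]
    if return_projection:
        return dist, proj + center
    return dist


def _ellipsoid_normal(points, center, semi_axes):
    n = (np.atleast_2d(points) - np.asarray(center)) / np.asarray(semi_axes) ** 2
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _myocardium_sdf(points, config):
    """Approximate signed distance of the myocardial solid (<0 inside)."""
    c = config
    s_le = ellipsoid_signed_distance(points, (0, 0, 0), c.lv_radii)
    s_lp = ellipsoid_signed_distance(points, (0, 0, 0), c.lv_epi_radii)
    lv_wall = np.maximum(s_lp, -s_le)
    if c.include_rv:
        s_re = ellipsoid_signed_distance(points, c.rv_center_offset, c.rv_radii)
        rv_wall = np.maximum.reduce([s_re - c.rv_wall_thickness, -s_re, -s_lp])
        sdf = np.minimum(lv_wall, rv_wall)
    else:
        sdf = lv_wall
    return np.maximum(sdf, points[:, 2] - c.base_z)


def _in_rv_cavity(points, config):
    c = config
    if not c.include_rv:
        return np.zeros(len(points), dtype=bool)
    s_re = ellipsoid_signed_distance(points, c.rv_center_offset, c.rv_radii)
    s_lp = ellipsoid_signed_distance(points, (0, 0, 0), c.lv_epi_radii)
    return (s_re < 0) & (s_lp > 0) & (points[:, 2] < config.base_z)


# ---------------------------------------------------------------------------
# surface sampling

def _sample_truncated_ellipsoid(center, semi_axes, z_cap, h, rng,
                                jitter=0.3, fixed_rim=True):
    """Quasi-uniform point sample of an ellipsoid surface below z = z_cap.

    Rings of constant colatitude; the top ring sits exactly on the
    truncation plane (when the surface reaches it) so the BASE plane is
    cleanly resolved.  In-surface jitter breaks Delaunay degeneracies while
    keeping every point exactly on the analytic surface.
    """
    cx, cy, cz = center
    a, b, cax = semi_axes
    top = np.clip((z_cap - cz) / cax, -1.0, 1.0)
    phi_top = np.arccos(top)
    arc = (np.pi - phi_top) * (a + b + cax) / 3.0
    n_phi = max(4, int(np.ceil(arc / h)))
    pts = []
    for k in range(n_phi):
        phi = phi_top + (np.pi - phi_top) * k / n_phi
        if k > 0 or not fixed_rim:
            phi += (np.pi - phi_top) / n_phi * jitter * (rng.random() - 0.5)
        rho = np.sin(phi)
        ring_len = np.pi * (a + b) * rho
        n_t = max(3, int(np.ceil(ring_len / h)))
        theta = 2 * np.pi * (np.arange(n_t) + jitter * (rng.random(n_t) - 0.5)) / n_t
        pts.append(np.column_stack([cx + a * rho * np.cos(theta),
                                    cy + b * rho * np.sin(theta),
                                    cz + cax * np.cos(phi) * np.ones(n_t)]))
    pts.append(np.array([[cx, cy, cz - cax]]))  # apex
    return np.vstack(pts)


def _build_point_cloud(config, rng):
    c = config
    h = c.edge_length
    z_cap = c.base_z
    clouds = []
    # LV wall: endo / mid / epi layers
    t = c.lv_wall_thickness
    n_layers = max(2, int(round(t / h)) + 1)
    for i in range(n_layers + 1):
        xi = i / n_layers
        semi = tuple(r + xi * t for r in c.lv_radii)
        pts = _sample_truncated_ellipsoid((0, 0, 0), semi, z_cap, h, rng)
        clouds.append(pts)
    if c.include_rv:
        endo = _sample_truncated_ellipsoid(c.rv_center_offset, c.rv_radii,
                                           z_cap, h, rng)
        s_lp = ellipsoid_signed_distance(endo, (0, 0, 0), c.lv_epi_radii)
        endo = endo[s_lp > -0.25 * h]  # keep free-wall portion (+ junction)
        normals = _ellipsoid_normal(endo, c.rv_center_offset, c.rv_radii)
        tw = c.rv_wall_thickness
        n_rv = max(1, int(round(tw / h)))
        for i in range(n_rv + 1):
            layer = endo + (i / n_rv) * tw * normals
            # keep the top ring on the base plane (offset normals near the
            # base point upward and would otherwise leave a hole)
            layer[:, 2] = np.minimum(layer[:, 2], z_cap)
            clouds.append(layer)
    pts = np.vstack(clouds)
    pts = pts[pts[:, 2] <= z_cap + 1e-9]
    # deduplicate (apex points repeat per layer only if radii coincide)
    _, idx = np.unique(np.round(pts / (0.05 * h)).astype(np.int64),
                       axis=0, return_index=True)
    return pts[np.sort(idx)]


# ---------------------------------------------------------------------------
# boundary extraction

_FACE_OF_TET = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]


def boundary_faces_of(tets):
    """Outward-oriented boundary triangles of a tet set (faces used once)."""
    faces = np.concatenate([tets[:, f] for f in _FACE_OF_TET])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def _orient_outward(nodes, tets):
    """Permute tets so their signed volume is positive (outward face rule)."""
    vols = _fem.tet_volumes(nodes, tets)
    flip = vols < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def _min_distance_to_triangles(points, nodes, faces, k=12):
    """Exact min distance from each point to a triangle soup.

    Candidate triangles are pruned with a KD-tree on triangle centroids and
    the distance evaluated exactly (Eberly's region decomposition).
    """
    tri = nodes[faces]
    cent = tri.mean(axis=1)
    k = min(k, len(faces))
    _, idx = cKDTree(cent).query(points, k=k)
    idx = np.atleast_2d(idx)
    P = np.repeat(points, k, axis=0)
    T = tri[idx.ravel()]
    d = _point_triangle_distance(P, T[:, 0], T[:, 1], T[:, 2])
    return d.reshape(len(points), k).min(axis=1)


def _point_triangle_distance(p, a, b, c):
    """Vectorized exact point-triangle distance."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def set_closest(mask, value):
        m = mask & ~done
        closest[m] = value[m] if value.ndim == 2 else value
        done[m] = True

    set_closest((d1 <= 0) & (d2 <= 0), a)                       # vertex A
    set_closest((d3 >= 0) & (d4 <= d3), b)                      # vertex B
    set_closest((d6 >= 0) & (d5 <= d6), c)                      # vertex C
    vc = d1 * d4 - d3 * d2
    v = np.divide(d1, d1 - d3, out=np.zeros_like(d1),
                  where=np.abs(d1 - d3) > 1e-30)
    set_closest((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2),
                  where=np.abs(d2 - d6) > 1e-30)
    set_closest((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)
    va = d3 * d6 - d5 * d4
    w2 = np.divide(d4 - d3, (d4 - d3) + (d5 - d6), out=np.zeros_like(d4),
                   where=np.abs((d4 - d3) + (d5 - d6)) > 1e-30)
    set_closest((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
                b + w2[:, None] * (c - b))
    denom = va + vb + vc
    v_in = np.divide(vb, denom, out=np.zeros_like(vb),
                     where=np.abs(denom) > 1e-30)
    w_in = np.divide(vc, denom, out=np.zeros_like(vc),
                     where=np.abs(denom) > 1e-30)
    set_closest(np.ones(len(p), dtype=bool),
                a + v_in[:, None] * ab + w_in[:, None] * ac)
    return np.linalg.norm(p - closest, axis=1)


# ---------------------------------------------------------------------------
# mesh construction

def build_biventricular_mesh(config=None, seed=0):
    """Generate the labeled synthetic bi-ventricular tetrahedral mesh.

    Deterministic for fixed (config, seed): the only randomness is the
    seeded in-surface jitter that regularizes the Delaunay triangulation.
    """
    config = config or AnatomyConfig()
    rng = np.random.default_rng(seed)
    pts = _build_point_cloud(config, rng)
    if len(pts) < 10:
        raise ValueError("degenerate anatomy: point cloud too small; "
                         "check radii vs edge_length")
    tri = Delaunay(pts)
    cents = pts[tri.simplices].mean(axis=1)
    inside = _myocardium_sdf(cents, config) < 0.0
    tets = tri.simplices[inside]
    if len(tets) == 0:
        raise ValueError("meshing failure: no interior tetrahedra "
                         "(degenerate radii or edge length too large)")
    tets = _orient_outward(pts, tets)
    # compact node numbering
    used = np.unique(tets)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = pts[used]
    tets = remap[tets]

    faces = boundary_faces_of(tets)
    labels = _label_boundary(nodes, faces, config)
    nodal_depth, elem_depth = _transmural_depth(nodes, tets, faces, labels)
    ventricle = _assign_ventricle(nodes, tets, faces, labels, elem_depth, config)
    valve_sets = _valve_annulus_sets(nodes, faces, labels, config)

    mesh = BiventricularMesh(
        nodes=nodes, tets=tets, boundary_faces=faces, surface_labels=labels,
        element_tags=np.full(len(tets), MYO), element_ventricle=ventricle,
        transmural_depth=elem_depth, nodal_depth=nodal_depth,
        long_axis=np.array([0.0, 0.0, 1.0]), valve_annulus_node_sets=valve_sets,
        base_z=config.base_z, config=config)
    if config.fast_layer_thickness > 0:
        mesh = tag_fast_layer(mesh, config.fast_layer_thickness)
    return mesh


def _label_boundary(nodes, faces, config):
    c = config
    cents = nodes[faces].mean(axis=1)
    normals = np.cross(nodes[faces[:, 1]] - nodes[faces[:, 0]],
                       nodes[faces[:, 2]] - nodes[faces[:, 0]])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-30)
    h = c.edge_length
    labels = np.full(len(faces), EPI)

    d_le = np.abs(ellipsoid_signed_distance(cents, (0, 0, 0), c.lv_radii))
    s_lp = ellipsoid_signed_distance(cents, (0, 0, 0), c.lv_epi_radii)
    cands = [d_le, np.abs(s_lp)]
    if c.include_rv:
        s_re = ellipsoid_signed_distance(cents, c.rv_center_offset, c.rv_radii)
        # the RV surfaces only exist outside the LV epicardium; where the
        # analytic RV ellipsoid dives inside it (apex, junction) it must not
        # capture LV facets
        rv_valid = s_lp > -0.5 * h
        d_re = np.where(rv_valid, np.abs(s_re), np.inf)
        d_rp = np.where(rv_valid, np.abs(s_re - c.rv_wall_thickness), np.inf)
        cands += [d_re, d_rp]
    nearest = np.argmin(np.stack(cands), axis=0)

    on_base = np.abs(cents[:, 2] - c.base_z) < 0.3 * h

    lv_endo = (nearest == 0) & ~on_base
    probe = cents - normals * (c.lv_wall_thickness + 2.0)
    septal_lv = _in_rv_cavity(probe, c)
    labels[lv_endo & ~septal_lv] = LV_ENDO
    labels[lv_endo & septal_lv] = LV_SEPTUM

    lv_epi = (nearest == 1) & ~on_base
    probe2 = cents + normals * 1.5
    rv_side = _in_rv_cavity(probe2, c)
    labels[lv_epi & rv_side] = RV_SEPTUM
    labels[lv_epi & ~rv_side] = EPI

    if c.include_rv:
        labels[(nearest == 2) & ~on_base] = RV_ENDO
        labels[(nearest == 3) & ~on_base] = EPI
    labels[on_base] = BASE
    return labels


def _transmural_depth(nodes, tets, faces, labels):
    """Laplace transmural coordinate: 1 on endocardium, 0 on the outer faces.

    The RV septal face counts as "outer" so the depth varies across the
    septum even though both of its faces are endocardial; the BASE plane
    carries the natural boundary condition.
    """
    endo_nodes = np.unique(faces[np.isin(labels, [LV_ENDO, LV_SEPTUM, RV_ENDO])])
    out_nodes = np.unique(faces[np.isin(labels, [EPI, RV_SEPTUM])])
    out_nodes = np.setdiff1d(out_nodes, endo_nodes)
    dir_nodes = np.concatenate([endo_nodes, out_nodes])
    dir_vals = np.concatenate([np.ones(len(endo_nodes)), np.zeros(len(out_nodes))])
    u = _fem.solve_laplace_dirichlet(nodes, tets, dir_nodes, dir_vals)
    u = np.clip(u, 0.0, 1.0)
    return u, u[tets].mean(axis=1)


def _assign_ventricle(nodes, tets, faces, labels, elem_depth, config):
    """LV/RV ownership for the fiber rule.

    RV free-wall elements belong to the RV; septal elements on the RV side
    of the septal mid-surface (depth < 0.5, i.e. closer to the RV cavity)
    also follow the RV rule.
    """
    cents = nodes[tets].mean(axis=1)
    ventricle = np.full(len(tets), LV)
    if not config.include_rv:
        return ventricle
    s_re = ellipsoid_signed_distance(cents, config.rv_center_offset,
                                     config.rv_radii)
    s_lp = ellipsoid_signed_distance(cents, (0, 0, 0), config.lv_epi_radii)
    rv_free = (s_lp > 0) & (s_re >= -0.5 * config.edge_length)
    ventricle[rv_free] = RV
    # septal split: nearest outer face decides septal membership
    epi_c = nodes[faces[labels == EPI]].mean(axis=1)
    sep_c = nodes[faces[labels == RV_SEPTUM]].mean(axis=1)
    if len(sep_c) and len(epi_c):
        d_epi, _ = cKDTree(epi_c).query(cents[~rv_free])
        d_sep, _ = cKDTree(sep_c).query(cents[~rv_free])
        septal = d_sep < d_epi
        rv_half = septal & (elem_depth[~rv_free] < 0.5)
        idx = np.flatnonzero(~rv_free)
        ventricle[idx[rv_half]] = RV
    return ventricle


def _valve_annulus_sets(nodes, faces, labels, config):
    """Four node rings on the base plane standing in for the valve annuli."""
    base_nodes = np.unique(faces[labels == BASE])
    sets = {"mitral": np.array([], int), "aortic": np.array([], int),
            "tricuspid": np.array([], int), "pulmonary": np.array([], int)}
    if len(base_nodes) == 0:
        return sets
    # keep only nodes actually on the truncation plane (a BASE facet can
    # reach one ring below it)
    on_plane = np.abs(nodes[base_nodes, 2] - config.base_z) \
        < 0.3 * config.edge_length
    base_nodes = base_nodes[on_plane]
    p = nodes[base_nodes]
    lv_ring = np.abs(ellipsoid_signed_distance(p, (0, 0, 0), config.lv_radii)) \
        < 0.75 * config.edge_length
    if config.include_rv:
        rv_ring = np.abs(ellipsoid_signed_distance(
            p, config.rv_center_offset, config.rv_radii)) < 0.75 * config.edge_length
        rv_ring &= ~lv_ring
    else:
        rv_ring = np.zeros(len(p), dtype=bool)
    ant = p[:, 1] >= 0
    sets["mitral"] = base_nodes[lv_ring & ~ant]
    sets["aortic"] = base_nodes[lv_ring & ant]
    sets["tricuspid"] = base_nodes[rv_ring & ~ant]
    sets["pulmonary"] = base_nodes[rv_ring & ant]
    return sets


# ---------------------------------------------------------------------------
# operations

def tag_fast_layer(mesh, thickness):
    """Tag the thin sub-endocardial fast-conduction (Purkinje-like) layer.

    Elements whose centroid lies within ``thickness`` of the LV (resp. RV)
    endocardial surface are tagged LV_FAST_LAYER (resp. RV_FAST_LAYER); ties
    go to the nearer surface.  Returns a new mesh; the input is unchanged.
    """
    if thickness <= 0:
        tags = np.full(mesh.n_elements, MYO)
    else:
        cfg = mesh.config
        if cfg is not None and thickness >= cfg.min_wall_thickness:
            raise ValueError(
                f"fast-layer thickness {thickness} mm would span the "
                f"{cfg.min_wall_thickness} mm wall")
        cents = mesh.element_centroids()
        d_lv = mesh.endo_distance(cents, LV)
        d_rv = mesh.endo_distance(cents, RV)
        tags = np.full(mesh.n_elements, MYO)
        tags[(d_lv <= thickness) & (d_lv <= d_rv)] = LV_FAST_LAYER
        tags[(d_rv <= thickness) & (d_rv < d_lv)] = RV_FAST_LAYER
    out = BiventricularMesh(
        mesh.nodes, mesh.tets, mesh.boundary_faces, mesh.surface_labels,
        tags, mesh.element_ventricle, mesh.transmural_depth, mesh.nodal_depth,
        mesh.long_axis, mesh.valve_annulus_node_sets, mesh.base_z, mesh.config)
    return out


def surface_volume(nodes, faces):
    """Signed volume (mm^3) enclosed by an oriented closed triangle surface."""
    a, b, c = nodes[faces[:, 0]], nodes[faces[:, 1]], nodes[faces[:, 2]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0


def _open_rim_edges(faces):
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return edges[counts[inv] == 1]


def chamber_volume(mesh, chamber, cap_base=True):
    """Blood-pool volume of a chamber in ml (divergence-theorem surface integral).

    The endocardial surface is capped at the base plane by a fan to the rim
    centroid.  With ``cap_base=False`` the surface must already be closed.
    """
    labels = {"LV": [LV_ENDO, LV_SEPTUM], "RV": [RV_ENDO, RV_SEPTUM]}[chamber]
    sel = np.isin(mesh.surface_labels, labels)
    if not np.any(sel):
        raise ValueError(f"no endocardial surface for chamber {chamber}")
    faces = mesh.boundary_faces[sel]
    # facet orientation is outward of the myocardium = inward of the cavity
    faces = faces[:, ::-1]
    rim = _open_rim_edges(faces)
    if len(rim):
        if not cap_base:
            raise ValueError("endocardial surface is open at the base; "
                             "call with cap_base=True")
        centroid = mesh.nodes[np.unique(rim)].mean(axis=0)
        nodes = np.vstack([mesh.nodes, centroid])
        cap = np.column_stack([rim[:, 1], rim[:, 0],
                               np.full(len(rim), len(nodes) - 1)])
        faces = np.vstack([faces, cap])
    else:
        nodes = mesh.nodes
    return abs(surface_volume(nodes, faces)) / 1000.0


def mean_wall_thickness(mesh, side=RV):
    """Mean endo-to-epi distance (mm) over the free-wall interior.

    Measured from endocardial facet centroids to the epicardial triangle
    soup; facets touching the base rim or the septal junction are excluded
    because their nearest epicardial point cuts the corner rather than
    crossing the wall.
    """
    endo_label = RV_ENDO if side == RV else LV_ENDO
    faces = mesh.boundary_faces
    labels = mesh.surface_labels
    endo_faces = faces[labels == endo_label]
    epi_faces = faces[labels == EPI]
    if len(endo_faces) == 0 or len(epi_faces) == 0:
        raise ValueError("missing surfaces for wall-thickness measurement")
    rim_labels = [BASE, RV_SEPTUM] if side == RV else [BASE, LV_SEPTUM]
    rim_nodes = np.unique(faces[np.isin(labels, rim_labels)])
    interior = ~np.isin(endo_faces, rim_nodes).any(axis=1)
    if interior.sum() == 0:
        interior[:] = True
    cents = mesh.nodes[endo_faces[interior]].mean(axis=1)
    d = _min_distance_to_triangles(cents, mesh.nodes, epi_faces)
    return float(d.mean())


# ---------------------------------------------------------------------------
# structured test meshes

def box_mesh(nx, ny, nz, dx, dy=None, dz=None, origin=(0.0, 0.0, 0.0)):
    """Structured box of (nx, ny, nz) nodes split into 6 tets per cell."""
    dy = dx if dy is None else dy
    dz = dx if dz is None else dz
    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    zs = origin[2] + dz * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                          np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    v = [nid(i + a, j + b, k + c) for a, b, c in
         [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
          (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]]
    # Kuhn subdivision around the main diagonal v0-v7
    pattern = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
               (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
    tets = np.concatenate([np.column_stack([v[p] for p in pat])
                           for pat in pattern])
    tets = _orient_outward(nodes, tets)
    return TetMesh(nodes, tets)


def load_mesh(path):
    """Read a mesh written by :meth:`BiventricularMesh.save` (labels are
    reconstructed only if present as cell data written by this package)."""
    points, cells, pdata, cdata = read_vtk(path)
    mesh = TetMesh(points, cells, cdata.get("element_tag"))
    for name in ("ventricle", "depth"):
        if name in cdata:
            setattr(mesh, name, cdata[name])
    if "transmural_depth" in pdata:
        mesh.nodal_depth = pdata["transmural_depth"]
    return mesh
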
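"""Synthetic anatomy: construction, labeling, tagging, volumes."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from cardiotwin import geometry as geo
from cardiotwin._vtk import read_vtk, write_vtk
from tests.conftest import SMALL_BIV_CONFIG


def test_build_is_deterministic():
    cfg = geo.AnatomyConfig(edge_length=4.5)
    m1 = geo.build_biventricular_mesh(cfg, seed=11)
    m2 = geo.build_biventricular_mesh(cfg, seed=11)
    assert np.array_equal(m1.nodes, m2.nodes)
    assert np.array_equal(m1.tets, m2.tets)
    assert np.array_equal(m1.surface_labels, m2.surface_labels)
    m3 = geo.build_biventricular_mesh(cfg, seed=12)
    assert not np.array_equal(m1.nodes, m3.nodes)


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        geo.AnatomyConfig(lv_wall_thickness=-1.0)
    with pytest.raises(ValueError):
        geo.AnatomyConfig(fast_layer_thickness=5.0)  # exceeds 3 mm RV wall
    with pytest.raises(ValueError):
        geo.AnatomyConfig(base_truncation=1.5)


def test_surface_labels_partition_boundary(small_biv_mesh):
    labels = small_biv_mesh.surface_labels
    assert len(labels) == len(small_biv_mesh.boundary_faces)
    known = {geo.LV_ENDO, geo.RV_ENDO, geo.LV_SEPTUM, geo.RV_SEPTUM,
             geo.EPI, geo.BASE}
    assert set(np.unique(labels)) <= known
    for lab in (geo.LV_ENDO, geo.RV_ENDO, geo.RV_SEPTUM, geo.EPI, geo.BASE):
        assert (labels == lab).sum() > 0


def test_transmural_depth_in_unit_interval(small_biv_mesh):
    assert small_biv_mesh.nodal_depth.min() >= 0.0
    assert small_biv_mesh.nodal_depth.max() <= 1.0
    # endo hot, outer cold
    endo = small_biv_mesh.surface_nodes([geo.LV_ENDO, geo.LV_SEPTUM,
                                         geo.RV_ENDO])
    # junction nodes shared with an endocardial surface carry the endo value
    epi = np.setdiff1d(small_biv_mesh.surface_nodes([geo.EPI]), endo)
    assert small_biv_mesh.nodal_depth[endo].mean() > 0.95
    assert small_biv_mesh.nodal_depth[epi].mean() < 0.05


def test_closed_ellipsoid_cavity_volume():
    """With no base truncation the LV cavity is a full ellipsoid."""
    cfg = geo.AnatomyConfig(lv_radii=(15, 15, 25), lv_wall_thickness=7,
                            include_rv=False, base_truncation=0.0,
                            edge_length=3.0)
    mesh = geo.build_biventricular_mesh(cfg, seed=1)
    analytic = 4.0 / 3.0 * np.pi * 15 * 15 * 25 / 1000.0
    vol = geo.chamber_volume(mesh, "LV", cap_base=False)
    # inscribed facets underestimate a curved surface by O(h^2/r^2)
    assert vol == pytest.approx(analytic, rel=0.025)


def test_truncated_cavity_volume_matches_analytic(small_biv_mesh):
    a, b, c = SMALL_BIV_CONFIG.lv_radii
    zt = SMALL_BIV_CONFIG.base_z / c
    analytic = np.pi * a * b * c * (2 / 3 + zt - zt ** 3 / 3) / 1000.0
    assert geo.chamber_volume(small_biv_mesh, "LV") == pytest.approx(
        analytic, rel=0.04)


def test_volume_translation_invariance(small_biv_mesh):
    v0 = geo.chamber_volume(small_biv_mesh, "LV")
    shifted = geo.BiventricularMesh(
        small_biv_mesh.nodes + np.array([13.0, -7.0, 42.0]),
        small_biv_mesh.tets, small_biv_mesh.boundary_faces,
        small_biv_mesh.surface_labels, small_biv_mesh.element_tags,
        small_biv_mesh.element_ventricle, small_biv_mesh.transmural_depth,
        small_biv_mesh.nodal_depth, small_biv_mesh.long_axis,
        small_biv_mesh.valve_annulus_node_sets, small_biv_mesh.base_z)
    assert geo.chamber_volume(shifted, "LV") == pytest.approx(v0, rel=1e-12)


def test_surface_volume_matches_convex_hull_oracle():
    rng = np.random.default_rng(4)
    pts = rng.standard_normal((120, 3)) * [12.0, 9.0, 15.0]
    hull = ConvexHull(pts)
    faces = hull.simplices
    # orient all faces outward (away from the centroid)
    cent = pts[np.unique(faces)].mean(axis=0)
    tri = pts[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", n, tri.mean(axis=1) - cent) < 0
    faces[flip] = faces[flip][:, ::-1]
    vol = geo.surface_volume(pts, faces)
    assert vol == pytest.approx(hull.volume, rel=1e-3)


def test_open_surface_without_cap_raises(small_biv_mesh):
    with pytest.raises(ValueError, match="open"):
        geo.chamber_volume(small_biv_mesh, "LV", cap_base=False)


def test_volume_converges_under_refinement():
    vols = []
    for edge in (4.0, 3.0):
        cfg = geo.AnatomyConfig(edge_length=edge)
        vols.append(geo.chamber_volume(
            geo.build_biventricular_mesh(cfg, seed=1), "LV"))
    assert abs(vols[1] - vols[0]) / vols[1] < 0.01


def test_rv_wall_thickness_near_3mm(small_biv_mesh):
    """The thin RV free wall is built as a 3 mm offset surface."""
    t = geo.mean_wall_thickness(small_biv_mesh, geo.RV)
    assert t == pytest.approx(3.0, abs=0.5)


def test_fast_layer_within_thickness(small_biv_mesh):
    tagged = small_biv_mesh.element_tags != geo.MYO
    assert tagged.sum() > 0
    cents = small_biv_mesh.element_centroids()[tagged]
    d_lv = small_biv_mesh.endo_distance(cents, geo.LV)
    d_rv = small_biv_mesh.endo_distance(cents, geo.RV)
    assert np.minimum(d_lv, d_rv).max() <= 1.0 + 1e-9
    # every tag appears
    assert (small_biv_mesh.element_tags == geo.LV_FAST_LAYER).sum() > 0
    assert (small_biv_mesh.element_tags == geo.RV_FAST_LAYER).sum() > 0


def test_fast_layer_zero_thickness_empty(small_biv_mesh):
    out = geo.tag_fast_layer(small_biv_mesh, 0.0)
    assert np.all(out.element_tags == geo.MYO)


def test_fast_layer_spanning_wall_raises(small_biv_mesh):
    with pytest.raises(ValueError, match="wall"):
        geo.tag_fast_layer(small_biv_mesh, 5.0)


def test_fast_layer_volume_converges_to_shell():
    """On a spherical LV the 1 mm sub-endocardial shell volume is known."""
    ratios = []
    for edge in (3.0, 2.0):
        cfg = geo.AnatomyConfig(lv_radii=(18, 18, 18), lv_wall_thickness=7,
                                include_rv=False, base_truncation=0.4,
                                edge_length=edge)
        mesh = geo.build_biventricular_mesh(cfg, seed=1)
        vols = np.abs(geo._fem.tet_volumes(mesh.nodes, mesh.tets))
        tagged_vol = vols[mesh.element_tags == geo.LV_FAST_LAYER].sum()

        def cap_vol(r, zcap):
            zc = min(zcap, r)
            return np.pi * (2 * r ** 3 / 3 + r ** 2 * zc - zc ** 3 / 3)

        shell = cap_vol(19.0, cfg.base_z) - cap_vol(18.0, cfg.base_z)
        ratios.append(tagged_vol / shell)
    assert 0.55 < ratios[0] < 1.3
    assert abs(ratios[1] - 1.0) < abs(ratios[0] - 1.0)
    assert 0.8 < ratios[1] < 1.2


def test_valve_annulus_rings_on_base(small_biv_mesh):
    sets = small_biv_mesh.valve_annulus_node_sets
    assert set(sets) == {"mitral", "aortic", "tricuspid", "pulmonary"}
    for name, nodes in sets.items():
        assert len(nodes) > 0, name
        z = small_biv_mesh.nodes[nodes, 2]
        assert np.allclose(z, small_biv_mesh.base_z, atol=1.0)


def test_vtk_roundtrip(tmp_path, small_biv_mesh):
    path = tmp_path / "heart.vtk"
    write_vtk(path, small_biv_mesh.nodes, small_biv_mesh.tets,
              point_data={"depth": small_biv_mesh.nodal_depth},
              cell_data={"tag": small_biv_mesh.element_tags,
                         "vec": np.ones((small_biv_mesh.n_elements, 3))})
    pts, cells, pdata, cdata = read_vtk(path)
    assert np.allclose(pts, small_biv_mesh.nodes)
    assert np.array_equal(cells, small_biv_mesh.tets)
    assert np.allclose(pdata["depth"], small_biv_mesh.nodal_depth, atol=1e-8)
    assert np.array_equal(cdata["tag"], small_biv_mesh.element_tags)
    assert cdata["vec"].shape == (small_biv_mesh.n_elements, 3)


def test_ellipsoid_signed_distance_sphere():
    pts = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
    d = geo.ellipsoid_signed_distance(pts, (0, 0, 0), (10.0, 10.0, 10.0))
    assert np.allclose(d, [-10.0, 10.0, -5.0], atol=1e-6)
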
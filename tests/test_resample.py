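import numpy as np
import pytest

import meshkit as mk
from meshkit import synth
from meshkit.topology import TET_FACES, _element_edges


def edge_lengths(mesh: mk.Mesh) -> np.ndarray:
    e, _ = _element_edges(mesh)
    ue = np.unique(e, axis=0)
    return np.linalg.norm(mesh.points[ue[:, 0]] - mesh.points[ue[:, 1]], axis=1)


def region_interior_edge_lengths(mesh: mk.Mesh, tag: int) -> np.ndarray:
    e, own = _element_edges(mesh)
    order = np.lexsort(e.T[::-1])
    e, own = e[order], own[order]
    u, start = np.unique(e, axis=0, return_index=True)
    bounds = np.append(start, len(e))
    keep = [i for i in range(len(u))
            if np.all(mesh.tags[own[bounds[i]:bounds[i + 1]]] == tag)]
    u = u[keep]
    return np.linalg.norm(mesh.points[u[:, 0]] - mesh.points[u[:, 1]], axis=1)


def assert_conforming(mesh: mk.Mesh):
    _, tc = mesh.tets()
    faces = np.sort(tc[:, TET_FACES].reshape(-1, 3), axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    assert set(counts.tolist()) <= {1, 2}


class TestResampleSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(mk.ValidationError):
            mk.ResampleSpec(max_edge=-1.0)
        with pytest.raises(mk.ValidationError):
            mk.ResampleSpec(min_edge=2.0, max_edge=1.0)
        with pytest.raises(mk.ValidationError):
            mk.ResampleSpec(min_edge=1.0, normal_change_max_deg=200.0)

    def test_average_maps_to_bracket(self):
        s = mk.ResampleSpec.from_average(2.0)
        assert s.min_edge == pytest.approx(1.4)
        assert s.max_edge == pytest.approx(2.8)


class TestSplitLongEdges:
    def test_identity_when_all_short(self, box3):
        out = mk.split_long_edges(box3, mk.ResampleSpec(max_edge=10.0))
        assert np.array_equal(out.conn, box3.conn)
        assert np.array_equal(out.points, box3.points)

    def test_single_tet_postconditions(self, single_tet):
        L = np.sqrt(2)  # longest edge of the right-corner tet
        out = mk.split_long_edges(single_tet, mk.ResampleSpec(max_edge=0.6 * L))
        assert edge_lengths(out).max() <= 0.6 * L + 1e-12
        vols = out.tet_volumes()
        assert np.all(vols > 0)
        assert vols.sum() == pytest.approx(1 / 6, rel=1e-9)  # volume conserved
        assert_conforming(out)
        assert np.all(out.tags == 7)  # children inherit the parent tag

    def test_fibers_inherited(self, single_tet):
        m = single_tet.copy()
        m.fibers = np.array([[0.0, 0.0, 1.0]])
        out = mk.split_long_edges(m, mk.ResampleSpec(max_edge=0.9))
        assert np.all(out.fibers == [0.0, 0.0, 1.0])

    def test_node_fields_midpoint_interpolated(self, box3):
        # a linear function of position must stay linear under bisection
        f = mk.DataField("node", box3.points @ np.array([1.0, 2.0, -0.5]))
        out, fields = mk.split_long_edges(
            box3, mk.ResampleSpec(max_edge=1.2), fields=[f])
        expect = out.points @ np.array([1.0, 2.0, -0.5])
        assert np.allclose(fields[0].values, expect, atol=1e-12)

    def test_tag_restriction_leaves_far_region_untouched(self, two_label_box):
        spec = mk.ResampleSpec(max_edge=1.2, tag_restriction={1})
        out = mk.split_long_edges(two_label_box, spec)
        out.validate()
        assert_conforming(out)
        # tag-2 cubes at x > 3 are not incident to the interface at x = 2
        def far_centroids(m):
            c = m.centroids()
            sel = (m.tags == 2) & (c[:, 0] > 3.0)
            return c[sel]
        a = np.array(sorted(map(tuple, far_centroids(two_label_box))))
        b = np.array(sorted(map(tuple, far_centroids(out))))
        assert np.array_equal(a, b)

    def test_requires_max_edge(self, box3):
        with pytest.raises(mk.ValidationError):
            mk.split_long_edges(box3, mk.ResampleSpec(min_edge=0.5))


class TestCollapseShortEdges:
    def test_identity_when_all_long(self, box3):
        out = mk.collapse_short_edges(box3, mk.ResampleSpec(min_edge=0.5))
        assert np.array_equal(out.conn, box3.conn)

    def test_coarsening_postconditions(self):
        m = synth.box_tet_mesh(6, 6, 6, h=0.5)
        stats: dict = {}
        out = mk.collapse_short_edges(m, mk.ResampleSpec(min_edge=1.0),
                                      stats_out=stats)
        out.validate()
        assert out.n_elems < m.n_elems
        assert np.all(out.tet_volumes() > 0)
        assert_conforming(out)
        assert stats["n_collapses"] > 0
        assert stats["n_uncollapsible"] >= 0  # reported, never an error
        # boundary vertices stay on the box surface
        s = mk.extract_boundary_surface(out, {1})
        bp = out.points[s.vertex_set]
        on_plane = np.any((np.abs(bp) < 1e-9) | (np.abs(bp - 3.0) < 1e-9), axis=1)
        assert np.all(on_plane)
        # corners are POINT-class and must survive untouched
        for corner in ([0, 0, 0], [3, 3, 3], [0, 3, 0]):
            assert np.any(np.all(out.points == corner, axis=1))

    def test_flip_case_dismissed(self):
        """An edge whose collapse would invert an incident tet survives."""
        pts = np.array([
            [1.0, 0, 0], [0, 1, 0], [-1, -1, 0],   # base plane z=0
            [0.0, 0, 0.01],                        # a: just above the plane
            [0.0, 0, -0.01],                       # b: just below
        ])
        conn = np.array([[0, 1, 2, 3], [0, 1, 3, 4]])
        m = mk.Mesh(pts, conn, np.array([4, 4]), np.array([1, 1]))
        mk.orient_tets_positive(m)
        # neutral labeling so only the geometric checks decide
        lab = mk.ManifoldLabeling(
            np.zeros(5, dtype=np.int8), [()] * 5,
            [np.empty(0, dtype=np.int64)] * 5)
        stats: dict = {}
        out = mk.collapse_short_edges(m, mk.ResampleSpec(min_edge=0.1),
                                      labeling=lab, stats_out=stats)
        assert stats["n_collapses"] == 0
        assert stats["n_uncollapsible"] == 1
        assert out.n_elems == 2  # nothing deleted

    def test_volume_change_bounded(self):
        m = synth.box_tet_mesh(5, 5, 5, h=0.6)
        v0 = m.tet_volumes().sum()
        out = mk.collapse_short_edges(
            m, mk.ResampleSpec(min_edge=1.0, normal_change_max_deg=25.0))
        v1 = out.tet_volumes().sum()
        assert abs(v1 - v0) / v0 <= 0.01


class TestResample:
    def test_spec_with_only_max_on_coarse_mesh_is_identity(self, box3):
        out, rep = mk.resample(box3, mk.ResampleSpec(max_edge=5.0))
        assert np.array_equal(out.conn, box3.conn)
        assert rep.n_splits == 0 and rep.n_collapses == 0

    def test_requires_some_target(self, box3):
        with pytest.raises(mk.ValidationError):
            mk.resample(box3, mk.ResampleSpec())

    def test_three_region_retargeting(self):
        """Per-region average targets are hit within 20% and the max target
        is never exceeded by a region-interior edge."""
        m = synth.box_tet_mesh(8, 8, 8, label_planes=[(0, 3.0), (0, 6.0)])
        targets = {1: 2.4, 2: 1.7, 3: 1.0}
        cur = m
        for tag, tgt in targets.items():
            spec = mk.ResampleSpec.from_average(tgt, tag_restriction={tag})
            cur, rep = mk.resample(cur, spec)
            assert rep.n_uncollapsible >= 0
        cur.validate()
        assert np.all(cur.tet_volumes() > 0)
        assert_conforming(cur)
        for tag, tgt in targets.items():
            ln = region_interior_edge_lengths(cur, tag)
            assert abs(ln.mean() - tgt) / tgt <= 0.20
            assert ln.max() <= 1.4 * tgt + 1e-9

    def test_quality_degrades_only_slightly(self):
        m = synth.box_tet_mesh(6, 6, 6)
        out, rep = mk.resample(m, mk.ResampleSpec.from_average(1.8))
        assert rep.quality_before is not None and rep.quality_after is not None
        assert rep.quality_before.mean - rep.quality_after.mean < 0.15
        assert rep.quality_after.histogram.sum() == int(out.tet_mask.sum())

    def test_triangle_surface_resampling(self, ico4):
        out, rep = mk.resample(ico4, mk.ResampleSpec.from_average(0.12))
        out.validate()
        ln = edge_lengths(out)
        assert ln.max() <= 1.4 * 0.12 + 1e-9
        # the resampled sphere is still closed and nearly volume-preserving
        s = mk.surface_from_triangles(out)
        v = mk.enclosed_volume(s, out.points)
        assert v == pytest.approx(4 / 3 * np.pi, rel=0.05)
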
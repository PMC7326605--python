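import numpy as np
import pytest

import meshkit as mk
from meshkit import synth


class TestExtractInsert:
    def test_full_extraction_is_identity(self, two_label_box):
        sub, mp = mk.extract_submesh(two_label_box, {1, 2})
        assert np.array_equal(sub.conn, two_label_box.conn)
        assert np.array_equal(mp.node_map, np.arange(two_label_box.n_points))
        assert np.array_equal(mp.elem_map, np.arange(two_label_box.n_elems))

    def test_one_label_coordinates_identical(self, two_label_box):
        sub, mp = mk.extract_submesh(two_label_box, {1})
        assert sub.n_elems == int((two_label_box.tags == 1).sum())
        assert np.array_equal(sub.points, two_label_box.points[mp.node_map])
        mp.validate(two_label_box)

    def test_empty_selection_raises(self, box3):
        with pytest.raises(mk.EmptySelectionError, match="42"):
            mk.extract_submesh(box3, {42})

    def test_insert_extract_round_trip(self, two_label_box):
        sub, mp = mk.extract_submesh(two_label_box, {2})
        back = mk.insert_submesh(two_label_box, sub, mp)
        assert np.array_equal(back.points, two_label_box.points)
        assert np.array_equal(back.tags, two_label_box.tags)

    def test_random_partition_reconstructs_exactly(self, box3):
        rng = np.random.default_rng(8)
        m = box3.copy()
        m.tags = rng.integers(1, 4, size=m.n_elems)
        acc = m.copy()
        acc.points = np.zeros_like(m.points)
        acc.tags = np.zeros_like(m.tags)
        for t in (1, 2, 3):
            sub, mp = mk.extract_submesh(m, {t})
            acc.points[mp.node_map] = sub.points
            acc.tags[mp.elem_map] = sub.tags
        assert np.array_equal(acc.points, m.points)
        assert np.array_equal(acc.tags, m.tags)

    def test_only_mapped_nodes_differ_after_edit(self, two_label_box):
        sub, mp = mk.extract_submesh(two_label_box, {1})
        moved = sub.copy()
        moved.points = moved.points + 0.01
        out = mk.insert_submesh(two_label_box, moved, mp)
        unmapped = np.setdiff1d(np.arange(two_label_box.n_points), mp.node_map)
        assert np.array_equal(out.points[unmapped], two_label_box.points[unmapped])
        assert np.allclose(out.points[mp.node_map], sub.points + 0.01)

    def test_stale_mapping_after_collapse(self, box3):
        sub, mp = mk.extract_submesh(box3, {1})
        coarse = mk.collapse_short_edges(sub, mk.ResampleSpec(min_edge=1.5))
        assert coarse.n_points != sub.n_points
        with pytest.raises(mk.MappingStaleError):
            mk.insert_submesh(box3, coarse, mp)


class TestDataTransfer:
    def test_gather_scatter_identity(self, two_label_box):
        sub, mp = mk.extract_submesh(two_label_box, {1})
        rng = np.random.default_rng(3)
        parent = mk.DataField("node", rng.normal(size=two_label_box.n_points))
        gathered = mk.extract_data(parent, mp)
        assert np.array_equal(gathered.values, parent.values[mp.node_map])
        back = mk.insert_data(parent, gathered, mp)
        assert np.array_equal(back.values, parent.values)

    def test_unmapped_entries_untouched(self, two_label_box):
        sub, mp = mk.extract_submesh(two_label_box, {1})
        parent = mk.DataField("element", np.zeros(two_label_box.n_elems))
        edited = mk.DataField("element", np.ones(len(mp.elem_map)))
        out = mk.insert_data(parent, edited, mp)
        unmapped = np.setdiff1d(np.arange(two_label_box.n_elems), mp.elem_map)
        assert np.all(out.values[unmapped] == 0.0)
        assert np.all(out.values[mp.elem_map] == 1.0)

    def test_length_mismatch_rejected(self, two_label_box):
        _, mp = mk.extract_submesh(two_label_box, {1})
        with pytest.raises(mk.ValidationError):
            mk.insert_data(mk.DataField("node", np.zeros(two_label_box.n_points)),
                           mk.DataField("node", np.zeros(3)), mp)


class TestExtractOverlap:
    def test_distant_mesh_gives_empty_overlap(self, box3):
        far = box3.copy()
        far.points = far.points + 1000.0
        (ovl, _), (compl, cmap) = mk.extract_overlap(box3, far, size=3.0)
        assert ovl.n_elems == 0
        assert compl.n_elems == box3.n_elems
        assert np.array_equal(cmap.elem_map, np.arange(box3.n_elems))

    def test_matches_all_pairs_oracle(self, box3):
        rod, rpts = synth.rod_surface(2.0, 0.4, segments=16, center=(1.5, 1.5, 1.5))
        rod_mesh = mk.Mesh(rpts, rod.faces, np.full(rod.n_faces, 3, dtype=np.int8),
                           np.zeros(rod.n_faces, dtype=np.int64))
        size = 0.5
        (ovl, omap), (compl, cmap) = mk.extract_overlap(box3, rod_mesh, size)
        cent = box3.centroids()
        d = np.min(np.linalg.norm(cent[:, None, :] - rpts[None], axis=2), axis=1)
        expect = set(np.flatnonzero(d <= size).tolist())
        assert set(omap.elem_map.tolist()) == expect
        # partition law
        assert ovl.n_elems + compl.n_elems == box3.n_elems
        assert set(omap.elem_map) | set(cmap.elem_map) == set(range(box3.n_elems))
        assert set(omap.elem_map) & set(cmap.elem_map) == set()

    def test_size_zero_boundary_semantics(self, box3):
        (ovl, _), _ = mk.extract_overlap(box3, box3, size=0.0)
        # centroids generically coincide with no vertex
        assert ovl.n_elems == 0


class TestMergeMeshes:
    def test_far_meshes_counts_add(self, box3):
        other = box3.copy()
        other.points = other.points + 100.0
        out = mk.merge_meshes(box3, other, tolerance=1e-9)
        assert out.n_points == 2 * box3.n_points
        assert out.n_elems == 2 * box3.n_elems
        out.validate()

    def test_interface_round_trip_restores_vertex_count(self, two_label_box):
        s1, _ = mk.extract_submesh(two_label_box, {1})
        s2, _ = mk.extract_submesh(two_label_box, {2})
        out = mk.merge_meshes(s1, s2)  # default tolerance: 1e-6 bbox diag
        assert out.n_points == two_label_box.n_points
        assert out.n_elems == two_label_box.n_elems
        out.validate()

    def test_zero_tolerance_exact_coordinates_only(self, two_label_box):
        s1, _ = mk.extract_submesh(two_label_box, {1})
        s2, _ = mk.extract_submesh(two_label_box, {2})
        exact = mk.merge_meshes(s1, s2, tolerance=0.0)
        assert exact.n_points == two_label_box.n_points  # interface is bit-equal
        jig = s2.copy()
        jig.points = jig.points + 1e-13
        apart = mk.merge_meshes(s1, jig, tolerance=0.0)
        assert apart.n_points == s1.n_points + s2.n_points

    def test_degenerate_unification_rejected(self):
        tri1 = mk.Mesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                       np.array([[0, 1, 2, -1]]), np.array([3]), np.array([1]))
        tri2 = mk.Mesh(np.array([[0.0, 0, 0], [1e-9, 0, 0], [5, 5, 5.0]]),
                       np.array([[0, 1, 2, -1]]), np.array([3]), np.array([2]))
        with pytest.raises(mk.ValidationError, match="degenerate"):
            mk.merge_meshes(tri1, tri2, tolerance=1e-6)

    def test_merge_with_empty_is_identity(self, box3):
        empty = mk.Mesh(np.empty((0, 3)), np.empty((0, 4), dtype=np.int64),
                        np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64))
        out = mk.merge_meshes(box3, empty)
        assert np.array_equal(out.points, box3.points)
        assert np.array_equal(out.conn, box3.conn)
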
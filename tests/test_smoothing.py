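import numpy as np
import pytest

import meshkit as mk
from meshkit import synth


def regular_tet(scale=1.0):
    return scale * np.array([
        [1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])


def oracle_volume_edge_ratio(c):
    """Independent arithmetic oracle for q = 6*sqrt(2)*V / l_rms^3."""
    v = abs(np.linalg.det(np.array([c[1] - c[0], c[2] - c[0], c[3] - c[0]]))) / 6
    ls = [np.linalg.norm(c[i] - c[j]) for i in range(4) for j in range(i + 1, 4)]
    lrms = np.sqrt(np.mean(np.square(ls)))
    return 6 * np.sqrt(2) * v / lrms**3


def oracle_min_dihedral_sine(c):
    """Oracle via face normals: dihedral at edge ij is pi minus the angle
    between the outward normals of the two faces meeting there."""
    import itertools

    if np.linalg.det(np.array([c[1] - c[0], c[2] - c[0], c[3] - c[0]])) < 0:
        c = c[[0, 1, 3, 2]]
    centroid = c.mean(axis=0)
    normals = {}
    for tri in itertools.combinations(range(4), 3):
        p = c[list(tri)]
        n = np.cross(p[1] - p[0], p[2] - p[0])
        n /= np.linalg.norm(n)
        if n @ (p.mean(axis=0) - centroid) < 0:
            n = -n
        normals[tri] = n
    sins = []
    for i, j in itertools.combinations(range(4), 2):
        fa, fb = [f for f in normals if i in f and j in f]
        cosang = np.clip(normals[fa] @ normals[fb], -1, 1)
        theta = np.pi - np.arccos(cosang)
        sins.append(np.sin(theta))
    return min(sins) / np.sin(np.radians(70.528779))


class TestQualityMetrics:
    @pytest.mark.parametrize("scale", [1.0, 0.01, 250.0])
    def test_regular_tet_scores_one(self, scale):
        assert mk.volume_edge_ratio(regular_tet(scale)) == pytest.approx(1.0, abs=1e-12)
        assert mk.min_dihedral_sine(regular_tet(scale)) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_tet_scores_zero(self):
        flat = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        assert mk.volume_edge_ratio(flat) == 0.0
        assert mk.min_dihedral_sine(flat) == 0.0

    def test_right_corner_tet_matches_oracle(self):
        c = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert mk.volume_edge_ratio(c) == pytest.approx(
            oracle_volume_edge_ratio(c), rel=1e-12)

    def test_sliver_scores_tiny(self):
        sliver = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1e-6]])
        assert mk.min_dihedral_sine(sliver) < 1e-3
        assert mk.volume_edge_ratio(sliver) < 1e-3

    def test_random_tets_match_dihedral_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            c = rng.normal(size=(4, 3))
            # the oracle goes through arccos of near-unit dot products, so
            # agreement is limited to ~sqrt(eps)
            assert mk.min_dihedral_sine(c) == pytest.approx(
                oracle_min_dihedral_sine(c), rel=1e-6, abs=1e-9)


class TestQualityReport:
    def test_single_regular_tet(self):
        m = mk.Mesh(regular_tet(), np.array([[0, 1, 2, 3]]),
                    np.array([4]), np.array([0]))
        mk.orient_tets_positive(m)
        rep = mk.quality_report(m)
        assert rep.min == pytest.approx(1.0) and rep.mean == pytest.approx(1.0)

    def test_histogram_sums_to_tet_count(self, shell):
        rep = mk.quality_report(shell, bins=25)
        assert rep.histogram.sum() == int(shell.tet_mask.sum())
        _, tc = shell.tets()
        elementwise = np.array([mk.volume_edge_ratio(shell.points[row])
                                for row in tc[:50]])
        assert np.allclose(rep.per_elem[:50], elementwise)

    def test_triangle_only_mesh_rejected(self, ico4):
        with pytest.raises(mk.MeshError, match="tetrahedra"):
            mk.quality_report(ico4)


class TestSmoothingParams:
    def test_pass_band_condition_enforced(self):
        with pytest.raises(mk.ValidationError):
            mk.SmoothingParams(lambda_step=0.5, mu_step=-0.4)
        with pytest.raises(mk.ValidationError):
            mk.SmoothingParams(lambda_step=1.5)
        mk.SmoothingParams(0.5, -0.53)
        mk.SmoothingParams(0.5, 0.0)  # pure Laplacian comparison mode


class TestTaubinSmooth:
    def test_zero_iterations_is_identity(self, box3):
        lab = mk.decompose_manifolds(box3)
        out = mk.taubin_smooth(box3, lab, mk.SmoothingParams(iterations=0))
        assert np.array_equal(out.points, box3.points)

    def test_flat_box_is_fixed_point(self, box3):
        # planar patches and straight lines are invariant under averaging
        lab = mk.decompose_manifolds(box3)
        out = mk.taubin_smooth(box3, lab, mk.SmoothingParams(iterations=5))
        assert np.allclose(out.points, box3.points, atol=1e-12)

    def test_labeling_mismatch_rejected(self, box3, single_tet):
        lab = mk.decompose_manifolds(single_tet)
        with pytest.raises(mk.ValidationError):
            mk.taubin_smooth(box3, lab, mk.SmoothingParams(iterations=1))

    @pytest.mark.parametrize("n_iter", [10, 50, 200])
    def test_shrinkage_control(self, ico4, n_iter):
        """Two-step low-pass smoothing loses strictly less enclosed volume
        than the same number of pure forward-averaging iterations."""
        noisy = synth.jitter(ico4, 0.02, seed=7)
        lab = mk.decompose_manifolds(noisy, feature_angle_deg=None)
        ref = mk.surface_from_triangles(ico4)
        v0 = mk.enclosed_volume(ref, ico4.points)
        taubin = mk.taubin_smooth(noisy, lab, mk.SmoothingParams(0.5, -0.53, n_iter))
        lap = mk.taubin_smooth(noisy, lab, mk.SmoothingParams(0.5, 0.0, n_iter))
        dv_taubin = abs(mk.enclosed_volume(ref, taubin.points) - v0) / v0
        dv_lap = abs(mk.enclosed_volume(ref, lap.points) - v0) / v0
        assert dv_taubin < dv_lap

    def test_quality_guard_holds_threshold(self):
        m = synth.box_tet_mesh(6, 6, 6, label_planes=[(0, 3.0)])
        lab0 = mk.decompose_manifolds(m)
        jit = synth.jitter(m, 0.25, seed=3, labeling=lab0)
        q0 = mk.quality_report(jit).min
        lab = mk.decompose_manifolds(jit, feature_angle_deg=None)
        out = mk.taubin_smooth(
            jit, lab, mk.SmoothingParams(iterations=30, quality_threshold=0.1))
        q1 = mk.quality_report(out).min
        assert q1 >= min(0.1, q0) - 1e-12

    def test_interface_vertices_stay_near_their_plane(self):
        m = synth.box_tet_mesh(6, 6, 6, label_planes=[(0, 3.0)])
        lab0 = mk.decompose_manifolds(m)
        jit = synth.jitter(m, 0.2, seed=9, labeling=lab0)
        lab = mk.decompose_manifolds(jit, feature_angle_deg=None)
        out = mk.taubin_smooth(jit, lab, mk.SmoothingParams(iterations=50))
        iface = [v for v in range(m.n_points)
                 if lab.vertex_patches[v] == ((1, 2),)
                 and lab.vertex_class[v] == mk.SURFACE]
        assert iface
        before = np.abs(jit.points[iface, 0] - 3.0).max()
        after = np.abs(out.points[iface, 0] - 3.0).max()
        assert after < before  # smoothing flattens the jittered interface


class TestSmoothData:
    def test_constant_field_fixed_point(self, box3):
        g = mk.build_graph(box3)
        f = mk.DataField("node", np.full(box3.n_points, 3.25))
        out = mk.smooth_data(f, g, mk.SmoothingParams(iterations=25))
        assert np.allclose(out.values, 3.25, atol=1e-12)

    def test_noise_variance_decreases(self, box3):
        g = mk.build_graph(box3)
        rng = np.random.default_rng(1)
        f = mk.DataField("node", rng.normal(size=box3.n_points))
        out = mk.smooth_data(f, g, mk.SmoothingParams(iterations=10))
        assert out.values.var() < f.values.var()

    def test_spike_decays_monotonically(self, box3):
        g = mk.build_graph(box3)
        vals = np.zeros(box3.n_points)
        center = int(np.argmin(np.linalg.norm(box3.points - 1.5, axis=1)))
        vals[center] = 1.0
        prev = 1.0
        f = mk.DataField("node", vals)
        for _ in range(5):
            f = mk.smooth_data(f, g, mk.SmoothingParams(iterations=1))
            assert f.values[center] < prev
            prev = f.values[center]

    def test_vector_field_componentwise(self, box3):
        g = mk.build_graph(box3)
        f = mk.DataField("node", np.tile([1.0, -2.0, 0.5], (box3.n_points, 1)))
        out = mk.smooth_data(f, g, mk.SmoothingParams(iterations=5))
        assert np.allclose(out.values, f.values, atol=1e-12)

    def test_element_data_rejected(self, box3):
        g = mk.build_graph(box3)
        f = mk.DataField("element", np.zeros(box3.n_elems))
        with pytest.raises(mk.MeshError):
            mk.smooth_data(f, g, mk.SmoothingParams(iterations=1))
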
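"""Fold extraction, fundus anchoring/skeletonization, and sulcus segmentation."""

import numpy as np
import pytest

from foldscape.io_formats import BACKGROUND, LabelField, ScalarField, TriangleMesh
from foldscape.mesh_graph import build_graph, connected_components, hop_distance_from_set
from foldscape.surface_features import (
    FundusConfig,
    SulcusProtocol,
    connect_points_erosion,
    default_protocol,
    extract_folds,
    extract_fundi,
    extract_label_boundary,
    extract_sulci,
    find_anchor_vertices,
    find_depth_threshold,
    find_outer_endpoints,
    fundus_likelihood,
    segment_by_region,
)
from foldscape.synthetic_fixtures import analytic_depth, gyrified_sheet, labeled_valley


def _strip_mesh(n):
    """A ladder strip whose rail 0..n-1 forms a path of n vertices."""
    coords = []
    for i in range(n):
        coords.append([i, 0.0, 0.0])
    for i in range(n):
        coords.append([i + 0.5, 1.0, 0.0])
    faces = []
    for i in range(n - 1):
        faces += [[i, i + 1, n + i], [i + 1, n + i + 1, n + i]]
    return TriangleMesh(np.array(coords, dtype=float), np.array(faces))


class TestDepthThreshold:
    def test_bimodal_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(10)
        shallow = np.abs(rng.normal(0.5, 0.2, size=5000))
        deep = rng.normal(6.0, 1.0, size=2000)
        depth = ScalarField(np.concatenate([shallow, deep]), name="depth")
        t = find_depth_threshold(depth)
        assert 1.5 < t < 4.5

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        v = np.concatenate([np.abs(rng.normal(0.5, 0.2, 4000)), rng.normal(6, 1, 1500)])
        t0 = find_depth_threshold(ScalarField(v, name="d"))
        t1 = find_depth_threshold(ScalarField(v + 2.5, name="d"))
        bin_width = np.ptp(v) / 100.0
        assert t1 - t0 == pytest.approx(2.5, abs=2 * bin_width)

    def test_two_separated_blocks(self):
        rng = np.random.default_rng(12)
        v = np.concatenate([rng.uniform(0, 1, 3000), rng.uniform(8, 9, 500)])
        t = find_depth_threshold(ScalarField(v, name="d"))
        assert 1.0 < t < 8.0

    def test_constant_depth_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            find_depth_threshold(ScalarField(np.ones(2000), name="d"))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            find_depth_threshold(ScalarField(np.arange(50, dtype=float), name="d"))


class TestExtractFolds:
    def test_two_valleys_two_folds(self, analytic_valley):
        info = gyrified_sheet(nx=60, ny=20, amplitude=10.0, wavelength=5.0, n_valleys=2)
        g = build_graph(info.mesh)
        depth = analytic_depth(info)
        folds = extract_folds(info.mesh, g, depth, threshold=5.0,
                              cfg=FundusConfig(min_fold_size=10))
        assert folds.n_folds == 2
        for k in range(2):
            assert (depth.values[folds.vertices(k)] >= 5.0).all()
            assert len(connected_components(g, folds.vertices(k))) == 1

    def test_fifty_vertex_fold_removed(self, analytic_valley):
        info, graph, _ = analytic_valley
        # paint a synthetic depth patch of exactly 50 connected vertices
        seed = int(info.top_vertices[len(info.top_vertices) // 2])
        dist = hop_distance_from_set(graph, [seed], within=info.top_vertices)
        order = np.lexsort((np.arange(len(dist)), np.where(dist < 0, 10 ** 9, dist)))
        patch50 = order[:50]
        depth = np.zeros(info.mesh.n_vertices)
        depth[patch50] = 10.0
        folds = extract_folds(info.mesh, graph, ScalarField(depth, name="d"), 5.0)
        assert folds.n_folds == 0
        patch51 = order[:51]
        depth[patch51] = 10.0
        folds = extract_folds(info.mesh, graph, ScalarField(depth, name="d"), 5.0)
        assert folds.n_folds == 1

    def test_threshold_above_max_no_folds(self, analytic_valley):
        info, graph, depth = analytic_valley
        folds = extract_folds(info.mesh, graph, depth, depth.values.max() + 1)
        assert folds.n_folds == 0
        assert (folds.fold_ids == BACKGROUND).all()

    def test_folds_numbered_largest_first(self):
        info = gyrified_sheet(nx=60, ny=20, amplitude=10.0, wavelength=5.0, n_valleys=2)
        g = build_graph(info.mesh)
        depth = analytic_depth(info).values
        depth[info.mesh.coordinates[:, 0] > 30] *= 0.65  # shrink second valley
        folds = extract_folds(info.mesh, g, ScalarField(depth, name="d"), 5.0,
                              FundusConfig(min_fold_size=5))
        sizes = [len(folds.vertices(k)) for k in range(folds.n_folds)]
        assert sizes == sorted(sizes, reverse=True)


class TestAnchors:
    def test_hand_computed_median_mad_cutoff(self):
        mesh = _strip_mesh(11)
        g = build_graph(mesh)
        values = np.zeros(mesh.n_vertices)
        values[:11] = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 30]
        # median 6, MAD 3, cutoff 12: only the value-30 vertex qualifies
        anchors = find_anchor_vertices(ScalarField(values, name="v"), range(11), g)
        assert list(anchors) == [10]

    def test_close_pair_keeps_higher_value(self):
        mesh = _strip_mesh(20)
        g = build_graph(mesh)
        values = np.zeros(mesh.n_vertices)
        values[:20] = 1.0
        values[5] = 20.0
        values[10] = 25.0  # 5 edges from the other candidate
        anchors = find_anchor_vertices(ScalarField(values, name="v"), range(20), g)
        assert 10 in anchors and 5 not in anchors

    def test_uniform_values_give_maximal_packing(self):
        mesh = _strip_mesh(40)
        g = build_graph(mesh)
        values = np.zeros(mesh.n_vertices)
        values[:40] = 5.0  # MAD = 0, cutoff = median: all qualify, then packed
        anchors = find_anchor_vertices(ScalarField(values, name="v"), range(40), g)
        assert len(anchors) >= 2
        for i, a in enumerate(anchors):
            for b in anchors[i + 1:]:
                assert abs(a - b) > 10  # path-graph hop distance

    def test_all_zero_values_empty(self):
        mesh = _strip_mesh(12)
        g = build_graph(mesh)
        anchors = find_anchor_vertices(ScalarField(np.zeros(24), name="v"), range(12), g)
        assert len(anchors) == 0


class TestEndpoints:
    def test_elliptical_valley_two_endpoints_near_tips(self, analytic_valley):
        info, graph, depth = analytic_valley
        folds = extract_folds(info.mesh, graph, depth, 3.0)
        assert folds.n_folds == 1
        fold = folds.vertices(0)
        curv = ScalarField(np.ones(info.mesh.n_vertices), name="c")
        like = fundus_likelihood(fold, depth, ScalarField(
            depth.values.copy(), name="c"))
        eps = find_outer_endpoints(fold, graph, like, depth)
        assert len(eps) == 2
        # endpoints sit near the two y-extremes of the valley floor
        floor = info.valley_floor_lines[0]
        y = info.mesh.coordinates[:, 1]
        y_lo, y_hi = y[floor].min(), y[floor].max()
        got = sorted(y[eps])
        assert got[0] <= y_lo + 4.0
        assert got[-1] >= y_hi - 4.0

    def test_endpoints_lie_on_fold_boundary(self, analytic_valley):
        info, graph, depth = analytic_valley
        folds = extract_folds(info.mesh, graph, depth, 3.0)
        fold = folds.vertices(0)
        in_fold = np.zeros(info.mesh.n_vertices, bool)
        in_fold[fold] = True
        like = fundus_likelihood(fold, depth, ScalarField(depth.values.copy(), name="c"))
        eps = find_outer_endpoints(fold, graph, like, depth)
        for e in eps:
            assert in_fold[e]
            assert any(not in_fold[u] for u in graph.neighbors[e])

    def test_fold_covering_closed_mesh_rejected(self, sphere_mesh, sphere_graph):
        v = ScalarField(np.ones(sphere_mesh.n_vertices), name="v")
        with pytest.raises(ValueError, match="boundary"):
            find_outer_endpoints(range(sphere_mesh.n_vertices), sphere_graph, v, v)


class TestErosionSkeleton:
    def test_path_with_protected_ends_survives_whole(self):
        mesh = _strip_mesh(12)
        g = build_graph(mesh)
        fold = list(range(12))  # the bottom rail: a 1-thick path
        values = ScalarField(np.arange(mesh.n_vertices, dtype=float), name="v")
        skel = connect_points_erosion([0], [11], fold, g, values)
        assert list(skel) == fold

    def test_disk_erodes_to_one_thick_curve(self, analytic_valley):
        info, graph, depth = analytic_valley
        folds = extract_folds(info.mesh, graph, depth, 3.0)
        fold = folds.vertices(0)
        like = fundus_likelihood(fold, depth, ScalarField(depth.values.copy(), name="c"))
        anchors = find_anchor_vertices(like, fold, graph)
        eps = find_outer_endpoints(fold, graph, like, depth)
        skel = connect_points_erosion(anchors, eps, fold, graph, like)
        skel_set = set(int(v) for v in skel)
        assert set(int(a) for a in anchors) <= skel_set
        assert set(int(e) for e in eps) <= skel_set
        assert len(connected_components(graph, skel)) == 1
        # 1-vertex thick: no vertex keeps 3+ skeleton neighbors unless its
        # removal is topologically blocked
        from foldscape.mesh_graph import is_simple_point

        for v in skel_set:
            deg = sum(1 for u in graph.neighbors[v] if int(u) in skel_set)
            if deg > 2:
                assert not is_simple_point(graph, skel_set, v)

    def test_no_protected_points_empty(self):
        mesh = _strip_mesh(8)
        g = build_graph(mesh)
        out = connect_points_erosion([], [], range(8), g,
                                     ScalarField(np.zeros(16), name="v"))
        assert len(out) == 0

    def test_erosion_preserves_topology(self, analytic_valley):
        info, graph, depth = analytic_valley
        folds = extract_folds(info.mesh, graph, depth, 3.0)
        fold = folds.vertices(0)
        like = fundus_likelihood(fold, depth, ScalarField(depth.values.copy(), name="c"))
        anchors = find_anchor_vertices(like, fold, graph)
        skel = connect_points_erosion(anchors, [], fold, graph, like)
        assert len(connected_components(graph, skel)) == 1


class TestExtractFundi:
    def test_fundus_hugs_valley_floor(self, analytic_valley):
        info, graph, depth = analytic_valley
        curv = ScalarField(depth.values * 0.1, name="mean_curvature")
        folds = extract_folds(info.mesh, graph, depth, 3.0)
        fundi = extract_fundi(info.mesh, graph, folds, depth, curv)
        fundus = np.flatnonzero(fundi.labels == 0)
        assert len(fundus) >= 5
        floor_dist = hop_distance_from_set(graph, info.valley_floor_lines[0], cutoff=2)
        frac = (floor_dist[fundus] >= 0).mean()
        assert frac >= 0.9

    def test_two_folds_two_fundi(self):
        info = gyrified_sheet(nx=60, ny=24, amplitude=10.0, wavelength=5.0,
                              n_valleys=2, valley_len=16.0)
        g = build_graph(info.mesh)
        depth = analytic_depth(info)
        curv = ScalarField(depth.values * 0.1, name="c")
        folds = extract_folds(info.mesh, g, depth, 3.0, FundusConfig(min_fold_size=20))
        assert folds.n_folds == 2
        fundi = extract_fundi(info.mesh, g, folds, depth, curv)
        ids = set(int(x) for x in np.unique(fundi.labels)) - {BACKGROUND}
        assert ids == {0, 1}
        for k in (0, 1):
            assert set(np.flatnonzero(fundi.labels == k)) <= set(folds.vertices(k))

    def test_flat_fold_no_crash(self, analytic_valley):
        info, graph, _ = analytic_valley
        const = ScalarField(np.where(np.isin(np.arange(info.mesh.n_vertices),
                                             info.top_vertices), 5.0, 0.0), name="d")
        folds = extract_folds(info.mesh, graph, const, 4.0)
        curv = ScalarField(np.zeros(info.mesh.n_vertices), name="c")
        fundi = extract_fundi(info.mesh, graph, folds, const, curv)
        assert len(fundi.labels) == info.mesh.n_vertices  # no exception

    def test_extraction_deterministic(self, analytic_valley):
        info, graph, depth = analytic_valley
        curv = ScalarField(depth.values * 0.1, name="c")
        folds = extract_folds(info.mesh, graph, depth, 3.0)
        a = extract_fundi(info.mesh, graph, folds, depth, curv)
        b = extract_fundi(info.mesh, graph, folds, depth, curv)
        assert np.array_equal(a.labels, b.labels)


class TestLabelBoundary:
    def test_half_labeled_sheet(self):
        info, labels, _ = labeled_valley(nx=21, ny=8)
        g = build_graph(info.mesh)
        boundary = extract_label_boundary(g, labels, (1, 2))
        x = info.mesh.coordinates[:, 0]
        c = info.valley_centers_x[0]
        assert len(boundary) > 0
        assert (np.abs(x[boundary] - c) <= 1.1).all()

    def test_absent_pair_empty(self):
        info, labels, _ = labeled_valley(nx=11, ny=6)
        g = build_graph(info.mesh)
        assert len(extract_label_boundary(g, labels, (7, 9))) == 0

    def test_matches_edge_scan_oracle(self):
        info, labels, _ = labeled_valley(nx=15, ny=8, scheme="three_bands")
        g = build_graph(info.mesh)
        got = set(extract_label_boundary(g, labels, (1, 2)).tolist())
        oracle = set()
        for a, b in info.mesh.edges():
            la, lb = labels.labels[a], labels.labels[b]
            if {la, lb} == {1, 2}:
                oracle |= {int(a), int(b)}
        assert got == oracle

    def test_symmetric_in_pair(self):
        info, labels, _ = labeled_valley(nx=15, ny=8)
        g = build_graph(info.mesh)
        assert np.array_equal(
            extract_label_boundary(g, labels, (1, 2)),
            extract_label_boundary(g, labels, (2, 1)),
        )


class TestExtractSulci:
    def _valley_setup(self, scheme):
        info, labels, proto = labeled_valley(nx=31, ny=16, amplitude=10.0,
                                             wavelength=6.0, scheme=scheme)
        g = build_graph(info.mesh)
        folds = extract_folds(info.mesh, g, analytic_depth(info), 2.0)
        return info, labels, SulcusProtocol(proto), g, folds

    def test_two_banks_whole_fold_one_sulcus(self):
        info, labels, proto, g, folds = self._valley_setup("two_banks")
        assert folds.n_folds == 1
        sulci = extract_sulci(info.mesh, g, folds, labels, proto)
        fold = folds.vertices(0)
        assert (sulci.labels[fold] == 0).all()
        assert (sulci.labels[folds.fold_ids == BACKGROUND] == BACKGROUND).all()

    def test_three_bands_split_by_nearest_boundary(self):
        info, labels, proto, g, folds = self._valley_setup("three_bands")
        sulci = extract_sulci(info.mesh, g, folds, labels, proto)
        present = set(int(s) for s in np.unique(sulci.labels)) - {BACKGROUND}
        assert present == {0, 1}
        # assigned vertices carry a label belonging to their sulcus's pair
        pair_of = {0: {1, 2}, 1: {2, 3}}
        for sid in (0, 1):
            sel = sulci.labels == sid
            assert set(np.unique(labels.labels[sel])) <= pair_of[sid]

    def test_no_protocol_pair_in_fold_all_background(self):
        info, labels, proto, g, folds = self._valley_setup("two_banks")
        other = SulcusProtocol({frozenset({7, 9}): 0})
        sulci = extract_sulci(info.mesh, g, folds, labels, other)
        assert (sulci.labels == BACKGROUND).all()

    def test_empty_protocol_rejected(self):
        info, labels, proto, g, folds = self._valley_setup("two_banks")
        with pytest.raises(ValueError, match="protocol"):
            extract_sulci(info.mesh, g, folds, labels, SulcusProtocol({}))

    def test_sulci_nested_in_folds(self):
        info, labels, proto, g, folds = self._valley_setup("three_bands")
        sulci = extract_sulci(info.mesh, g, folds, labels, proto)
        assert set(np.flatnonzero(sulci.labels >= 0)) <= set(np.flatnonzero(folds.fold_ids >= 0))


class TestSegmentByRegion:
    def test_pointwise_rule(self):
        fundi = LabelField(np.array([0, 0, 0, -1, 1]))
        sulci = LabelField(np.array([3, -1, 4, 4, -1]))
        out = segment_by_region(fundi, sulci)
        assert list(out.labels) == [3, -1, 4, -1, -1]

    def test_fundus_inside_one_sulcus_relabelled(self):
        fundi = LabelField(np.array([0, 0, -1]))
        sulci = LabelField(np.array([5, 5, 5]))
        assert list(segment_by_region(fundi, sulci).labels) == [5, 5, -1]

    def test_fundus_outside_sulci_background(self):
        fundi = LabelField(np.array([0, 0]))
        sulci = LabelField(np.array([-1, -1]))
        assert list(segment_by_region(fundi, sulci).labels) == [-1, -1]


class TestDefaultProtocol:
    def test_62_cortical_labels_31_per_hemisphere(self):
        proto = default_protocol()
        labels = proto.cortical_labels
        assert len(labels) == 62
        assert sum(1 for x in labels if 1000 < x < 2000) == 31
        assert sum(1 for x in labels if 2000 < x < 3000) == 31

    def test_25_sulcus_ids(self):
        proto = default_protocol()
        assert proto.sulcus_ids == list(range(25))

    def test_each_pair_unique_to_one_sulcus(self):
        proto = default_protocol()
        assert len(proto.pairs) == len(set(proto.pairs.keys()))

    def test_round_trip_csv(self, tmp_path):
        proto = default_protocol()
        p = proto.to_csv(tmp_path / "proto.csv")
        again = SulcusProtocol.from_csv(p)
        assert again.pairs == proto.pairs
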
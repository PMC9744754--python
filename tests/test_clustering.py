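"""Connectivity-constrained Ward agglomeration: oracles and invariants."""

import numpy as np
import pytest

from tractcluster.clustering import (
    ConnectivityGraph,
    FeatureTable,
    build_connectivity,
    cluster_regionwise,
    cluster_slicewise,
    cluster_stack,
    normalize_metrics,
    sweep_cluster_counts,
    ward_cluster,
)
from tractcluster.images import MetricStack
from tractcluster.signatures import METRICS


def stack_from(values: np.ndarray, mask=None) -> MetricStack:
    mask = np.isfinite(values) if mask is None else mask
    return MetricStack(channels={m: values.copy() for m in METRICS}, mask=mask)


def full_graph(n: int) -> ConnectivityGraph:
    return ConnectivityGraph(
        neighbors=[set(range(n)) - {i} for i in range(n)],
        scheme="axial8",
        component_labels=np.zeros(n, dtype=np.int64),
        n_components=1,
    )


def features_from(x: np.ndarray) -> FeatureTable:
    x = np.atleast_2d(x.T).T if x.ndim == 1 else x
    n = len(x)
    return FeatureTable(
        values=x.reshape(n, -1).astype(float),
        coords=np.argwhere(np.ones((1, n), bool)),
        metric_names=tuple(f"f{i}" for i in range(x.reshape(n, -1).shape[1])),
        shape=(1, n),
    )


def brute_force_ward(x: np.ndarray, k: int) -> np.ndarray:
    """Oracle: recompute every pairwise Ward cost from scratch per step."""
    clusters = {i: ([i], x[i].astype(float).copy(), 1) for i in range(len(x))}
    while len(clusters) > k:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                _, sa, na = clusters[a]
                _, sb, nb = clusters[b]
                cost = na * nb / (na + nb) * float(np.sum((sa / na - sb / nb) ** 2))
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, a, b)
        _, a, b = best
        ma, sa, na = clusters.pop(a)
        mb, sb, nb = clusters.pop(b)
        clusters[a] = (ma + mb, sa + sb, na + nb)
    labels = np.zeros(len(x), dtype=int)
    for li, cid in enumerate(sorted(clusters)):
        for m in clusters[cid][0]:
            labels[m] = li
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b) == 1.0


class TestNormalize:
    def test_minmax_scaling_arithmetic(self):
        vals = np.array([[2.0, 4.0, 6.0]])
        ft = normalize_metrics(stack_from(vals))
        assert np.allclose(ft.values[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_becomes_zero_with_warning(self):
        vals = np.full((1, 3), 5.0)
        with pytest.warns(UserWarning, match="constant"):
            ft = normalize_metrics(stack_from(vals))
        assert np.all(ft.values == 0)

    def test_columns_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(50, 20, size=(10, 10))
        ft = normalize_metrics(stack_from(vals))
        assert ft.values.min() == 0.0 and ft.values.max() == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_metrics(stack_from(np.ones((2, 2)), mask=np.zeros((2, 2), bool)))


class TestConnectivity:
    def test_2x2_axial4_has_4_edges(self):
        g = build_connectivity(np.ones((2, 2), bool), "axial4")
        assert g.n_edges == 4 and g.n_components == 1

    def test_2x2_axial8_has_6_edges(self):
        g = build_connectivity(np.ones((2, 2), bool), "axial8")
        assert g.n_edges == 6

    def test_two_separated_blobs_report_two_components(self):
        mask = np.zeros((3, 5), bool)
        mask[:, :2] = True
        mask[:, 3:] = True
        g = build_connectivity(mask, "axial4")
        assert g.n_components == 2

    def test_edges_only_inside_mask_symmetric_no_self_loops(self):
        rng = np.random.default_rng(0)
        mask = rng.random((8, 8)) > 0.4
        mask[0, 0] = True
        g = build_connectivity(mask)
        for i, nbrs in enumerate(g.neighbors):
            assert i not in nbrs
            for j in nbrs:
                assert i in g.neighbors[j]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            build_connectivity(np.ones((2, 2), bool), "axial6")


class TestWardCluster:
    def test_n_clusters_equals_pixels_means_no_merges(self):
        ft = features_from(np.arange(5.0))
        parc, dendro = ward_cluster(ft, full_graph(5), 5)
        assert parc.n_clusters == 5 and dendro.merges == []

    def test_identical_features_merge_to_one_at_zero_cost(self):
        ft = features_from(np.zeros(6))
        parc, dendro = ward_cluster(ft, full_graph(6), 1)
        assert parc.n_clusters == 1
        assert all(m.cost == 0.0 for m in dendro.merges)

    def test_step_feature_strip_splits_at_the_step(self):
        ft = features_from(np.array([0.0, 0, 0, 1, 1, 1]))
        chain = ConnectivityGraph(
            neighbors=[{1}, {0, 2}, {1, 3}, {2, 4}, {3, 5}, {4}],
            scheme="axial4",
            component_labels=np.zeros(6, dtype=np.int64),
            n_components=1,
        )
        parc, _ = ward_cluster(ft, chain, 2)
        assert np.array_equal(parc.labels[0], [1, 1, 1, 2, 2, 2])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle_on_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 16))
        x = rng.random((n, int(rng.integers(1, 4))))
        k = int(rng.integers(1, n + 1))
        parc, _ = ward_cluster(features_from(x), full_graph(n), k)
        assert same_partition(parc.labels[0], brute_force_ward(x, k))

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_sklearn_ward_on_fully_connected_graphs(self, trial):
        """Independent cross-check against scikit-learn's implementation."""
        from sklearn.cluster import AgglomerativeClustering

        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(6, 15))
        x = rng.random((n, 3))
        k = int(rng.integers(2, n))
        parc, _ = ward_cluster(features_from(x), full_graph(n), k)
        sk = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
        assert same_partition(parc.labels[0], sk)

    def test_every_merge_joins_adjacent_clusters(self):
        """Replay the dendrogram and verify the connectivity constraint."""
        rng = np.random.default_rng(7)
        mask = rng.random((9, 9)) > 0.25
        vals = rng.random((9, 9))
        vals[~mask] = np.nan
        stack = stack_from(vals, mask)
        ft = normalize_metrics(stack)
        graph = build_connectivity(mask, "axial4")
        _, dendro = ward_cluster(ft, graph, max(graph.n_components, 2))
        members = {i: {i} for i in range(ft.n_pixels)}
        adj = {i: set(graph.neighbors[i]) for i in range(ft.n_pixels)}
        for rec in dendro.merges:
            a, b = rec.cluster_a, rec.cluster_b
            assert adj[a] & members[b] or adj[b] & members[a] or b in adj[a]
            merged = members.pop(a) | members.pop(b)
            members[rec.new_id] = merged
            adj[rec.new_id] = (adj.pop(a) | adj.pop(b)) - merged

    def test_clusters_are_spatially_connected(self):
        rng = np.random.default_rng(11)
        vals = rng.random((12, 12))
        parc, _ = cluster_stack(stack_from(vals), 6)
        from scipy import ndimage

        for c in range(1, parc.n_clusters + 1):
            _, n = ndimage.label(parc.labels == c, structure=ndimage.generate_binary_structure(2, 1))
            assert n == 1

    def test_disconnected_mask_apportions_budget_by_pixel_share(self):
        mask = np.zeros((2, 10), bool)
        mask[:, :6] = True   # component of 12 pixels
        mask[0, 8:] = True   # component of 2 pixels
        vals = np.random.default_rng(0).random((2, 10))
        vals[~mask] = np.nan
        parc, _ = cluster_stack(stack_from(vals, mask), 7)
        labels_big = set(parc.labels[mask & (np.arange(10) < 6)]) - {0}
        labels_small = set(parc.labels[mask & (np.arange(10) >= 8)]) - {0}
        # proportional shares: 7 × 12/14 → 6 clusters, 7 × 2/14 → 1 cluster
        assert len(labels_big) == 6 and len(labels_small) == 1

    def test_more_clusters_than_pixels_rejected(self):
        ft = features_from(np.arange(3.0))
        with pytest.raises(ValueError):
            ward_cluster(ft, full_graph(3), 4)

    def test_deterministic_labels_across_runs(self):
        rng = np.random.default_rng(5)
        vals = rng.random((10, 10))
        a, _ = cluster_stack(stack_from(vals), 5)
        b, _ = cluster_stack(stack_from(vals), 5)
        assert np.array_equal(a.labels, b.labels)


class TestDrivers:
    def _templates(self, spec, signatures, levels):
        from tractcluster.atlas import build_reference_atlas
        from tractcluster.synthetic import sample_subject

        out = {}
        for lv in levels:
            atlas, _ = build_reference_atlas(spec, lv)
            out[lv] = sample_subject(atlas, signatures, 0.3, 0.0, seed=2).stack
        return out

    def test_slicewise_parcellates_each_level_at_requested_count(self, spec32, signatures):
        templates = self._templates(spec32, signatures, ["C1", "C2", "C3"])
        parcs = cluster_slicewise(templates, 8)
        assert set(parcs) == {"C1", "C2", "C3"}
        assert all(p.n_clusters == 8 for p in parcs.values())

    def test_count_sweep_produces_one_result_per_count(self, spec32, signatures):
        templates = self._templates(spec32, signatures, ["C1"])
        results = sweep_cluster_counts(templates["C1"], range(5, 12))
        assert sorted(results) == list(range(5, 12))
        assert all(results[k].n_clusters == k for k in results)

    def test_regionwise_returns_one_parcellation_per_region(self, spec32, signatures):
        stacks = self._templates(spec32, signatures, ["C1", "L1"])
        stacks = {"cervical": stacks["C1"], "lumbar": stacks["L1"]}
        parcs = cluster_regionwise(stacks, 8)
        assert set(parcs) == {"cervical", "lumbar"}

    def test_level_errors_carry_the_level_label(self, spec32, signatures):
        templates = self._templates(spec32, signatures, ["C1"])
        templates["C1"].mask[:] = False
        with pytest.raises(RuntimeError, match="C1"):
            cluster_slicewise(templates, 8)

    def test_two_metric_variant_runs_and_differs(self, spec32, signatures):
        templates = self._templates(spec32, signatures, ["C1"])
        full = cluster_slicewise(templates, 8)["C1"]
        two = cluster_slicewise(
            templates, 8, metrics=("axon_density", "axon_volume_fraction")
        )["C1"]
        assert two.n_clusters == 8
        assert not np.array_equal(full.labels, two.labels)
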
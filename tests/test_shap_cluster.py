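import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from shapstrat.cohort_io import ExpressionMatrix
from shapstrat.shap_cluster import (
    SNNGraph,
    choose_k_eigengap,
    cluster_embedding,
    dynamic_k,
    hierarchical_baseline,
    knn_neighbors,
    pca_reduce,
    snn_similarity,
    spectral_partition,
    subcluster,
    _laplacian_eigen,
)


def _gaussian_clouds(n=300, k=4, sep_radii=3.0, sd=1.0, dim=5, seed=0):
    """Isotropic Gaussian clouds with centers ``sep_radii`` cloud radii apart.

    The radius of an isotropic cloud with per-coordinate sd ``sd`` is
    sd * sqrt(dim); centers sit on a square grid with that spacing, so every
    adjacent pair of clouds is separated by ``sep_radii`` radii.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), n // k)[:n]
    spacing = sep_radii * sd * np.sqrt(dim)
    side = int(np.ceil(np.sqrt(k)))
    centers = np.zeros((k, dim))
    for i in range(k):
        centers[i, 0] = spacing * (i % side)
        centers[i, 1] = spacing * (i // side)
    x = centers[labels] + rng.normal(0, sd, size=(n, dim))
    return x, labels


class TestPcaReduce:
    def test_rank_one_matrix_floored_at_two_components(self, rng):
        x = np.outer(rng.normal(size=20), rng.normal(size=6))
        emb = pca_reduce(x, var_target=0.8)
        assert emb.m == 2
        assert emb.explained_var[0] / emb.explained_var.sum() > 0.999

    def test_scores_are_centered_and_orthogonal(self, rng):
        emb = pca_reduce(rng.normal(size=(40, 10)), var_target=0.9)
        assert np.allclose(emb.scores.mean(axis=0), 0, atol=1e-10)
        gram = emb.scores.T @ emb.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(emb.explained_var) <= 1e-12)

    def test_independent_features_with_known_variance_ratio(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.normal(0, 3, 4000), rng.normal(0, 1, 4000)])
        emb = pca_reduce(x, var_target=1.0)
        ratio = emb.explained_var / emb.explained_var.sum()
        assert ratio[0] == pytest.approx(0.9, abs=0.02)
        assert ratio[1] == pytest.approx(0.1, abs=0.02)

    def test_scaled_mode_equalizes_feature_variance(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.normal(0, 30, 4000), rng.normal(0, 1, 4000)])
        ratio = pca_reduce(x, var_target=1.0, scale=True).explained_var
        assert ratio[0] / ratio.sum() == pytest.approx(0.5, abs=0.03)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_reduce(np.ones((10, 4)))


class TestDynamicK:
    @pytest.mark.parametrize("n,expected", [(298, 15), (88, 5), (6, 5), (2000, 50)])
    def test_clamped_fraction_rule(self, n, expected):
        assert dynamic_k(n) == expected

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            dynamic_k(5)


class TestKnnNeighbors:
    def test_one_dimensional_hand_check(self):
        nbrs = knn_neighbors(np.array([[0.0], [1.0], [10.0]]), k=1)
        assert nbrs.tolist() == [[1], [0], [1]]

    def test_full_k_contains_all_others(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3))
        nbrs = knn_neighbors(x, k=7)
        for i in range(8):
            assert set(nbrs[i]) == set(range(8)) - {i}

    def test_duplicate_points_tie_broken_by_index(self):
        x = np.zeros((4, 2))
        nbrs = knn_neighbors(x, k=2)
        assert nbrs.tolist() == [[1, 2], [0, 2], [0, 1], [0, 1]]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            knn_neighbors(np.zeros((3, 1)), k=3)


class TestSnnSimilarity:
    def test_identical_disjoint_and_partial_overlap(self):
        nbrs = np.array(
            [[1, 2, 3], [4, 5, 6], [3, 4, 5], [1, 2, 6], [1, 2, 3], [2, 3, 6], [0, 1, 2]]
        )
        g = snn_similarity(nbrs, k=3)
        assert g.similarity[0, 4] == 3  # identical lists -> k
        assert g.similarity[0, 1] == 0  # disjoint lists
        assert g.similarity[0, 5] == 2  # {1,2,3} vs {2,3,6} -> 2
        assert np.all(np.diag(g.similarity) == 3)
        assert np.array_equal(g.similarity, g.similarity.T)

    def test_ragged_lists_rejected(self):
        with pytest.raises(ValueError):
            snn_similarity(np.array([[1, 2], [0, 2], [0, 1]]), k=3)


def _block_graph(sizes, k=3, noise=0, seed=0):
    """Dense within-block SNN-like similarity, zero (or noisy) across."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    sim = np.zeros((n, n), dtype=int)
    for b in range(len(sizes)):
        idx = np.flatnonzero(labels == b)
        sim[np.ix_(idx, idx)] = k
    if noise:
        rng = np.random.default_rng(seed)
        for _ in range(noise):
            i, j = rng.integers(0, n, 2)
            if labels[i] != labels[j]:
                sim[i, j] = sim[j, i] = 1
    np.fill_diagonal(sim, k)
    return SNNGraph(similarity=sim, k_used=k), labels


class TestSpectralPartition:
    def test_disconnected_blocks_recovered_exactly(self):
        graph, labels = _block_graph([10, 15])
        assign = spectral_partition(graph, 2, seed=0)
        assert adjusted_rand_score(labels, assign.labels) == 1.0

    def test_single_cluster_trivial(self):
        graph, _ = _block_graph([8])
        assign = spectral_partition(graph, 1, seed=0)
        assert set(assign.labels) == {1}

    def test_labels_ordered_by_descending_size(self):
        graph, labels = _block_graph([5, 20, 10])
        assign = spectral_partition(graph, 3, seed=0)
        sizes = [np.sum(assign.labels == l) for l in [1, 2, 3]]
        assert sizes == sorted(sizes, reverse=True)

    def test_reproducible_and_reorder_invariant(self):
        rng = np.random.default_rng(4)
        x, labels = _gaussian_clouds(n=120, k=3, seed=4)
        k_nn = dynamic_k(120)
        graph = snn_similarity(knn_neighbors(x, k_nn), k_nn)
        a = spectral_partition(graph, 3, seed=7)
        b = spectral_partition(graph, 3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        perm = rng.permutation(120)
        graph_p = SNNGraph(graph.similarity[np.ix_(perm, perm)], graph.k_used)
        c = spectral_partition(graph_p, 3, seed=7)
        assert adjusted_rand_score(a.labels[perm], c.labels) == 1.0

    def test_isolated_vertex_becomes_singleton_with_warning(self):
        graph, _ = _block_graph([6, 6])
        sim = graph.similarity.copy()
        sim[5, :] = 0
        sim[:, 5] = 0
        sim[5, 5] = graph.k_used
        g2 = SNNGraph(sim, graph.k_used)
        with pytest.warns(RuntimeWarning, match="isolated"):
            assign = spectral_partition(g2, 2, seed=0)
        assert np.sum(assign.labels == assign.labels[5]) == 1

    def test_laplacian_eigenvalues_in_valid_range(self, rng):
        x, _ = _gaussian_clouds(n=90, k=3, seed=2)
        graph = snn_similarity(knn_neighbors(x, 5), 5)
        vals, _, _ = _laplacian_eigen(graph.similarity)
        assert vals.min() > -1e-8
        assert vals.max() < 2 + 1e-8


class TestChooseKEigengap:
    @pytest.mark.parametrize("sizes", [[10, 12], [8, 9, 10], [7, 8, 9, 10]])
    def test_disconnected_blocks_give_block_count(self, sizes):
        graph, _ = _block_graph(sizes)
        assert choose_k_eigengap(graph) == len(sizes)

    def test_degenerate_complete_graph_warns_and_returns_minimum(self):
        n, k = 12, 3
        sim = np.full((n, n), k)
        graph = SNNGraph(sim, k)
        with pytest.warns(RuntimeWarning, match="weak"):
            assert choose_k_eigengap(graph) == 2

    def test_noisy_three_block_graph(self):
        graph, _ = _block_graph([15, 18, 12], noise=10, seed=3)
        assert choose_k_eigengap(graph) == 3


class TestSubcluster:
    def test_two_block_target_split_and_locality(self):
        # clusters: one tight cloud + one cloud made of two separated blocks
        rng = np.random.default_rng(8)
        a = rng.normal([0, 0], 0.3, size=(20, 2))
        b1 = rng.normal([8, 0], 0.3, size=(12, 2))
        b2 = rng.normal([8, 6], 0.3, size=(12, 2))
        x = np.vstack([a, b1, b2])
        emb = pca_reduce(x, var_target=1.0)
        assign, _, _ = cluster_embedding(emb, k_clusters=2, seed=0)
        target = assign.labels[25]  # a b1 point's top-level cluster
        before = assign.labels.copy()
        refined = subcluster(assign, int(target), emb, k_sub=2, seed=0)
        assert np.array_equal(refined.labels, before)  # top-level labels unchanged
        sub_paths = [tuple(p) for p in refined.hierarchy_path[20:]]
        assert len(set(sub_paths)) == 2  # the two blocks separated
        other = [tuple(p) for i, p in enumerate(refined.hierarchy_path) if before[i] != target]
        assert all(len(p) == 1 for p in other)

    def test_too_small_cluster_rejected(self):
        x, _ = _gaussian_clouds(n=40, k=2, seed=0)
        emb = pca_reduce(x, var_target=1.0)
        assign, _, _ = cluster_embedding(emb, k_clusters=8, seed=0)
        smallest = min(set(assign.labels), key=lambda l: np.sum(assign.labels == l))
        if np.sum(assign.labels == smallest) >= 6:
            pytest.skip("no small enough cluster emerged")
        with pytest.raises(ValueError, match="too small"):
            subcluster(assign, int(smallest), emb, k_sub=3, seed=0)


class TestPlantedPartitionRecovery:
    def test_four_gaussian_clouds_via_full_stack(self):
        x, labels = _gaussian_clouds(n=300, k=4, sep_radii=3.0, seed=1)
        k_nn = dynamic_k(300)
        graph = snn_similarity(knn_neighbors(x, k_nn), k_nn)
        assign = spectral_partition(graph, 4, seed=1)
        assert adjusted_rand_score(labels, assign.labels) >= 0.9


class TestHierarchicalBaseline:
    def test_perfectly_anticorrelated_groups_separate(self):
        t = np.linspace(0, 1, 10)
        profiles = np.vstack([t, 2 * t + 1, -t, -3 * t + 5])  # samples x genes
        expr = ExpressionMatrix(profiles.T, [f"g{i}" for i in range(10)],
                                ["a1", "a2", "b1", "b2"])
        assign = hierarchical_baseline(expr, k=2)
        assert assign.labels[0] == assign.labels[1]
        assert assign.labels[2] == assign.labels[3]
        assert assign.labels[0] != assign.labels[2]

    def test_k_equal_n_gives_singletons(self, rng):
        expr = ExpressionMatrix(rng.normal(size=(10, 5)), [f"g{i}" for i in range(10)],
                                [f"s{i}" for i in range(5)])
        assign = hierarchical_baseline(expr, k=5)
        assert len(set(assign.labels)) == 5

    def test_hand_traced_five_sample_dendrogram(self):
        # A,B identical (d=0); C correlates 0.5 with A/B; D,E identical and
        # anti-correlated with A (d=2): cutting at k=2 gives {A,B,C} | {D,E},
        # at k=3 it must peel C off first (complete-linkage d(AB,C)=0.5 < 2)
        base = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, 3.0, 2.0, 4.0])  # r = 0.6 with base
        profiles = np.vstack([base, 2 * base, c, -base, 1 - base])
        expr = ExpressionMatrix(profiles.T, [f"g{i}" for i in range(4)],
                                list("ABCDE"))
        k2 = hierarchical_baseline(expr, k=2).labels
        assert k2[0] == k2[1] == k2[2] and k2[3] == k2[4] and k2[0] != k2[3]
        k3 = hierarchical_baseline(expr, k=3).labels
        assert k3[0] == k3[1] and k3[3] == k3[4]
        assert len({k3[0], k3[2], k3[3]}) == 3

    def test_zero_variance_sample_rejected_by_name(self):
        profiles = np.vstack([np.ones(4), np.arange(4.0)])
        expr = ExpressionMatrix(profiles.T, [f"g{i}" for i in range(4)], ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hierarchical_baseline(expr, k=2)

    def test_kmeans_variant_recovers_separated_groups(self):
        x, labels = _gaussian_clouds(n=60, k=2, sep_radii=6.0, seed=5)
        expr = ExpressionMatrix(x.T, [f"g{i}" for i in range(x.shape[1])],
                                [f"s{i}" for i in range(60)])
        assign = hierarchical_baseline(expr, k=2, method="kmeans", seed=0)
        assert adjusted_rand_score(labels, assign.labels) == 1.0
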
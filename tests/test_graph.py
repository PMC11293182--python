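import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.neighbors import NearestNeighbors

from aknno.preprocess import EmbeddingMatrix
from aknno.graph import (
    AdaptiveGraphConfig,
    adaptive_k,
    build_adaptive_graph,
    build_fixed_graph,
    compute_neighbor_table,
    cutoff_distance,
    snn_jaccard,
)


def embedding_from(coords):
    coords = np.asarray(coords, dtype=float)
    return EmbeddingMatrix(
        coords=coords, cell_ids=np.array([f"c{i}" for i in range(len(coords))])
    )


class TestNeighborTable:
    def test_three_point_line(self):
        emb = embedding_from([[0, 0], [1, 0], [3, 0]])
        table = compute_neighbor_table(emb, K_max=2)
        assert list(table.indices[0]) == [1, 2]
        np.testing.assert_allclose(table.distances[0], [1, 3])
        assert list(table.indices[1]) == [0, 2]
        np.testing.assert_allclose(table.distances[1], [1, 2])

    def test_self_never_a_neighbor(self):
        rng = np.random.default_rng(0)
        emb = embedding_from(rng.normal(size=(50, 4)))
        table = compute_neighbor_table(emb, 10)
        assert not np.any(table.indices == np.arange(50)[:, None])

    def test_duplicate_points_zero_distance_first(self):
        emb = embedding_from([[1, 1], [1, 1], [5, 5], [7, 7]])
        table = compute_neighbor_table(emb, 2)
        assert table.indices[0, 0] == 1 and table.distances[0, 0] == 0.0
        assert table.indices[1, 0] == 0 and table.distances[1, 0] == 0.0

    def test_tie_break_by_smaller_index(self):
        # cells 1 and 2 are equidistant from cell 0
        emb = embedding_from([[0, 0], [2, 0], [-2, 0], [0, 9]])
        table = compute_neighbor_table(emb, 3)
        assert list(table.indices[0]) == [1, 2, 3]

    def test_agrees_with_sklearn_exact_search(self):
        rng = np.random.default_rng(1)
        emb = embedding_from(rng.normal(size=(300, 8)))
        table = compute_neighbor_table(emb, 15)
        nn = NearestNeighbors(n_neighbors=16, algorithm="brute").fit(emb.coords)
        dist, idx = nn.kneighbors(emb.coords)
        np.testing.assert_allclose(table.distances, dist[:, 1:], atol=1e-10)
        assert np.array_equal(table.indices, idx[:, 1:])

    def test_k_max_too_large_raises(self):
        emb = embedding_from(np.eye(4))
        with pytest.raises(ValueError, match="K_max"):
            compute_neighbor_table(emb, 4)


class TestCutoffAndAdaptiveK:
    # closed form: (sum sqrt(d) / (K_max - 1 - delta))^2
    @pytest.mark.parametrize(
        "distances,delta,expected",
        [
            ([4.0] * 10, -1.0, 4.0),  # (20/10)^2
            ([4.0] * 10, 0.0, (20 / 9) ** 2),
            ([1.0] * 5 + [9.0] * 5, -0.5, (20 / 9.5) ** 2),
            ([0.0] * 8, -0.5, 0.0),
        ],
    )
    def test_closed_form_hand_values(self, distances, delta, expected):
        assert cutoff_distance(distances, delta) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "distances,delta,expected_k",
        [
            # tight 5-neighborhood then a jump: small k chosen for a rare cell
            ([1.0] * 5 + [9.0] * 5, -0.5, 5),
            # slowly growing distances of an abundant cell: k = K_max
            ([4.0] * 10, 0.0, 10),
            # cutoff below the nearest neighbor: floored at k = 1
            ([4.0] * 10, -2.0, 1),
        ],
    )
    def test_piecewise_rule(self, distances, delta, expected_k):
        assert adaptive_k(distances, delta) == expected_k

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            cutoff_distance([-1.0, 2.0], -0.5)

    def test_positive_delta_raises(self):
        with pytest.raises(ValueError, match="delta"):
            cutoff_distance([1.0, 2.0], 0.5)

    def test_cutoff_increasing_in_delta(self):
        rng = np.random.default_rng(2)
        d = np.sort(rng.exponential(size=12))
        cuts = [cutoff_distance(d, delta) for delta in (-3.0, -1.5, -0.5, 0.0)]
        assert np.all(np.diff(cuts) > 0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=40),
        st.floats(-5.0, 0.0),
    )
    def test_matches_brute_force_count(self, distances, delta):
        d = np.sort(np.asarray(distances))
        cut = (np.sqrt(d).sum() / (len(d) - 1 - delta)) ** 2
        expected = int(np.clip((d < cut).sum(), 1, len(d)))
        assert adaptive_k(d, delta) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0.01, 50.0), min_size=3, max_size=30),
        st.floats(-4.0, -0.1),
        st.floats(0.0, 3.0),
    )
    def test_k_monotone_in_delta(self, distances, delta, step):
        d = np.sort(np.asarray(distances))
        assert adaptive_k(d, delta) <= adaptive_k(d, min(delta + step, 0.0))


class TestAdaptiveGraph:
    def test_rare_cluster_keeps_only_internal_edges(self):
        # 6-cell tight cluster far from a 400-cell mass
        rng = np.random.default_rng(3)
        mass = rng.normal(0, 1, size=(400, 2))
        tight = rng.normal(50, 0.05, size=(6, 2))
        emb = embedding_from(np.vstack([mass, tight]))
        table = compute_neighbor_table(emb, 10)
        g = build_adaptive_graph(table, AdaptiveGraphConfig(K_max=10))
        rare = np.arange(400, 406)
        for i in rare:
            assert g.k_per_cell[i] <= 5
            assert set(g.adjacency[i].indices) <= set(rare)

    def test_uniform_distances_keep_k_max_at_delta_zero(self):
        # near-uniform local distances -> cutoff above d_Kmax -> k = K_max
        rng = np.random.default_rng(4)
        emb = embedding_from(rng.normal(size=(100, 3)))
        table = compute_neighbor_table(emb, 8)
        d = np.full((100, 8), 4.0) + rng.uniform(0, 1e-6, (100, 8))
        table.distances = np.sort(d, axis=1)
        g = build_adaptive_graph(table, AdaptiveGraphConfig(K_max=8, delta=0.0))
        assert np.all(g.k_per_cell == 8)

    def test_out_degree_equals_k_per_cell(self):
        rng = np.random.default_rng(5)
        emb = embedding_from(rng.normal(size=(80, 4)))
        table = compute_neighbor_table(emb, 12)
        g = build_adaptive_graph(table, AdaptiveGraphConfig(K_max=12))
        out_deg = np.asarray(g.adjacency.sum(axis=1)).ravel()
        assert np.array_equal(out_deg, g.k_per_cell)

    def test_config_k_max_mismatch_raises(self):
        emb = embedding_from(np.random.default_rng(6).normal(size=(20, 2)))
        table = compute_neighbor_table(emb, 5)
        with pytest.raises(ValueError, match="K_max"):
            build_adaptive_graph(table, AdaptiveGraphConfig(K_max=10))


class TestFixedGraph:
    def test_k_equals_k_max_keeps_full_table(self):
        rng = np.random.default_rng(7)
        emb = embedding_from(rng.normal(size=(30, 3)))
        table = compute_neighbor_table(emb, 6)
        g = build_fixed_graph(table, 6)
        assert g.adjacency.nnz == 30 * 6

    def test_k_one_keeps_single_nearest(self):
        emb = embedding_from([[0, 0], [1, 0], [5, 0]])
        table = compute_neighbor_table(emb, 2)
        g = build_fixed_graph(table, 1)
        assert list(g.adjacency[0].indices) == [1]
        assert list(g.adjacency[2].indices) == [1]

    def test_fixed_superset_of_adaptive_at_max_k(self):
        rng = np.random.default_rng(8)
        emb = embedding_from(rng.normal(size=(120, 4)))
        table = compute_neighbor_table(emb, 10)
        adaptive = build_adaptive_graph(table, AdaptiveGraphConfig(K_max=10))
        fixed = build_fixed_graph(table, int(adaptive.k_per_cell.max()))
        diff = adaptive.adjacency - adaptive.adjacency.multiply(
            fixed.adjacency.astype(bool)
        )
        assert diff.nnz == 0

    def test_k_above_k_max_raises(self):
        emb = embedding_from(np.random.default_rng(9).normal(size=(10, 2)))
        table = compute_neighbor_table(emb, 4)
        with pytest.raises(ValueError, match="exceeds"):
            build_fixed_graph(table, 5)


class TestSnnJaccard:
    def brute_force_snn(self, graph, prune):
        n = graph.n_cells
        sets = [set(graph.adjacency[i].indices) | {i} for i in range(n)]
        weights = np.zeros((n, n))
        directed = graph.adjacency.toarray() > 0
        for i in range(n):
            for j in range(n):
                if i != j and (directed[i, j] or directed[j, i]):
                    w = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
                    if w > prune:
                        weights[i, j] = w
        return weights

    def test_hand_examples(self):
        # N(i)={i,a,b}, N(j)={j,a,b} -> 2/4; N(i)={i,a}, N(j)={j,a} -> 1/3
        assert len({0, 1, 2} & {3, 1, 2}) / len({0, 1, 2} | {3, 1, 2}) == 0.5
        import scipy.sparse as sp
        from aknno.graph import AdaptiveKNNGraph

        adj = sp.csr_matrix(
            np.array(
                [  # 0 and 3 both point to {1, 2}; also 0 -> 3 to connect them
                    [0, 1, 1, 1],
                    [0, 0, 1, 1],
                    [0, 1, 0, 1],
                    [0, 1, 1, 0],
                ]
            )
        )
        g = AdaptiveKNNGraph(adjacency=adj, k_per_cell=np.array([3, 2, 2, 2]))
        snn = snn_jaccard(g, prune=0.0)
        # N(0)={0,1,2,3}, N(3)={1,2,3}: intersection 3, union 4
        assert snn.weights[0, 3] == pytest.approx(3 / 4)

    @pytest.mark.parametrize("n,k_max,prune", [(60, 6, 0.0), (200, 12, 1 / 15)])
    def test_matches_brute_force_sets(self, n, k_max, prune):
        rng = np.random.default_rng(n)
        emb = embedding_from(rng.normal(size=(n, 3)))
        table = compute_neighbor_table(emb, k_max)
        g = build_adaptive_graph(table, AdaptiveGraphConfig(K_max=k_max))
        snn = snn_jaccard(g, prune)
        np.testing.assert_allclose(
            snn.weights.toarray(), self.brute_force_snn(g, prune), atol=1e-12
        )

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(11)
        emb = embedding_from(rng.normal(size=(150, 4)))
        table = compute_neighbor_table(emb, 10)
        snn = snn_jaccard(build_adaptive_graph(table, AdaptiveGraphConfig(K_max=10)))
        W = snn.weights
        assert (W - W.T).nnz == 0
        assert W.diagonal().sum() == 0
        assert np.all(W.data > 1 / 15) and np.all(W.data <= 1.0)

    def test_prune_boundary_exact(self):
        # construct a pair whose Jaccard weight is exactly 1/15: |I|=1, |U|=15
        import scipy.sparse as sp
        from aknno.graph import AdaptiveKNNGraph

        n = 16
        adj = np.zeros((n, n), dtype=np.int8)
        adj[0, 1:8] = 1  # N(0) = {0..7}, size 8
        adj[8, list(range(1, 2)) + list(range(9, 15))] = 1  # N(8)={8,1,9..14}, 8
        # intersection {1}; union size 15 -> weight exactly 1/15, pruned (<=)
        g = AdaptiveKNNGraph(
            adjacency=sp.csr_matrix(adj), k_per_cell=adj.sum(1).astype(np.int64)
        )
        adj2 = adj.copy()
        adj2[0, 8] = 1  # connect the pair so it is a candidate edge
        g = AdaptiveKNNGraph(
            adjacency=sp.csr_matrix(adj2), k_per_cell=adj2.sum(1).astype(np.int64)
        )
        # N(0)={0..8} size 9, N(8)={8,1,9..14} size 8: |I|={1,8}=2, |U|=15
        snn = snn_jaccard(g, prune=2 / 15)
        assert snn.weights[0, 8] == 0.0  # weight == prune -> removed
        snn = snn_jaccard(g, prune=2 / 15 - 1e-12)
        assert snn.weights[0, 8] == pytest.approx(2 / 15)
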
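import numpy as np
import pytest

from circdis import (
    GCNConfig,
    WalkConfig,
    embed_walks,
    gcn_embed,
    node2vec_embed,
    normalize_adjacency,
    simulate_walks,
    transition_probability,
)
from circdis.data_io import HeterogeneousAdjacency
from circdis.features import NodeFeatureMatrix
from circdis.similarity import build_heterogeneous_adjacency


def _hetero(A_vals):
    """Wrap a binary circRNA x disease block into a HeterogeneousAdjacency."""
    from circdis import AssociationMatrix

    A_vals = np.asarray(A_vals)
    A = AssociationMatrix(
        A_vals,
        [f"c{i}" for i in range(A_vals.shape[0])],
        [f"d{j}" for j in range(A_vals.shape[1])],
    )
    return build_heterogeneous_adjacency(A)


class TestNormalizeAdjacency:
    def test_edgeless_graph_gives_identity(self):
        assert np.allclose(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_single_edge_pair_all_half(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_adjacency(adj), 0.5)

    def test_symmetric_with_bounded_spectrum(self, small_dataset):
        A, _ = small_dataset
        N = normalize_adjacency(build_heterogeneous_adjacency(A))
        assert np.allclose(N, N.T)
        eigs = np.linalg.eigvalsh(N)
        assert np.abs(eigs).max() <= 1 + 1e-9


class TestGcnEmbed:
    def test_outputs_nonnegative_and_shaped(self, small_dataset):
        A, _ = small_dataset
        X = build_heterogeneous_adjacency(A)
        nm = len(X.node_ids)
        Q = NodeFeatureMatrix(
            np.random.default_rng(0).random((nm, 6)), list(X.node_ids), A.n_circ
        )
        H = gcn_embed(X, Q, GCNConfig(depth=2, weight_init_seed=4))
        assert H.values.shape == (nm, 6)
        assert (H.values >= 0).all()

    def test_seeded_determinism(self, small_dataset):
        A, _ = small_dataset
        X = build_heterogeneous_adjacency(A)
        nm = len(X.node_ids)
        Q = NodeFeatureMatrix(
            np.random.default_rng(1).random((nm, 4)), list(X.node_ids), A.n_circ
        )
        cfg = GCNConfig(depth=2, weight_init_seed=9)
        assert np.array_equal(gcn_embed(X, Q, cfg).values, gcn_embed(X, Q, cfg).values)

    def test_shape_mismatch_errors(self):
        X = _hetero([[1, 0], [0, 1]])
        Q = NodeFeatureMatrix(np.zeros((3, 2)), ["a", "b", "c"], 2)
        with pytest.raises(ValueError):
            gcn_embed(X, Q, GCNConfig())


class TestTransitionProbability:
    def test_alpha_ratios_at_paper_defaults(self):
        # v's neighbours: t (distance 0), a common neighbour of t (distance
        # 1) and a far node (distance 2); with p=1, q=0.25 the unnormalised
        # weights are 1 : 1 : 4
        adj = np.zeros((4, 4))
        for u, w in [(0, 1), (1, 2), (0, 2), (1, 3)]:
            adj[u, w] = adj[w, u] = 1.0
        probs = [transition_probability(adj, 0, 1, x, p=1.0, q=0.25) for x in (0, 2, 3)]
        assert probs == pytest.approx([1 / 6, 1 / 6, 4 / 6], abs=1e-12)

    def test_triangle_uniform_when_unbiased(self):
        adj = 1.0 - np.eye(3)
        for x in (0, 2):
            assert transition_probability(adj, 0, 1, x, 1.0, 1.0) == pytest.approx(0.5)

    def test_probabilities_normalise(self):
        rng = np.random.default_rng(0)
        adj = (rng.random((6, 6)) < 0.5).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        t, v = next(
            (t, v) for t in range(6) for v in range(6) if adj[t, v] > 0
        )
        total = sum(
            transition_probability(adj, t, v, x, 2.0, 0.5) for x in range(6)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_non_edge_arrival_errors(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        adj3 = np.zeros((3, 3))
        adj3[:2, :2] = adj
        with pytest.raises(ValueError):
            transition_probability(adj3, 2, 0, 1, 1.0, 1.0)


class TestSimulateWalks:
    def test_single_edge_graph_alternates(self):
        X = _hetero([[1]])
        walks = simulate_walks(X, WalkConfig(walk_length=10, num_walks=2, seed=0))
        for walk in walks:
            assert all(a != b for a, b in zip(walk, walk[1:]))
            assert set(walk) <= {0, 1}

    def test_seeded_determinism(self, small_dataset):
        A, _ = small_dataset
        X = build_heterogeneous_adjacency(A)
        cfg = WalkConfig(walk_length=20, num_walks=2, seed=3)
        assert simulate_walks(X, cfg) == simulate_walks(X, cfg)

    def test_isolated_nodes_start_no_walks(self):
        X = _hetero([[1, 0], [0, 0]])  # c2 is isolated
        walks = simulate_walks(X, WalkConfig(walk_length=5, num_walks=3, seed=0))
        assert all(w[0] != 1 for w in walks)

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            simulate_walks(np.zeros((3, 3)), WalkConfig())


class TestEmbedWalks:
    def test_finite_vectors_and_isolated_zero_rows(self):
        X = _hetero([[1, 0], [0, 0]])
        walks = simulate_walks(X, WalkConfig(walk_length=20, num_walks=5, seed=1))
        H = embed_walks(walks, list(X.node_ids), k=4, epochs=2, seed=1)
        assert np.isfinite(H.values).all()
        assert np.array_equal(H.values[1], np.zeros(4))  # isolated circRNA c2
        assert np.any(H.values[0] != 0)

    def test_invalid_width_errors(self):
        with pytest.raises(ValueError):
            embed_walks([[0, 1, 0]], ["a", "b"], k=0)

    def test_two_clique_structure_separates(self):
        # two 5-cliques joined by a single bridge edge
        adj = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        adj[i, j] = 1.0
        adj[4, 5] = adj[5, 4] = 1.0
        walks = simulate_walks(
            adj, WalkConfig(walk_length=40, num_walks=10, seed=7)
        )
        H = embed_walks(walks, [str(i) for i in range(10)], k=8, epochs=5, seed=7)
        V = H.values / np.linalg.norm(H.values, axis=1, keepdims=True)
        cos = V @ V.T
        within, between = [], []
        for i in range(10):
            for j in range(i + 1, 10):
                (within if (i < 5) == (j < 5) else between).append(cos[i, j])
        assert np.mean(within) > np.mean(between)


def test_node2vec_embed_deterministic(small_dataset):
    A, _ = small_dataset
    X = build_heterogeneous_adjacency(A)
    cfg = WalkConfig(walk_length=20, num_walks=3, seed=5)
    H1 = node2vec_embed(X, cfg, k=6)
    H2 = node2vec_embed(X, cfg, k=6)
    assert np.array_equal(H1.values, H2.values)
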
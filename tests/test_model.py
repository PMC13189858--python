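"""Directed autoencoder: normalisation, layer math, encoder, decoder, training."""

import numpy as np
import pytest

from ccinet.graph import CellGraph, EdgeSplit, SpatialDataset, split_edges
from ccinet.metrics import evaluate_split
from ccinet.model import (
    DigaeModel,
    decode,
    directed_layer,
    hetero_directed_layer,
    normalize_adjacency,
    predict_interactions,
    reconstruction_loss,
    train,
    _forward,
    _init_weights,
)
from ccinet.synthetic import SyntheticConfig, generate_dataset


def _dense_normalize_oracle(graph, alpha, beta, self_loops=True):
    """Independent dense-matrix computation of (D+)^-b A~ (D-)^-a."""
    A = graph.adjacency().toarray()
    if self_loops:
        A = A + np.eye(graph.n_nodes)
    d_out = A.sum(axis=1)
    d_in = A.sum(axis=0)
    s_out = np.where(d_out > 0, d_out ** -beta, 1.0)
    s_in = np.where(d_in > 0, d_in ** -alpha, 1.0)
    return s_out[:, None] * A * s_in[None, :]


class TestNormalize:
    def test_alpha_beta_zero_is_augmented_adjacency(self):
        g = CellGraph.from_contacts(4, np.array([[0, 1], [1, 2]]))
        Ahat = normalize_adjacency(g, alpha=0.0, beta=0.0)
        np.testing.assert_array_equal(Ahat.toarray(),
                                      g.augmented_adjacency().toarray())

    def test_empty_graph_with_self_loops_is_identity(self):
        g = CellGraph(n_nodes=3, edges=np.empty((0, 2), dtype=np.int64))
        Ahat = normalize_adjacency(g, alpha=0.7, beta=0.3)
        np.testing.assert_allclose(Ahat.toarray(), np.eye(3))

    def test_two_node_hand_computation(self):
        # single directed edge 0->1, self loops on, alpha = beta = 0.5:
        # A~ = [[1,1],[0,1]], D+ = diag(2,1), D- = diag(1,2)
        g = CellGraph(n_nodes=2, edges=np.array([[0, 1]]))
        Ahat = normalize_adjacency(g, alpha=0.5, beta=0.5).toarray()
        expected = np.array([[2 ** -0.5, 2 ** -0.5 * 2 ** -0.5],
                             [0.0, 2 ** -0.5]])
        np.testing.assert_allclose(Ahat, expected, atol=1e-12)
        np.testing.assert_allclose(Ahat, [[0.7071, 0.5], [0.0, 0.7071]],
                                   atol=5e-5)

    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.5), (1.0, 0.0), (0.3, 0.8)])
    def test_matches_dense_oracle(self, alpha, beta):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = int(rng.integers(2, 9))
            pairs = rng.integers(0, n, size=(n, 2))
            pairs = np.unique(pairs[pairs[:, 0] != pairs[:, 1]], axis=0)
            g = CellGraph(n_nodes=n, edges=pairs)
            got = normalize_adjacency(g, alpha, beta).toarray()
            np.testing.assert_allclose(
                got, _dense_normalize_oracle(g, alpha, beta), atol=1e-12)


def _layer_oracle(Ahat_dense, S, T, W_S_of, W_T_of, activation=None):
    """Per-node loop reference for directed message passing.

    ``W_S_of(j)``/``W_T_of(j)`` give the weight matrix applied to node j's
    embedding row before aggregation.
    """
    n = len(S)
    act = activation or (lambda x: x)
    S_next = np.zeros((n, W_T_of(0).shape[1]))
    T_next = np.zeros((n, W_S_of(0).shape[1]))
    for i in range(n):
        for j in range(n):
            S_next[i] += Ahat_dense[i, j] * (T[j] @ W_T_of(j))
            T_next[i] += Ahat_dense[j, i] * (S[j] @ W_S_of(j))
    return act(S_next), act(T_next)


class TestLayers:
    def test_identity_adjacency_swaps_channels(self):
        g = CellGraph(n_nodes=3, edges=np.empty((0, 2), dtype=np.int64))
        Ahat = normalize_adjacency(g)  # identity
        rng = np.random.default_rng(1)
        S, T = rng.random((3, 2)), rng.random((3, 2))
        I = np.eye(2)
        S_next, T_next = directed_layer(Ahat, S, T, I, I)
        np.testing.assert_allclose(S_next, T)
        np.testing.assert_allclose(T_next, S)

    def test_zero_receiver_embeddings(self):
        g = CellGraph(n_nodes=3, edges=np.array([[0, 1], [1, 0]]))
        Ahat = normalize_adjacency(g)
        S = np.ones((3, 2))
        S_next, _ = directed_layer(Ahat, S, np.zeros((3, 2)), np.eye(2),
                                   np.eye(2), activation=np.tanh)
        np.testing.assert_allclose(S_next, 0.0)

    def test_homogeneous_layer_matches_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, din, dout = 4, 3, 2
            pairs = rng.integers(0, n, size=(6, 2))
            pairs = np.unique(pairs[pairs[:, 0] != pairs[:, 1]], axis=0)
            g = CellGraph(n_nodes=n, edges=pairs)
            Ahat = normalize_adjacency(g)
            S, T = rng.normal(size=(n, din)), rng.normal(size=(n, din))
            W_S, W_T = rng.normal(size=(din, dout)), rng.normal(size=(din, dout))
            S_next, T_next = directed_layer(Ahat, S, T, W_S, W_T,
                                            activation=np.tanh)
            Se, Te = _layer_oracle(Ahat.toarray(), S, T,
                                   lambda j: W_S, lambda j: W_T, np.tanh)
            np.testing.assert_allclose(S_next, Se, atol=1e-10)
            np.testing.assert_allclose(T_next, Te, atol=1e-10)

    def test_hetero_layer_matches_oracle(self):
        rng = np.random.default_rng(3)
        n, din, dout, K = 4, 3, 2, 2
        pairs = np.array([[0, 1], [1, 0], [1, 2], [2, 3], [3, 0]])
        g = CellGraph(n_nodes=n, edges=pairs)
        Ahat = normalize_adjacency(g)
        types = np.array([0, 1, 0, 1])
        S, T = rng.normal(size=(n, din)), rng.normal(size=(n, din))
        W_S = rng.normal(size=(K, din, dout))
        W_T = rng.normal(size=(K, din, dout))
        S_next, T_next = hetero_directed_layer(Ahat, S, T, types, W_S, W_T)
        Se, Te = _layer_oracle(Ahat.toarray(), S, T,
                               lambda j: W_S[types[j]],
                               lambda j: W_T[types[j]])
        np.testing.assert_allclose(S_next, Se, atol=1e-10)
        np.testing.assert_allclose(T_next, Te, atol=1e-10)

    def test_hetero_single_type_reduces_to_homogeneous(self):
        rng = np.random.default_rng(4)
        n, d = 5, 3
        pairs = np.array([[0, 1], [1, 2], [2, 0], [3, 4]])
        g = CellGraph(n_nodes=n, edges=pairs)
        Ahat = normalize_adjacency(g)
        S, T = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        W_S, W_T = rng.normal(size=(d, d)), rng.normal(size=(d, d))
        hS, hT = directed_layer(Ahat, S, T, W_S, W_T)
        eS, eT = hetero_directed_layer(Ahat, S, T, np.zeros(n, dtype=int),
                                       W_S[None], W_T[None])
        np.testing.assert_array_equal(hS, eS)  # bitwise
        np.testing.assert_array_equal(hT, eT)

    def test_hetero_equal_weights_equals_homogeneous(self):
        rng = np.random.default_rng(5)
        n, d = 4, 2
        g = CellGraph(n_nodes=n, edges=np.array([[0, 1], [1, 2], [2, 3]]))
        Ahat = normalize_adjacency(g)
        S, T = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        W_S, W_T = rng.normal(size=(d, d)), rng.normal(size=(d, d))
        types = np.array([0, 1, 1, 0])
        eS, eT = hetero_directed_layer(Ahat, S, T, types,
                                       np.stack([W_S, W_S]),
                                       np.stack([W_T, W_T]))
        hS, hT = directed_layer(Ahat, S, T, W_S, W_T)
        np.testing.assert_allclose(eS, hS, atol=1e-12)
        np.testing.assert_allclose(eT, hT, atol=1e-12)

    def test_missing_type_weights_raises(self):
        g = CellGraph(n_nodes=2, edges=np.array([[0, 1]]))
        Ahat = normalize_adjacency(g)
        with pytest.raises(KeyError):
            hetero_directed_layer(Ahat, np.ones((2, 2)), np.ones((2, 2)),
                                  np.array([0, 3]), np.ones((2, 2, 2)),
                                  np.ones((2, 2, 2)))


class TestEncoder:
    def test_zero_weights_give_zero_codes(self):
        g = CellGraph(n_nodes=3, edges=np.array([[0, 1], [1, 0]]))
        Ahat = normalize_adjacency(g)
        X = np.random.default_rng(0).random((3, 4))
        W = {k: np.zeros((1, 4, 2)) if k.endswith("0") else np.zeros((1, 2, 2))
             for k in ("W_S0", "W_T0", "W_S1", "W_T1")}
        Z_S, Z_T, _ = _forward(Ahat, X, X, W, np.zeros(3, dtype=int))
        np.testing.assert_array_equal(Z_S, 0.0)
        np.testing.assert_array_equal(Z_T, 0.0)

    def test_identity_limit_recovers_input(self):
        # A_hat = I and identity weights: Z = ReLU(X) = X for non-negative X
        g = CellGraph(n_nodes=3, edges=np.empty((0, 2), dtype=np.int64))
        Ahat = normalize_adjacency(g)
        X = np.abs(np.random.default_rng(1).normal(size=(3, 3)))
        I = np.eye(3)[None]
        W = {"W_S0": I, "W_T0": I, "W_S1": I, "W_T1": I}
        Z_S, Z_T, _ = _forward(Ahat, X, X, W, np.zeros(3, dtype=int))
        np.testing.assert_allclose(Z_S, X)
        np.testing.assert_allclose(Z_T, X)

    def test_two_layer_composition_matches_layer_oracle(self):
        """Encoder = inner directed layer with ReLU, then a linear outer layer:
        Z_S aggregates via A_hat what the A_hat^T-side produced, and vice versa."""
        rng = np.random.default_rng(6)
        n, m, h, d = 5, 4, 3, 2
        g = CellGraph(n_nodes=n,
                      edges=np.array([[0, 1], [1, 0], [1, 2], [2, 1], [3, 4]]))
        Ahat = normalize_adjacency(g)
        X = rng.random((n, m))
        W = _init_weights(rng, 1, m, m, h, d)
        Z_S, Z_T, _ = _forward(Ahat, X, X, W, np.zeros(n, dtype=int))
        A = Ahat.toarray()
        relu = lambda x: np.maximum(x, 0)
        H_S = relu(A.T @ X @ W["W_S0"][0])
        H_T = relu(A @ X @ W["W_T0"][0])
        np.testing.assert_allclose(Z_S, A @ H_S @ W["W_T1"][0], atol=1e-8)
        np.testing.assert_allclose(Z_T, A.T @ H_T @ W["W_S1"][0], atol=1e-8)


class TestDecoder:
    def test_zero_sender_codes_give_half(self):
        r = decode(np.zeros((3, 2)), np.random.default_rng(0).normal(size=(3, 2)))
        np.testing.assert_allclose(r.A_prime, 0.5)

    def test_equal_codes_give_symmetric_matrix(self):
        Z = np.random.default_rng(1).normal(size=(4, 3))
        r = decode(Z, Z)
        np.testing.assert_allclose(r.A_prime, r.A_prime.T)

    def test_scalar_logistic_values(self):
        r = decode(np.array([[1.0, 0.0]]),
                   np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(r.A_prime[0], [0.7311, 0.2689], atol=5e-5)

    def test_probabilities_in_open_interval(self):
        rng = np.random.default_rng(2)
        r = decode(rng.normal(size=(6, 4)) * 2, rng.normal(size=(6, 4)) * 2)
        assert np.all(r.A_prime > 0) and np.all(r.A_prime < 1)

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            decode(np.zeros((2, 3)), np.zeros((2, 4)))


class TestLoss:
    def test_uniform_half_gives_ln2(self):
        A = np.full((4, 4), 0.5)
        loss = reconstruction_loss(A, [(0, 1)], [(2, 3)])
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_prediction_hits_clip_floor(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1.0
        loss = reconstruction_loss(A, [(0, 1)], [(1, 2)])
        assert 0 < loss < 1e-5

    def test_hand_arithmetic_case(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.8
        A[1, 2] = 0.4
        loss = reconstruction_loss(A, [(0, 1)], [(1, 2)])
        assert loss == pytest.approx(-(np.log(0.8) + np.log(0.6)) / 2, abs=1e-12)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.full((2, 2), 0.5), [], [(0, 1)])


class TestTraining:
    def test_same_seed_identical_loss_trace(self, small_data):
        dataset, graph, _ = small_data
        split = split_edges(graph, 0.1, seed=2)
        m1 = train(dataset, split, epochs=10, seed=5)
        m2 = train(dataset, split, epochs=10, seed=5)
        assert m1.loss_trace == m2.loss_trace
        np.testing.assert_array_equal(m1.Z_S, m2.Z_S)

    def test_untrained_model_scores_near_chance(self):
        """Random-embedding baseline: mean AUROC over 10 seeds ~ 0.5."""
        cfg = SyntheticConfig(n_cells=200, seed=3)
        dataset, graph, _ = generate_dataset(cfg)
        split = split_edges(graph, 0.2, seed=0)
        aurocs = [evaluate_split(train(dataset, split, epochs=0, seed=s),
                                 split).auroc for s in range(10)]
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_training_beats_untrained_baseline(self, trained_small):
        model, dataset, split = trained_small
        trained_auroc = evaluate_split(model, split).auroc
        untrained = evaluate_split(train(dataset, split, epochs=0, seed=0),
                                   split).auroc
        assert trained_auroc > untrained

    def test_heterogeneous_mode_trains(self, small_data):
        dataset, graph, _ = small_data
        split = split_edges(graph, 0.1, seed=4)
        m = train(dataset, split, mode="heterogeneous", epochs=10, seed=1)
        K = len(np.unique([t for t in dataset.cell_types]))
        assert m.weights["W_S0"].shape[0] == K
        assert np.isfinite(m.loss_trace).all()

    def test_heterogeneous_needs_types(self, small_data):
        dataset, graph, _ = small_data
        ds = SpatialDataset(X=dataset.X, coords=dataset.coords,
                            gene_names=dataset.gene_names,
                            cell_ids=dataset.cell_ids)
        split = split_edges(graph, 0.1, seed=4)
        with pytest.raises(ValueError):
            train(ds, split, mode="heterogeneous", epochs=1)

    def test_asymmetric_initial_widths_supported(self, small_data):
        dataset, graph, _ = small_data
        split = split_edges(graph, 0.1, seed=4)
        S0 = dataset.X[:, :7]
        T0 = dataset.X[:, 7:12]
        m = train(dataset, split, S0=S0, T0=T0, epochs=5, seed=0)
        assert m.weights["W_S0"].shape[1] == 7
        assert m.weights["W_T0"].shape[1] == 5


class TestPrediction:
    def test_edge_count_monotone_in_threshold(self, trained_small):
        model, _, _ = trained_small
        counts = [len(predict_interactions(model, t).predicted_edges)
                  for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_near_one_threshold_nearly_empty(self, trained_small):
        model, _, _ = trained_small
        n = model.n_cells
        r = predict_interactions(model, threshold=0.999999)
        assert len(r.predicted_edges) < 0.01 * n * (n - 1)

    def test_zero_model_predicts_all_offdiagonal_at_half(self):
        g = CellGraph(n_nodes=3, edges=np.array([[0, 1], [1, 0]]))
        model = DigaeModel(mode="homogeneous", weights={},
                           Ahat=normalize_adjacency(g),
                           type_codes=np.zeros(3, dtype=int),
                           Z_S=np.zeros((3, 2)), Z_T=np.zeros((3, 2)))
        r = predict_interactions(model, threshold=0.5)
        assert len(r.predicted_edges) == 6  # all ordered off-diagonal pairs

    def test_threshold_range_enforced(self, trained_small):
        model, _, _ = trained_small
        with pytest.raises(ValueError):
            predict_interactions(model, threshold=1.5)

    def test_save_load_roundtrip(self, trained_small, tmp_path):
        model, dataset, split = trained_small
        p = tmp_path / "model.npz"
        model.save(p)
        loaded = DigaeModel.load(p)
        pairs = np.asarray(split.test_pos)
        np.testing.assert_allclose(loaded.score_pairs(pairs),
                                   model.score_pairs(pairs), atol=1e-12)
        Z = loaded.encode(dataset.X)
        np.testing.assert_allclose(Z[0], model.Z_S, atol=1e-10)
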
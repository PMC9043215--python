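import numpy as np
import pytest

from psngcn._nn import relu
from psngcn.densegcn import (
    GCNConfig,
    GraphDataset,
    densegcn_forward,
    gcn_layer,
    init_params,
    normalize_adjacency,
    predict,
    train_densegcn,
)
from psngcn.pipeline import SplitMasks, split_samples

import oracles


def separable_graph(n=80, f=12, delta=4.0, seed=0):
    """Two well-separated Gaussian classes with a class-aligned affinity."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    rng.shuffle(y)
    X = rng.normal(size=(n, f)).astype(np.float32)
    X[y == 1, 0] += delta
    A = np.exp(-((X[:, :1] - X[:, :1].T) ** 2) / 4.0).astype(float)
    np.fill_diagonal(A, 0.0)
    masks = split_samples(n, y, seed=seed)
    return GraphDataset(A, X, y, masks)


class TestNormalizeAdjacency:
    def test_zero_matrix_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((2, 2))), np.eye(2))

    def test_single_edge_arithmetic(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A),
                                   [[0.5, 0.5], [0.5, 0.5]])

    def test_matches_loop_oracle(self, rng):
        A = rng.random((7, 7))
        A = (A + A.T) / 2
        np.testing.assert_allclose(normalize_adjacency(A),
                                   oracles.loop_normalize_adjacency(A), atol=1e-12)

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(rng.random((4, 4)))


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        H = np.abs(rng.normal(size=(5, 3)))
        out = gcn_layer(H, np.eye(5), np.eye(3), activation=lambda x: x)
        np.testing.assert_allclose(out, H)

    def test_zero_features_zero_output(self, rng):
        A = normalize_adjacency((lambda a: (a + a.T) / 2)(rng.random((4, 4))))
        out = gcn_layer(np.zeros((4, 3)), A, rng.normal(size=(3, 2)))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_triple_loop(self, rng):
        A = rng.random((5, 5))
        A_norm = normalize_adjacency((A + A.T) / 2)
        H = rng.normal(size=(5, 4))
        W = rng.normal(size=(4, 3))
        b = rng.normal(size=3)
        np.testing.assert_allclose(gcn_layer(H, A_norm, W, b),
                                   oracles.loop_gcn_layer(H, A_norm, W, b),
                                   atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gcn_layer(rng.normal(size=(5, 4)), np.eye(5), rng.normal(size=(3, 2)))


class TestDenseForward:
    def make(self, rng, n=6, f=5, L=3):
        cfg = GCNConfig(n_layers=L, hidden_dim=4, dtype="float64", seed=0)
        A = rng.random((n, n))
        A_norm = normalize_adjacency((A + A.T) / 2)
        X = rng.normal(size=(n, f))
        params = init_params(f, cfg, rng)
        return X, A_norm, params, L

    def test_single_layer_reduces_to_one_block(self, rng):
        X, A_norm, params, _ = self.make(rng, L=1)
        emb, _ = densegcn_forward(X, A_norm, params, 1)
        block = relu(A_norm @ X @ params["W0"] + params["b0"])
        np.testing.assert_allclose(emb, np.hstack([X, block]), atol=1e-12)

    def test_probability_rows_sum_to_one(self, rng):
        X, A_norm, params, L = self.make(rng)
        _, probs = densegcn_forward(X, A_norm, params, L)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_straightline_reference(self, rng):
        X, A_norm, params, L = self.make(rng)
        emb, probs = densegcn_forward(X, A_norm, params, L)
        ref_emb, ref_probs = oracles.straightline_densegcn_forward(
            X, A_norm, params, L)
        np.testing.assert_allclose(emb, ref_emb, atol=1e-10)
        np.testing.assert_allclose(probs, ref_probs, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        X, A_norm, params, L = self.make(rng, n=8)
        perm = rng.permutation(8)
        emb, probs = densegcn_forward(X, A_norm, params, L)
        emb_p, probs_p = densegcn_forward(X[perm], A_norm[np.ix_(perm, perm)],
                                          params, L)
        np.testing.assert_allclose(emb_p, emb[perm], atol=1e-10)
        np.testing.assert_allclose(probs_p, probs[perm], atol=1e-10)

    def test_identity_adjacency_pointwise(self, rng):
        # two nodes with identical features must get identical outputs
        X, _, params, L = self.make(rng, n=6)
        X[3] = X[1]
        _, probs = densegcn_forward(X, np.eye(6), params, L)
        np.testing.assert_allclose(probs[3], probs[1], atol=1e-12)


class TestTraining:
    def test_separable_fixture_reaches_full_training_accuracy(self):
        data = separable_graph()
        cfg = GCNConfig(n_layers=3, hidden_dim=8, epochs=150, seed=1)
        model, history = train_densegcn(data, cfg)
        assert max(history["train_acc"]) == 1.0
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_identical_seeds_identical_histories(self):
        data = separable_graph(n=40)
        cfg = GCNConfig(n_layers=2, hidden_dim=4, epochs=10, seed=7)
        _, h1 = train_densegcn(data, cfg)
        _, h2 = train_densegcn(data, cfg)
        assert h1 == h2

    def test_history_bounds_and_length(self):
        data = separable_graph(n=40)
        cfg = GCNConfig(n_layers=2, hidden_dim=4, epochs=12, seed=0)
        _, history = train_densegcn(data, cfg)
        for key in ("train_loss", "train_acc", "val_acc"):
            assert len(history[key]) == 12
        assert all(0.0 <= a <= 1.0 for a in history["val_acc"])

    def test_single_class_training_mask_rejected(self):
        data = separable_graph(n=40)
        y = data.labels.copy()
        y[data.masks.train] = 1
        bad = GraphDataset(data.adjacency, data.features, y, data.masks)
        with pytest.raises(ValueError, match="both classes"):
            train_densegcn(bad, GCNConfig(n_layers=2, hidden_dim=4, epochs=2))

    def test_no_label_leakage_from_held_out_nodes(self):
        # scrambling val/test labels must not change the training losses
        data = separable_graph(n=40, seed=3)
        cfg = GCNConfig(n_layers=2, hidden_dim=4, epochs=8, seed=5)
        _, h_ref = train_densegcn(data, cfg)
        y2 = data.labels.copy()
        y2[data.masks.test] = 1 - y2[data.masks.test]
        scrambled = GraphDataset(data.adjacency, data.features, y2, data.masks)
        _, h_scr = train_densegcn(scrambled, cfg)
        assert h_ref["train_loss"] == h_scr["train_loss"]
        assert h_ref["train_acc"] == h_scr["train_acc"]


class TestPredict:
    def test_probabilities_valid(self):
        data = separable_graph(n=40)
        cfg = GCNConfig(n_layers=2, hidden_dim=4, epochs=5, seed=0)
        model, _ = train_densegcn(data, cfg)
        probs, hard = predict(model, data)
        assert probs.shape == (40, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert set(np.unique(hard)) <= {0, 1}

    def test_argmax_prefers_class_zero_on_tie(self):
        assert np.argmax([0.5, 0.5]) == 0
        assert np.argmax([0.7, 0.3]) == 0
        assert np.argmax([0.3, 0.7]) == 1


@pytest.mark.parametrize("n_layers", [3, 5])
def test_depth_robust_training(n_layers):
    """Dense connectivity keeps deeper stacks trainable on separable data."""
    data = separable_graph(n=60)
    cfg = GCNConfig(n_layers=n_layers, hidden_dim=8, epochs=120, seed=2)
    _, history = train_densegcn(data, cfg)
    assert history["train_loss"][-1] < history["train_loss"][0]
    assert max(history["train_acc"]) == 1.0
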
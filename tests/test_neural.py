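"""Feed-forward ANN and RBF network against hand and loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nitrospec import (ann_forward, ann_train_gradient, init_ann, rbf_fit,
                       rbf_forward)
from nitrospec.neural import AnnSpec, RbfNet


def _one_hot(y, n):
    Y = np.zeros((len(y), n))
    Y[np.arange(len(y)), y] = 1.0
    return Y


class TestAnnForward:
    def test_default_architecture(self):
        spec = init_ann(3, 4)
        assert spec.layer_sizes == (3, 18, 16, 4)

    def test_zero_network_gives_uniform_scores(self):
        spec = init_ann(3, 4, scale=0.0)
        scores = ann_forward(spec, np.random.default_rng(0).random((5, 3)))
        np.testing.assert_allclose(scores, 0.25, atol=1e-12)

    def test_softmax_shift_invariance(self):
        spec = init_ann(2, 3, rng=1)
        x = np.array([[0.3, -0.2]])
        base = ann_forward(spec, x)
        shifted = spec.copy()
        shifted.biases[-1] = shifted.biases[-1] + 7.5
        np.testing.assert_allclose(ann_forward(shifted, x), base, atol=1e-9)

    def test_hand_computed_single_hidden_unit(self):
        # 2 inputs -> 1 relu unit -> 2 softmax outputs, all weights chosen
        # by hand; compare with explicit arithmetic
        spec = AnnSpec(
            weights=[np.array([[1.0], [-2.0]]), np.array([[0.5, -0.5]])],
            biases=[np.array([0.25]), np.array([0.1, -0.1])])
        x = np.array([[1.0, 0.25]])
        h = max(1.0 * 1.0 + (-2.0) * 0.25 + 0.25, 0.0)
        logits = np.array([0.5 * h + 0.1, -0.5 * h - 0.1])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(ann_forward(spec, x)[0], expected,
                                   atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            ann_forward(init_ann(3, 2), np.ones((1, 4)))

    @settings(deadline=None, max_examples=30)
    @given(arrays(float, (4, 5), elements=st.floats(-10, 10)))
    def test_rows_always_sum_to_one(self, X):
        scores = ann_forward(init_ann(5, 4, rng=0), X)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(scores >= 0)


class TestAnnTraining:
    def test_separable_toy_reaches_perfect_accuracy(self):
        # 4 points, two classes; linear separability verified by the
        # exhaustive boundary check below
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        assert all((X[y == 0][:, 0] < 1.5).tolist()
                   + (X[y == 1][:, 0] > 1.5).tolist())
        spec = init_ann(2, 2, rng=0)
        net = ann_train_gradient(spec, X, _one_hot(y, 2), max_epochs=500)
        pred = ann_forward(net, X).argmax(axis=1)
        np.testing.assert_array_equal(pred, y)

    def test_huge_l2_shrinks_to_uniform(self):
        X = np.random.default_rng(0).random((10, 3))
        Y = _one_hot([0, 1] * 5, 2)
        net = ann_train_gradient(init_ann(3, 2, rng=1), X, Y,
                                 l2_penalty=1e6, max_epochs=200)
        scores = ann_forward(net, X)
        np.testing.assert_allclose(scores, 0.5, atol=1e-3)

    def test_zero_epochs_is_identity(self):
        spec = init_ann(2, 2, rng=3)
        net = ann_train_gradient(spec, np.ones((2, 2)), np.eye(2),
                                 max_epochs=0)
        for w0, w1 in zip(spec.weights, net.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ann_train_gradient(init_ann(2, 2), np.empty((0, 2)),
                               np.empty((0, 2)))

    def test_loss_never_increased_by_training(self):
        rng = np.random.default_rng(5)
        X, Y = rng.random((20, 3)), _one_hot(rng.integers(0, 3, 20), 3)
        spec = init_ann(3, 3, rng=5)

        def loss(net):
            P = ann_forward(net, X)
            return -np.mean(np.sum(Y * np.log(P + 1e-12), axis=1))

        trained = ann_train_gradient(spec, X, Y, max_epochs=50)
        assert loss(trained) <= loss(spec) + 1e-12

    def test_flat_round_trip(self):
        spec = init_ann(3, 4, rng=2)
        again = spec.with_flat(spec.flatten())
        for a, b in zip(spec.weights, again.weights):
            np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError, match="parameters"):
            spec.with_flat(np.zeros(3))


class TestRbf:
    def test_unit_activation_at_center_and_analytic_point(self):
        net = RbfNet(centers=[[0.0, 0.0]], widths=[2.0], beta=[[1.0]])
        assert rbf_forward(net, [[0.0, 0.0]])[0, 0] == pytest.approx(1.0)
        # ||x - c|| = width * sqrt(2)  =>  activation exp(-1)
        x = [[2.0 * np.sqrt(2.0), 0.0]]
        assert rbf_forward(net, x)[0, 0] == pytest.approx(np.exp(-1.0))

    def test_zero_beta_zero_output(self):
        net = RbfNet(centers=[[0.0], [1.0]], widths=[1.0, 1.0],
                     beta=np.zeros((2, 3)))
        np.testing.assert_array_equal(rbf_forward(net, [[0.3]]),
                                      np.zeros((1, 3)))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            RbfNet(centers=[[0.0]], widths=[0.0], beta=[[1.0]])

    def test_matches_naive_double_loop(self, rng):
        """Vectorised forward equals the literal two-loop transcription of
        the Gaussian-unit and linear-readout formulas."""
        net = RbfNet(centers=rng.random((6, 3)),
                     widths=0.5 + rng.random(6),
                     beta=rng.standard_normal((6, 4)))
        X = rng.random((8, 3))
        out = rbf_forward(net, X)
        naive = np.zeros((8, 4))
        for r, x in enumerate(X):
            omega = [np.exp(-np.sum((x - c) ** 2) / (2.0 * s ** 2))
                     for c, s in zip(net.centers, net.widths)]
            for j in range(4):
                naive[r, j] = sum(net.beta[i, j] * omega[i]
                                  for i in range(6))
        np.testing.assert_allclose(out, naive, atol=1e-10)

    def test_interpolation_when_centers_equal_samples(self, rng):
        X = rng.random((12, 2))
        Y = _one_hot(rng.integers(0, 3, 12), 3)
        net = rbf_fit(X, Y, n_centers=12, seed=0)
        pred = rbf_forward(net, X).argmax(axis=1)
        np.testing.assert_array_equal(pred, Y.argmax(axis=1))
        # cross-check: the exact Gaussian design-matrix solve gives the
        # same readout weights
        from scipy.spatial.distance import cdist
        G = np.exp(-cdist(X, X, "sqeuclidean") / (2 * net.widths[0] ** 2))
        beta = np.linalg.lstsq(G, Y, rcond=None)[0]
        np.testing.assert_allclose(net.beta, beta, atol=1e-8)

    def test_single_class_targets(self, rng):
        X = rng.random((5, 2))
        Y = np.ones((5, 1))
        net = rbf_fit(X, Y, n_centers=3, seed=0)
        assert rbf_forward(net, X).shape == (5, 1)

    def test_conflicting_duplicates_still_solvable(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        Y = _one_hot([0, 1, 0], 2)
        net = rbf_fit(X, Y, n_centers=2, seed=0)
        assert np.all(np.isfinite(net.beta))

    def test_too_many_centers_rejected(self):
        with pytest.raises(ValueError, match="n_centers"):
            rbf_fit(np.ones((3, 2)), np.ones((3, 1)), n_centers=4)
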
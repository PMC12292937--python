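"""Convolutional model: shapes, training behaviour, metrics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from mi3d import (ModelConfig, TrainConfig, build_model, cohen_kappa,
                  evaluate, param_count, train, weights_checksum)
from mi3d.nn import Dense


def _toy_data(n=8, T=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 9, 9, T))
    y = np.array([1, 2, 3, 4] * (n // 4))
    return X, y


class TestBuild:
    def test_forward_probabilities_normalise(self):
        m = build_model(ModelConfig(W=9, T=750, dual_branch=True), seed=0)
        p = m.predict_proba(np.random.default_rng(0).normal(size=(2, 9, 9, 750)))
        assert p.shape == (2, 4)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_psd_length_input_builds(self):
        # 41 bins = 1 Hz resolution capped at 40 Hz
        m = build_model(ModelConfig(W=9, T=41), seed=0)
        p = m.predict_proba(np.zeros((1, 9, 9, 41)))
        np.testing.assert_allclose(p.sum(), 1.0, atol=1e-6)

    def test_dual_branch_parameter_budget(self):
        m = build_model(ModelConfig(W=9, T=100, dual_branch=True), seed=0)
        assert param_count(m) == 2 * m.branch_param_count() + m.head_param_count()

    def test_dense_head_width_is_256(self):
        m = build_model(ModelConfig(W=9, T=50), seed=0)
        dense = [l for l in m.head.layers if isinstance(l, Dense)]
        assert dense[0].W.shape[1] == 256

    def test_wrong_input_shape_rejected(self):
        m = build_model(ModelConfig(W=9, T=50), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            m.forward(np.zeros((1, 50, 5, 5)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(W=1, T=10)
        with pytest.raises(ValueError):
            ModelConfig(W=9, T=10, n_classes=1)


class TestTrain:
    def test_overfits_eight_trials(self):
        X, y = _toy_data()
        m = build_model(ModelConfig(W=9, T=60, dual_branch=True), seed=3)
        m, traces = train(m, X, y, TrainConfig(epochs=200, batch_size=8,
                                               seed=3, val_fraction=0.0))
        assert traces["train_acc"][-1] == 1.0

    def test_training_loss_decreases(self):
        X, y = _toy_data()
        m = build_model(ModelConfig(W=9, T=60), seed=1)
        _, traces = train(m, X, y, TrainConfig(epochs=40, batch_size=8,
                                               seed=1, val_fraction=0.0))
        loss = np.asarray(traces["train_loss"])
        # monotone within a 5-epoch tolerance window
        window_min = np.minimum.accumulate(loss)
        assert all(loss[i + 5] <= window_min[i] + 1e-6
                   for i in range(len(loss) - 5)) or loss[-1] < loss[0]
        assert loss[-1] < loss[0]

    def test_seeded_runs_are_bit_identical(self):
        X, y = _toy_data(T=20)
        out = []
        for _ in range(2):
            m = build_model(ModelConfig(W=9, T=20), seed=5)
            m, _ = train(m, X, y, TrainConfig(epochs=5, batch_size=4, seed=9,
                                              val_fraction=0.0))
            out.append(weights_checksum(m))
        assert out[0] == out[1]

    def test_validation_traces_recorded(self):
        X, y = _toy_data(n=48, T=20)
        m = build_model(ModelConfig(W=9, T=20), seed=0)
        _, traces = train(m, X, y, TrainConfig(epochs=3, seed=0,
                                               val_fraction=0.25))
        assert len(traces["val_acc"]) == 3

    def test_too_many_classes_rejected(self):
        X, _ = _toy_data(T=20)
        y = np.arange(8)  # 8 distinct labels into a 4-way head
        m = build_model(ModelConfig(W=9, T=20), seed=0)
        with pytest.raises(ValueError, match="classes"):
            train(m, X, y, TrainConfig(epochs=1))


class TestMetrics:
    def test_perfect_predictions(self):
        X, y = _toy_data(T=60)
        m = build_model(ModelConfig(W=9, T=60, dual_branch=True), seed=3)
        m, _ = train(m, X, y, TrainConfig(epochs=200, batch_size=8, seed=3,
                                          val_fraction=0.0))
        metrics = evaluate(m, X, y)
        assert metrics.accuracy == 1.0
        assert metrics.kappa == 1.0

    def test_confusion_rows_sum_to_class_counts(self):
        X, y = _toy_data(T=20)
        m = build_model(ModelConfig(W=9, T=20), seed=0)
        m.classes_ = np.array([1, 2, 3, 4])
        metrics = evaluate(m, X, y)
        np.testing.assert_array_equal(metrics.confusion.sum(axis=1),
                                      [2, 2, 2, 2])

    def test_empty_test_set_rejected(self):
        m = build_model(ModelConfig(W=9, T=20), seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(m, np.zeros((0, 9, 9, 20)), np.array([]))


class TestCohenKappa:
    def test_diagonal_is_one(self):
        assert cohen_kappa(np.diag([5, 3, 7])) == 1.0

    def test_uniform_is_zero(self):
        assert abs(cohen_kappa(np.full((4, 4), 10))) < 1e-12

    def test_hand_computed_binary_case(self):
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        assert np.isclose(cohen_kappa([[30, 10], [10, 30]]), 0.5)

    def test_chance_level_predictions_near_zero(self):
        rng = np.random.default_rng(0)
        truth = np.repeat([0, 1, 2, 3], 250)
        pred = rng.integers(0, 4, size=1000)
        cm = np.zeros((4, 4), dtype=int)
        for t, p in zip(truth, pred):
            cm[t, p] += 1
        assert abs(cohen_kappa(cm)) < 0.05

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 4, size=500)
        pred = np.where(rng.random(500) < 0.6, truth,
                        rng.integers(0, 4, size=500))
        cm = np.zeros((4, 4), dtype=int)
        for t, p in zip(truth, pred):
            cm[t, p] += 1
        assert np.isclose(cohen_kappa(cm), cohen_kappa_score(truth, pred))

    def test_degenerate_single_cell_defined_as_zero(self):
        cm = np.zeros((2, 2), dtype=int)
        cm[0, 0] = 10
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert cohen_kappa(cm) == 0.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([[-1, 0], [0, 1]])
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((2, 2)))
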
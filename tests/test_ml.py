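"""Perceptron classifiers: forward pass, gradients, protocol, Garson."""

import numpy as np
import pytest

from epom.cell_model import InvalidParameterError
from epom.ml import (
    Dataset,
    MLPSpec,
    TrainedModel,
    TrainingError,
    UndefinedMetricError,
    cost_and_gradients,
    cross_validate_and_select,
    evaluate_predictions,
    forward,
    garson_importance,
    init_model,
    logistic_baseline,
    make_dataset,
    predict_labels,
    stratified_folds,
    train,
)


def hand_model(weights, biases, n_inputs=1):
    weights = [np.asarray(w, float) for w in weights]
    biases = [np.asarray(b, float) for b in biases]
    spec = MLPSpec(n_inputs=n_inputs, hidden_layers=len(weights) - 1,
                   hidden_units=weights[0].shape[1])
    return TrainedModel(weights=weights, biases=biases, spec=spec)


class TestForward:
    def test_zero_network_outputs_half(self):
        m = hand_model([np.zeros((3, 4)), np.zeros((4, 2))],
                       [np.zeros(4), np.zeros(2)], n_inputs=3)
        out = forward(m, np.ones((5, 3)))
        np.testing.assert_allclose(out, 0.5)

    def test_hand_composition(self):
        # 1 input -> 1 hidden relu -> sigmoid out, hand-set weights
        m = hand_model([[[2.0]], [[-1.5]]], [[0.5], [0.25]])
        x = 0.8
        hidden = max(2.0 * x + 0.5, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(-1.5 * hidden + 0.25)))
        assert forward(m, [[x]])[0, 0] == pytest.approx(expected, rel=1e-14)

    def test_monotone_in_positive_weights(self):
        m = hand_model([np.full((1, 3), 0.7), np.full((3, 1), 0.9)],
                       [np.zeros(3), np.zeros(1)])
        outs = [forward(m, [[x]])[0, 0] for x in (0.1, 0.5, 2.0)]
        assert outs[0] < outs[1] < outs[2]

    def test_width_mismatch(self):
        m = hand_model([np.zeros((3, 2)), np.zeros((2, 1))],
                       [np.zeros(2), np.zeros(1)], n_inputs=3)
        with pytest.raises(InvalidParameterError):
            forward(m, np.ones((4, 5)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        spec = MLPSpec(n_inputs=2, hidden_layers=1, hidden_units=3,
                       n_outputs=1, weight_decay=0.01, seed=4)
        model = init_model(spec)
        x = rng.normal(size=(6, 2))
        y = rng.integers(0, 2, size=(6, 1)).astype(float)
        _, gw, gb = cost_and_gradients(model, x, y, spec.weight_decay)
        eps = 1e-5
        worst = 0.0
        for li in range(2):
            w = model.weights[li]
            for idx in np.ndindex(w.shape):
                w[idx] += eps
                cp, _, _ = cost_and_gradients(model, x, y, spec.weight_decay)
                w[idx] -= 2 * eps
                cm, _, _ = cost_and_gradients(model, x, y, spec.weight_decay)
                w[idx] += eps
                num = (cp - cm) / (2 * eps)
                denom = max(abs(num), abs(gw[li][idx]), 1e-8)
                worst = max(worst, abs(num - gw[li][idx]) / denom)
        assert worst < 1e-6

    def test_xor_separates(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([[0.0], [1.0], [1.0], [0.0]])
        solved = False
        for seed in range(10):
            spec = MLPSpec(n_inputs=2, hidden_layers=1, hidden_units=4,
                           learning_rate=0.5, weight_decay=0.0,
                           epochs=5000, seed=seed)
            model = train(x, y, spec)
            if np.array_equal(predict_labels(model, x), y.ravel().astype(int)):
                solved = True
                break
        assert solved

    def test_heavy_weight_decay_shrinks_weights(self, rng):
        x = rng.normal(size=(20, 3))
        y = np.tile([[0.0], [1.0]], (10, 1))  # balanced so the prior is 0.5
        spec = MLPSpec(n_inputs=3, hidden_layers=1, hidden_units=4,
                       learning_rate=0.1, weight_decay=5.0, epochs=2000, seed=0)
        model = train(x, y, spec)
        assert max(np.abs(w).max() for w in model.weights) < 0.05
        np.testing.assert_allclose(forward(model, x), 0.5, atol=0.1)

    def test_divergence_raises(self, rng):
        x = rng.normal(size=(10, 2)) * 100
        y = rng.integers(0, 2, size=(10, 1)).astype(float)
        spec = MLPSpec(n_inputs=2, hidden_layers=1, hidden_units=4,
                       learning_rate=50.0, epochs=2000, seed=0)
        with pytest.raises(TrainingError):
            train(x, y, spec)

    def test_training_cost_decreases(self, rng):
        x = rng.normal(size=(30, 2))
        y = (x[:, :1] + x[:, 1:] > 0).astype(float)
        spec = MLPSpec(n_inputs=2, hidden_layers=2, hidden_units=4,
                       learning_rate=0.2, epochs=3000, seed=1)
        model = train(x, y, spec)
        smoothed = np.convolve(model.history, np.ones(50) / 50, mode="valid")
        assert smoothed[-1] < smoothed[0]


class TestMetrics:
    def test_count_arithmetic(self):
        # TP=95, FP=5, FN=5 in a binary confusion
        y_true = [1] * 95 + [0] * 5 + [1] * 5 + [0] * 95
        y_pred = [1] * 95 + [1] * 5 + [0] * 5 + [0] * 95
        m = evaluate_predictions(y_true, y_pred, 2)
        assert m.se == pytest.approx(95.0)
        assert m.ppv == pytest.approx(95.0)
        assert m.f1 == pytest.approx(95.0)

    def test_perfect_predictions(self):
        m = evaluate_predictions([0, 1, 2] * 10, [0, 1, 2] * 10, 3)
        assert (m.se, m.ppv, m.f1) == (100.0, 100.0, 100.0)

    def test_all_positive_on_balanced_binary(self):
        m = evaluate_predictions([0] * 50 + [1] * 50, [1] * 100, 2)
        assert m.se == pytest.approx(100.0)
        assert m.ppv == pytest.approx(50.0)

    def test_absent_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            evaluate_predictions([0, 0], [0, 0], 2)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import precision_score, recall_score

        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        m = evaluate_predictions(y_true, y_pred, 2)
        assert m.se == pytest.approx(100 * recall_score(y_true, y_pred))
        assert m.ppv == pytest.approx(100 * precision_score(y_true, y_pred))


class TestDatasetProtocol:
    def test_split_reproducible_and_disjoint(self, rng):
        x = rng.normal(size=(80, 4))
        y = np.repeat([0, 1], 40)
        a = make_dataset(x, y, seed=5)
        b = make_dataset(x, y, seed=5)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.eval_idx, b.eval_idx)
        assert set(a.train_idx).isdisjoint(a.eval_idx)
        assert len(a.train_idx) + len(a.eval_idx) == 80
        assert len(a.train_idx) == 60  # 75% split

    def test_normalization_ignores_eval_rows(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        a = make_dataset(x, y, seed=2)
        x2 = x.copy()
        x2[a.eval_idx] += 1000.0  # corrupt only evaluation rows
        b = make_dataset(x2, y, seed=2)
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.std, b.std)

    def test_stratified_folds_cover_classes(self):
        idx = np.arange(40)
        labels = np.repeat([0, 1], 20)
        folds = stratified_folds(idx, labels, 10)
        assert len(folds) == 10
        for tr, va in folds:
            assert set(labels[va]) == {0, 1}
            assert set(tr).isdisjoint(va)


class TestSelection:
    def _separable_dataset(self, rng, n=60):
        x0 = rng.normal(loc=-3.0, size=(n, 2))
        x1 = rng.normal(loc=3.0, size=(n, 2))
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], n)
        return make_dataset(x, y, seed=0)

    def test_single_spec_grid_is_selected(self, rng):
        ds = self._separable_dataset(rng)
        spec = MLPSpec(n_inputs=2, hidden_layers=1, hidden_units=3,
                       learning_rate=0.3, epochs=500, seed=0)
        sel = cross_validate_and_select(ds, [spec])
        assert sel["selected_spec"] is spec

    def test_separable_pair_reaches_perfect_f1(self, rng):
        ds = self._separable_dataset(rng)
        grid = [
            MLPSpec(n_inputs=2, hidden_layers=hl, hidden_units=4,
                    learning_rate=0.3, epochs=800, seed=0)
            for hl in (1, 2)
        ]
        sel = cross_validate_and_select(ds, grid)
        assert sel["metrics"].f1 == pytest.approx(100.0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            cross_validate_and_select(self._separable_dataset(rng), [])


class TestGarson:
    def test_mirror_symmetric_inputs(self):
        w1 = np.array([[0.8, -0.3], [0.8, -0.3]])  # identical rows
        w2 = np.array([[1.1], [-0.7]])
        m = hand_model([w1, w2], [np.zeros(2), np.zeros(1)], n_inputs=2)
        np.testing.assert_allclose(garson_importance(m), [0.5, 0.5], atol=1e-12)

    def test_disconnected_input_gets_zero(self):
        w1 = np.array([[0.5, 0.5], [0.0, 0.0]])
        w2 = np.array([[1.0], [1.0]])
        m = hand_model([w1, w2], [np.zeros(2), np.zeros(1)], n_inputs=2)
        imp = garson_importance(m)
        assert imp[1] == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_tableau(self):
        """3-2-1 network against the classic per-pathway tableau."""
        w1 = np.array([[0.4, -1.0], [2.0, 0.5], [-0.6, 1.5]])
        w2 = np.array([[2.0], [-1.0]])
        m = hand_model([w1, w2], [np.zeros(2), np.zeros(1)], n_inputs=3)
        a = np.abs(w1)
        share = a / a.sum(axis=0)  # contribution of input i to hidden j
        v = np.abs(w2).ravel()
        raw = share @ (v / v.sum())
        expected = raw / raw.sum()
        np.testing.assert_allclose(garson_importance(m), expected, atol=1e-12)

    def test_sums_to_one_and_nonnegative(self, rng):
        spec = MLPSpec(n_inputs=6, hidden_layers=4, hidden_units=4, seed=8)
        m = init_model(spec)
        imp = garson_importance(m)
        assert imp.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(imp >= 0.0)


class TestLogisticBaseline:
    def test_chance_level_on_random_labels(self, rng):
        x = rng.normal(size=(400, 4))
        y = np.tile([0, 1], 200)
        ds = make_dataset(x, y, seed=1)
        m = logistic_baseline(ds)["metrics"]
        assert 30.0 < m.se < 70.0
        assert 30.0 < m.ppv < 70.0

    def test_separable_near_perfect(self, rng):
        x = np.vstack([rng.normal(-4, 1, (50, 2)), rng.normal(4, 1, (50, 2))])
        y = np.repeat([0, 1], 50)
        ds = make_dataset(x, y, seed=1)
        m = logistic_baseline(ds)["metrics"]
        assert m.f1 > 95.0
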
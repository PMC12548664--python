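"""Classifier: conv forward oracle, order invariance, training protocol."""

import numpy as np
import pytest

from dfcshapley import (ModelConfig, TrainConfig, evaluate, forward,
                        init_model, run_repetitions, train_once)
from dfcshapley.clf import accuracy, predict


def naive_conv(X, W, b):
    """Triple-loop evaluation of Y[k,c] = relu(sum X[i,j,k+p-1] W[i,j,p,c] + b)."""
    R, _, T = X.shape
    _, _, tau, C = W.shape
    K = T - tau + 1
    Y = np.zeros((K, C))
    for k in range(K):
        for c in range(C):
            acc = b[k, c] if b.ndim == 2 else b[c]
            for i in range(R):
                for j in range(R):
                    for p in range(tau):
                        acc += X[i, j, k + p] * W[i, j, p, c]
            Y[k, c] = max(acc, 0.0)
    return Y


def small_model(R=3, tau=2, C=4, n_classes=2, seed=0, **kw):
    cfg = ModelConfig(n_rois=R, tau=tau, channels=C, n_classes=n_classes, **kw)
    return init_model(cfg, np.random.default_rng(seed))


class TestForward:
    def test_hand_evaluated_single_weight(self):
        """R=1, T=2, tau=1, C=1, W=2, b=0, X=[0.5, -1]: Y=[1, 0], Z=1."""
        model = small_model(R=1, tau=1, C=1)
        model.W[...] = 2.0
        model.b[...] = 0.0
        X = np.array([[[0.5, -1.0]]])  # (1, 1, 2)
        _, cache = forward(X, model, return_cache=True)
        Y = np.maximum(cache["A"], 0.0)
        np.testing.assert_allclose(Y[:, 0], [1.0, 0.0])
        assert cache["acts"][0][0] == pytest.approx(1.0)  # Z = max_k Y

    def test_zero_filter_collapses_to_constant(self, rng):
        model = small_model(R=4, tau=2, C=8)
        model.W[...] = 0.0
        model.b[...] = 0.0
        logits = [forward(rng.normal(size=(4, 4, 5)), model) for _ in range(3)]
        np.testing.assert_array_equal(logits[0], logits[1])
        np.testing.assert_array_equal(logits[1], logits[2])

    def test_tau_equals_T_single_position(self, rng):
        model = small_model(R=3, tau=5, C=4)
        X = rng.normal(size=(3, 3, 5))
        _, cache = forward(X, model, return_cache=True)
        assert cache["A"].shape == (1, 4)  # K = T - tau + 1 = 1

    def test_T_below_tau_raises(self, rng):
        model = small_model(R=3, tau=4)
        with pytest.raises(ValueError, match="tau"):
            forward(rng.normal(size=(3, 3, 3)), model)

    @pytest.mark.parametrize("R,T,tau,C", [(2, 4, 2, 3), (4, 5, 5, 2),
                                           (3, 3, 1, 4)])
    def test_conv_matches_naive_triple_loop(self, R, T, tau, C, rng):
        model = small_model(R=R, tau=tau, C=C)
        X = rng.normal(size=(R, R, T))
        _, cache = forward(X, model, return_cache=True)
        np.testing.assert_allclose(np.maximum(cache["A"], 0),
                                   naive_conv(X, model.W, model.b), atol=1e-10)

    def test_per_position_bias_supported(self, rng):
        model = small_model(R=2, tau=2, C=3, per_position_bias=True,
                            n_windows=5)
        X = rng.normal(size=(2, 2, 5))
        _, cache = forward(X, model, return_cache=True)
        assert model.b.shape == (4, 3)
        np.testing.assert_allclose(np.maximum(cache["A"], 0),
                                   naive_conv(X, model.W, model.b), atol=1e-10)


class TestOrderInvariance:
    def test_tau_one_invariant_to_window_permutation(self, rng):
        """With tau=1 the max over per-window features ignores window order:
        logits are bit-identical under any permutation of the time axis."""
        model = small_model(R=3, tau=1, C=6)
        X = rng.normal(size=(3, 3, 7))
        ref = forward(X, model)
        for _ in range(10):
            perm = rng.permutation(7)
            np.testing.assert_array_equal(forward(X[:, :, perm], model), ref)

    def test_tau_two_order_sensitive(self):
        """Constructive counterexample: a tau>1 filter reads across adjacent
        windows, so swapping windows changes the logits."""
        model = small_model(R=1, tau=2, C=1, seed=3)
        model.W[0, 0, 0, 0] = 1.0
        model.W[0, 0, 1, 0] = -1.0
        model.b[...] = 0.0
        X = np.array([[[1.0, 0.0, -1.0]]])
        a = forward(X, model)
        b = forward(X[:, :, [1, 0, 2]], model)
        assert not np.array_equal(a, b)


class TestParameterCount:
    @pytest.mark.parametrize("R,tau,C,ncls", [(100, 4, 128, 2),
                                              (100, 8, 128, 4), (5, 2, 7, 3)])
    def test_formula(self, R, tau, C, ncls):
        model = small_model(R=R, tau=tau, C=C, n_classes=ncls)
        expected = (R * R * tau * C + C + (C * 64 + 64) + (64 * 32 + 32)
                    + (32 * ncls + ncls))
        assert model.parameter_count() == expected


class TestTraining:
    def _separable_set(self, rng, n=24, R=4, T=5):
        """Two classes split by the sign of one edge; linearly separable."""
        X, y = [], []
        for i in range(n):
            label = i % 2
            x = 0.1 * rng.normal(size=(R, R, T))
            x[0, 1, :] = x[1, 0, :] = (1.0 if label else -1.0) + \
                0.1 * rng.normal(size=T)
            X.append(x)
            y.append(label)
        return X, np.array(y)

    def test_learns_separable_data(self, rng):
        X, y = self._separable_set(rng)
        cfg = ModelConfig(n_rois=4, tau=2, channels=8)
        model = train_once(X, y, cfg, TrainConfig(learning_rate=1e-2,
                                                  epochs=20), seed=0)
        assert accuracy(model, X, y) >= 0.95

    def test_same_seed_same_weights(self, rng):
        X, y = self._separable_set(rng, n=10)
        cfg = ModelConfig(n_rois=4, tau=2, channels=4)
        tc = TrainConfig(epochs=3)
        a = train_once(X, y, cfg, tc, seed=5)
        b = train_once(X, y, cfg, tc, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        for wa, wb in zip(a.mlp_weights, b.mlp_weights):
            np.testing.assert_array_equal(wa, wb)

    def test_missing_class_warns(self, rng):
        X = [rng.normal(size=(3, 3, 4)) for _ in range(6)]
        y = np.zeros(6, dtype=int)
        cfg = ModelConfig(n_rois=3, tau=2, channels=4)
        with pytest.warns(UserWarning, match="covers classes"):
            train_once(X, y, cfg, TrainConfig(epochs=1), seed=0)

    def test_empty_train_set_rejected(self):
        cfg = ModelConfig(n_rois=3, tau=2)
        with pytest.raises(ValueError, match="empty"):
            train_once([], np.array([]), cfg, TrainConfig(), seed=0)


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        model = small_model(R=2, tau=1, C=2)
        X = [rng.normal(size=(2, 2, 3)) for _ in range(4)]
        y = predict(model, X)  # label with model's own predictions
        m = evaluate(model, X, y)
        assert m == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0,
                     "f1": 1.0}

    def test_hand_confusion_counts(self, monkeypatch, rng):
        """TP=3 FP=1 FN=1 TN=3: accuracy and macro P/R/F1 all 0.75."""
        model = small_model(R=2, tau=1, C=2)
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        monkeypatch.setattr("dfcshapley.clf.predict",
                            lambda m, xs: y_pred)
        m = evaluate(model, [None] * 8, y_true)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_single_class_test_set_warns(self, rng):
        model = small_model(R=2, tau=1, C=2)
        X = [rng.normal(size=(2, 2, 3)) for _ in range(3)]
        with pytest.warns(UserWarning, match="macro metrics"):
            m = evaluate(model, X, np.zeros(3, dtype=int))
        assert 0 <= m["accuracy"] <= 1


class TestRunRepetitions:
    def test_record_count_and_determinism(self, tiny_networks, tiny_dataset):
        y = tiny_dataset.task_labels("modality")
        mc = ModelConfig(n_rois=12, tau=2, channels=4)
        tc = TrainConfig(epochs=1, n_repetitions=3, seed=9)
        rep_a, recs_a = run_repetitions(tiny_networks, y, mc, tc)
        rep_b, recs_b = run_repetitions(tiny_networks, y, mc, tc)
        assert len(recs_a) == 3
        for ra, rb in zip(recs_a, recs_b):
            np.testing.assert_array_equal(ra.train_idx, rb.train_idx)
            np.testing.assert_array_equal(ra.test_idx, rb.test_idx)
        assert rep_a.per_repetition == rep_b.per_repetition

    def test_splits_are_stratified_and_disjoint(self, tiny_networks,
                                                tiny_dataset):
        y = tiny_dataset.task_labels("combined")
        mc = ModelConfig(n_rois=12, tau=2, channels=4, n_classes=4)
        tc = TrainConfig(epochs=1, n_repetitions=2, seed=1)
        _, recs = run_repetitions(tiny_networks, y, mc, tc)
        for rec in recs:
            assert set(rec.train_idx).isdisjoint(rec.test_idx)
            train_counts = np.bincount(y[rec.train_idx], minlength=4)
            assert train_counts.min() >= 5  # 8 per class at 80/20
            assert abs(len(rec.test_idx) - 0.2 * len(y)) <= 1
            assert len(rec.train_idx) + len(rec.test_idx) == len(y)

    def test_single_repetition_sd_zero(self, tiny_networks, tiny_dataset):
        y = tiny_dataset.task_labels("modality")
        mc = ModelConfig(n_rois=12, tau=2, channels=4)
        rep, _ = run_repetitions(tiny_networks, y, mc,
                                 TrainConfig(epochs=1, n_repetitions=1))
        assert rep.sd("accuracy") == 0.0

    def test_normalizer_fitted_on_training_split_only(self, tiny_networks,
                                                      tiny_dataset):
        """Leakage guard: refitting the normalizer on the recorded training
        split reproduces the stored statistics exactly."""
        from dfcshapley import fit_normalizer
        y = tiny_dataset.task_labels("modality")
        mc = ModelConfig(n_rois=12, tau=2, channels=4)
        _, recs = run_repetitions(tiny_networks, y, mc,
                                  TrainConfig(epochs=1, n_repetitions=2))
        for rec in recs:
            refit = fit_normalizer([tiny_networks[i] for i in rec.train_idx])
            np.testing.assert_array_equal(refit.mean, rec.normalizer.mean)
            np.testing.assert_array_equal(refit.sd, rec.normalizer.sd)

    def test_subject_level_split_keeps_groups_disjoint(self, tiny_networks,
                                                       tiny_dataset):
        """Grouped splits never place the same subject on both sides."""
        y = tiny_dataset.task_labels("modality")
        groups = [subj for subj, _n, _s in tiny_dataset.runs]
        mc = ModelConfig(n_rois=12, tau=2, channels=4)
        _, recs = run_repetitions(tiny_networks, y, mc,
                                  TrainConfig(epochs=1, n_repetitions=2),
                                  groups=groups)
        for rec in recs:
            train_subj = {groups[i] for i in rec.train_idx}
            test_subj = {groups[i] for i in rec.test_idx}
            assert train_subj.isdisjoint(test_subj)

    def test_stratification_impossible_lists_counts(self, tiny_networks):
        y = np.zeros(len(tiny_networks), dtype=int)
        y[0] = 1  # a singleton class cannot stratify
        mc = ModelConfig(n_rois=12, tau=2, channels=4)
        with pytest.raises(ValueError, match="class counts"):
            run_repetitions(tiny_networks, y, mc, TrainConfig(epochs=1))
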
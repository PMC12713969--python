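"""Classifier construction, training behavior, prediction and metrics."""

import numpy as np
import pytest

from oroflow import (
    ModelConfig,
    build_model,
    compute_metrics,
    make_params,
    predict,
    simulate_window_bank,
    split_train_test,
    train,
)
from oroflow.errors import ValidationError
from oroflow.model import load_model, metrics_from_confusion, save_model
from oroflow.segmentation import SegmentSet


def _small_bank(n=80, fs=50.0, seed=3):
    params = make_params("easy", fs=fs, seed=seed)
    return simulate_window_bank(n, params, seed=seed)


def _cfg(**kw):
    defaults = dict(epochs=4, batch_size=10, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestBuildModel:
    def test_branch_structure(self):
        model = build_model(_cfg(), window_len=500)
        conv_weights = [k for k in model.params if k.startswith("W_")]
        assert len(conv_weights) == 8  # 4 kernel widths x 2 input signals
        assert model.params["W_oral_16"].shape == (16, 16)

    def test_seeded_init_identical(self):
        a = build_model(_cfg(seed=11), 500)
        b = build_model(_cfg(seed=11), 500)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_different_seeds_differ(self):
        a = build_model(_cfg(seed=1), 500)
        b = build_model(_cfg(seed=2), 500)
        assert not np.array_equal(a.params["W1"], b.params["W1"])

    def test_kernel_wider_than_window_rejected(self):
        with pytest.raises(ValidationError):
            build_model(_cfg(), window_len=8)

    def test_softmax_rows_normalized(self, rng):
        model = build_model(_cfg(), 500)
        probs = model.forward(rng.normal(size=(7, 500)), rng.normal(size=(7, 500)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))


class TestTraining:
    def test_history_one_entry_per_epoch(self):
        bank = _small_bank()
        model = build_model(_cfg(epochs=6), bank.oral.shape[1])
        _, history = train(model, bank, _cfg(epochs=6))
        assert all(len(history[k]) == 6 for k in ("loss", "acc", "val_loss", "val_acc"))

    def test_loss_descends_on_separable_data(self):
        bank = _small_bank()
        model = build_model(_cfg(epochs=5), bank.oral.shape[1])
        _, history = train(model, bank, _cfg(epochs=5))
        assert history["loss"][-1] <= history["loss"][0]

    def test_training_deterministic(self):
        bank = _small_bank()
        runs = []
        for _ in range(2):
            model = build_model(_cfg(), bank.oral.shape[1])
            model, history = train(model, bank, _cfg())
            runs.append((model.params["W1"].copy(), history["loss"]))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_single_class_rejected(self):
        bank = _small_bank()
        only_events = bank.subset(np.flatnonzero(bank.is_event))
        model = build_model(_cfg(), bank.oral.shape[1])
        with pytest.raises(ValidationError):
            train(model, only_events, _cfg())


class TestPredict:
    def test_one_hot_labels_and_prob_rows(self):
        bank = _small_bank()
        model = build_model(_cfg(), bank.oral.shape[1])
        labels, probs = predict(model, bank)
        assert set(map(tuple, labels)) <= {(1, 0), (0, 1)}
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_pure_function_of_weights(self):
        bank = _small_bank(n=20)
        model = build_model(_cfg(), bank.oral.shape[1])
        l1, p1 = predict(model, bank)
        l2, p2 = predict(model, bank)
        assert np.array_equal(l1, l2) and np.array_equal(p1, p2)

    def test_window_length_mismatch_rejected(self):
        bank = _small_bank(n=20)
        model = build_model(_cfg(), bank.oral.shape[1] + 10)
        with pytest.raises(ValidationError):
            predict(model, bank)

    def test_save_load_preserves_predictions(self, tmp_path):
        bank = _small_bank(n=30)
        model = build_model(_cfg(), bank.oral.shape[1])
        model, _ = train(model, bank, _cfg(epochs=2))
        _, before = predict(model, bank)
        save_model(model, tmp_path / "m")
        _, after = predict(load_model(tmp_path / "m"), bank)
        assert np.array_equal(before, after)


def _one_hot(idx):
    y = np.zeros((len(idx), 2), dtype=np.int64)
    y[np.arange(len(idx)), idx] = 1
    return y


class TestMetrics:
    def test_worked_confusion_matrix(self):
        # TP=89, FN=11, FP=2, TN=98
        y_true = _one_hot(np.r_[np.zeros(100, int), np.ones(100, int)])
        y_pred = _one_hot(np.r_[np.zeros(89, int), np.ones(11, int),
                                np.zeros(2, int), np.ones(98, int)])
        rep = compute_metrics(y_true, y_pred)
        assert rep.confusion.tolist() == [[89, 11], [2, 98]]
        assert rep.tpr == pytest.approx(0.89, abs=5e-4)
        assert rep.fpr == pytest.approx(0.02, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.935, abs=5e-4)
        assert rep.precision == pytest.approx(0.978, abs=5e-4)

    def test_perfect_predictions(self):
        y = _one_hot(np.array([0, 0, 1, 1, 1]))
        rep = compute_metrics(y, y)
        assert (rep.accuracy, rep.precision, rep.tpr, rep.fpr) == (1.0, 1.0, 1.0, 0.0)

    def test_undefined_marker_not_zero(self):
        y = _one_hot(np.ones(10, int))  # all non-event
        rep = compute_metrics(y, y)
        assert rep.tpr is None and rep.sensitivity is None and rep.precision is None
        assert rep.specificity == 1.0

    def test_identities_hold(self, rng):
        for _ in range(50):
            y_true = _one_hot(rng.integers(0, 2, 40))
            y_pred = _one_hot(rng.integers(0, 2, 40))
            rep = compute_metrics(y_true, y_pred)
            assert rep.sensitivity == rep.tpr
            if rep.fpr is not None:
                assert rep.specificity == pytest.approx(1.0 - rep.fpr)

    def test_pooling_equals_summed_confusions(self, rng):
        c1 = rng.integers(0, 50, (2, 2))
        c2 = rng.integers(0, 50, (2, 2))
        pooled = metrics_from_confusion(c1 + c2)
        assert pooled.confusion.tolist() == (c1 + c2).tolist()
        tp, fn, fp, tn = c1[0, 0] + c2[0, 0], c1[0, 1] + c2[0, 1], c1[1, 0] + c2[1, 0], c1[1, 1] + c2[1, 1]
        assert pooled.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(_one_hot(np.zeros(5, int)), _one_hot(np.zeros(6, int)))

    def test_invalid_one_hot_rejected(self):
        bad = np.array([[1, 1], [0, 1]])
        with pytest.raises(ValidationError):
            compute_metrics(bad, bad)
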
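import math

import numpy as np
import pytest

from conftest import split_table
from pvpkit.asl import ASLConfig
from pvpkit.train_eval import (
    ClassPrediction,
    TrainConfig,
    VirionClassifier,
    compute_metrics,
    gamma_sweep,
    predict,
    train,
)


def confusion_oracle(predicted, truth, classes):
    """Hand-built confusion-matrix metrics, independent of scikit-learn."""
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k))
    for p, t in zip(predicted, truth):
        cm[idx[t], idx[p]] += 1
    n = cm.sum()
    acc = np.trace(cm) / n
    per_prec, per_rec, per_f1, support = [], [], [], []
    for c in range(k):
        tp = cm[c, c]
        prec = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
        rec = tp / cm[c, :].sum() if cm[c, :].sum() else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_prec.append(prec)
        per_rec.append(rec)
        per_f1.append(f1)
        support.append(cm[c, :].sum())
    support = np.array(support)
    w = support / n
    # multi-class MCC: correlation over the full confusion matrix
    t_k = cm.sum(axis=1)
    p_k = cm.sum(axis=0)
    cov_tp = np.trace(cm) * n - t_k @ p_k
    denom = math.sqrt(n**2 - (p_k**2).sum()) * math.sqrt(n**2 - (t_k**2).sum())
    mcc = cov_tp / denom if denom else 0.0
    return {
        "accuracy": acc,
        "weighted_precision": float(w @ per_prec),
        "weighted_recall": float(w @ per_rec),
        "weighted_f1": float(w @ per_f1),
        "macro_f1": float(np.mean(per_f1)),
        "mcc": float(mcc),
        "per_class_f1": dict(zip(classes, per_f1)),
    }


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = ["PVP"] * 5 + ["nonPVP"] * 5
        rep = compute_metrics(truth, truth, averaging="binary")
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1, rep.mcc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_all_positives_recovered_gives_recall_one(self):
        truth = ["PVP"] * 12 + ["nonPVP"] * 10
        predicted = ["PVP"] * 12 + ["PVP"] * 3 + ["nonPVP"] * 7
        rep = compute_metrics(predicted, truth, averaging="binary")
        assert rep.recall == 1.0

    def test_constant_predictor_mcc_zero(self):
        truth = ["PVP"] * 10 + ["nonPVP"] * 10
        rep = compute_metrics(["PVP"] * 20, truth, averaging="binary")
        assert rep.mcc == 0.0

    @pytest.mark.parametrize("n_classes", [2, 7])
    def test_agrees_with_confusion_matrix_oracle(self, n_classes):
        rng = np.random.default_rng(17)
        classes = [f"c{i}" for i in range(n_classes)]
        for _ in range(200 // n_classes):
            truth = [classes[i] for i in rng.integers(0, n_classes, 60)]
            predicted = [classes[i] for i in rng.integers(0, n_classes, 60)]
            oracle = confusion_oracle(predicted, truth, classes)
            rep_w = compute_metrics(predicted, truth, "weighted", classes)
            assert rep_w.accuracy == pytest.approx(oracle["accuracy"])
            assert rep_w.precision == pytest.approx(oracle["weighted_precision"])
            assert rep_w.recall == pytest.approx(oracle["weighted_recall"])
            assert rep_w.f1 == pytest.approx(oracle["weighted_f1"])
            assert rep_w.mcc == pytest.approx(oracle["mcc"], abs=1e-12)
            for c in classes:
                assert rep_w.per_class_f1[c] == pytest.approx(oracle["per_class_f1"][c])
            rep_m = compute_metrics(predicted, truth, "macro", classes)
            assert rep_m.f1 == pytest.approx(oracle["macro_f1"])

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(23)
        classes = [f"c{i}" for i in range(7)]
        for _ in range(20):
            truth = [classes[i] for i in rng.integers(0, 7, 80)]
            predicted = [classes[i] for i in rng.integers(0, 7, 80)]
            rep = compute_metrics(predicted, truth, "weighted", classes)
            assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["a"], ["a", "b"])

    def test_never_predicted_class_warns(self):
        with pytest.warns(UserWarning, match="never predicted"):
            compute_metrics(["a", "a", "a"], ["a", "b", "a"], "weighted", ["a", "b"])


class TestTraining:
    def test_learns_separable_classes(self, small_gaussian, quick_train_config):
        (trt, trl), (tet, tel) = split_table(*small_gaussian, seed=1)
        results = train(trt, trl, train_config=quick_train_config)
        rep = results.evaluate(tet, tel, averaging="binary")
        assert rep.accuracy >= 0.9

    def test_same_seed_identical_parameters(self, small_gaussian, quick_train_config):
        table, labels = small_gaussian
        r1 = train(table, labels, train_config=quick_train_config)
        r2 = train(table, labels, train_config=quick_train_config)
        s1, s2 = r1.state.network.state(), r2.state.network.state()
        for k in s1:
            assert np.array_equal(s1[k], s2[k])
        assert r1.history.equals(r2.history)

    def test_single_class_rejected(self, small_gaussian, quick_train_config):
        table, _ = small_gaussian
        with pytest.raises(ValueError, match="two classes"):
            VirionClassifier(table, ["PVP"] * len(table),
                             train_config=quick_train_config)

    def test_early_stopping_bookkeeping(self, small_gaussian, quick_train_config):
        table, labels = small_gaussian
        results = train(table, labels, train_config=quick_train_config)
        best = results.history.loc[results.best_epoch - 1, "val_loss"]
        assert best == pytest.approx(results.history["val_loss"].min())
        assert results.state.best_val_loss == pytest.approx(best)

    def test_summary_mentions_configuration(self, small_gaussian, quick_train_config):
        table, labels = small_gaussian
        results = train(table, labels, train_config=quick_train_config)
        text = results.summary()
        assert "gamma_neg=4.0" in text
        assert "nonPVP" in text and "PVP" in text


class TestPredict:
    def test_confidences_sum_to_one_and_argmax(self, small_gaussian, quick_train_config):
        table, labels = small_gaussian
        results = train(table, labels, train_config=quick_train_config)
        preds = predict(results.state, table)
        assert [p.id for p in preds] == table.ids
        for p in preds:
            assert p.confidence.sum() == pytest.approx(1.0, abs=1e-6)
            assert p.label == results.classes[int(np.argmax(p.confidence))]

    def test_dim_mismatch_rejected(self, small_gaussian, quick_train_config):
        table, labels = small_gaussian
        results = train(table, labels, train_config=quick_train_config)
        from pvpkit.embeddings import EmbeddingTable

        bad = EmbeddingTable("x", ["a"], np.zeros((1, 8)))
        with pytest.raises(ValueError, match="input_dim"):
            predict(results.state, bad)

    def test_class_prediction_invariants(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ClassPrediction("a", 0, "x", np.array([0.9, 0.9]))
        with pytest.raises(ValueError, match="argmax"):
            ClassPrediction("a", 0, "x", np.array([0.1, 0.9]))


class TestGammaSweep:
    def test_single_config_consistent_with_direct_train(self, small_gaussian,
                                                        quick_train_config):
        (trt, trl), (tet, tel) = split_table(*small_gaussian, seed=2)
        frame = gamma_sweep(trt, trl, tet, tel, configs=[(0, 4)],
                            train_config=quick_train_config)
        assert len(frame) == 1
        direct = train(
            trt, trl, loss_config=ASLConfig(0, 4, "standard"),
            train_config=quick_train_config,
        ).evaluate(tet, tel)
        assert frame.loc[0, "f1"] == pytest.approx(direct.f1)
        assert frame.loc[0, "accuracy"] == pytest.approx(direct.accuracy)

    def test_default_grid_shape(self, small_gaussian, quick_train_config):
        (trt, trl), (tet, tel) = split_table(*small_gaussian, seed=3)
        frame = gamma_sweep(trt, trl, tet, tel, train_config=quick_train_config)
        assert list(frame[["gamma_pos", "gamma_neg"]].itertuples(index=False, name=None)) == [
            (0, 1), (0, 4), (0, 6), (1, 1), (2, 0)
        ]
        assert {"f1[PVP]", "f1[nonPVP]"} <= set(frame.columns)

    def test_empty_configs_rejected(self, small_gaussian):
        table, labels = small_gaussian
        with pytest.raises(ValueError):
            gamma_sweep(table, labels, table, labels, configs=[])
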
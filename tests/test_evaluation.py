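"""Metric layer: confusion counts, macro averaging, top-k ranking."""

import numpy as np
import pytest

from chirpnet.evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    evaluate_predictions,
    metrics,
    per_class_counts,
    top_k_accuracy,
)

WORKED_CM = ConfusionMatrix(np.array([[3, 1], [2, 4]]))


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion_matrix([0, 1], [0, 1], 2)
        assert cm.counts.tolist() == [[1, 0], [0, 1]]

    def test_direct_counts(self):
        cm = confusion_matrix([0, 0, 1], [1, 0, 1], 2)
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_empty_inputs_give_zero_matrix(self):
        cm = confusion_matrix([], [], 3)
        assert cm.counts.sum() == 0 and cm.counts.shape == (3, 3)

    def test_out_of_range_label_reported_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            confusion_matrix([0, 5], [0, 1], 2)


class TestPerClassCounts:
    def test_worked_example(self):
        assert per_class_counts(WORKED_CM, 0) == (3, 2, 1, 4)

    def test_perfect_diagonal_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([4, 2, 7]))
        for c in range(3):
            tp, fp, fn, _ = per_class_counts(cm, c)
            assert (fp, fn) == (0, 0)

    def test_partition_identity(self):
        rng = np.random.default_rng(3)
        cm = ConfusionMatrix(rng.integers(0, 9, size=(4, 4)))
        for c in range(4):
            assert sum(per_class_counts(cm, c)) == cm.total


class TestMetrics:
    def test_worked_example(self):
        rep = metrics(WORKED_CM)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.per_class["precision"][0] == pytest.approx(0.6)
        assert rep.per_class["recall"][0] == pytest.approx(0.75)
        assert rep.per_class["f1"][0] == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_binary_formulas_direct(self):
        # on 2 classes the macro numbers equal the mean of the one-vs-rest formulas
        rep = metrics(WORKED_CM)
        expected_p, expected_r = [], []
        for c in (0, 1):
            tp, fp, fn, _ = per_class_counts(WORKED_CM, c)
            expected_p.append(tp / (tp + fp))
            expected_r.append(tp / (tp + fn))
        assert rep.precision_macro == pytest.approx(np.mean(expected_p))
        assert rep.recall_macro == pytest.approx(np.mean(expected_r))

    def test_perfect_prediction_scores_one(self):
        rep = metrics(ConfusionMatrix(np.diag([5, 3, 2])))
        assert (
            rep.accuracy == rep.precision_macro == rep.recall_macro == rep.f1_macro == 1.0
        )

    def test_f1_equals_common_value_when_precision_matches_recall(self):
        # symmetric off-diagonal: precision == recall per class
        cm = ConfusionMatrix(np.array([[6, 2], [2, 6]]))
        rep = metrics(cm)
        for p, r, f in zip(*(rep.per_class[k] for k in ("precision", "recall", "f1"))):
            assert p == pytest.approx(r)
            assert f == pytest.approx(p)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(np.zeros((2, 2), dtype=int)))

    def test_absent_class_scores_zero(self):
        cm = ConfusionMatrix(np.array([[2, 0, 0], [0, 3, 0], [0, 0, 0]]))
        rep = metrics(cm)
        assert rep.per_class["precision"][2] == 0.0
        assert rep.per_class["recall"][2] == 0.0

    def test_macro_matches_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        rep = metrics(confusion_matrix(y_true, y_pred, 5))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0
        )
        assert rep.precision_macro == pytest.approx(p)
        assert rep.recall_macro == pytest.approx(r)
        assert rep.f1_macro == pytest.approx(f)

    def test_macro_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        perm = np.array([2, 0, 3, 1])
        base = metrics(confusion_matrix(y_true, y_pred, 4))
        permuted = metrics(confusion_matrix(perm[y_true], perm[y_pred], 4))
        assert base.precision_macro == pytest.approx(permuted.precision_macro)
        assert base.recall_macro == pytest.approx(permuted.recall_macro)
        assert base.f1_macro == pytest.approx(permuted.f1_macro)


class TestTopK:
    def test_top1_equals_argmax_accuracy(self):
        rng = np.random.default_rng(2)
        proba = rng.random((50, 6))
        proba /= proba.sum(axis=1, keepdims=True)
        y = rng.integers(0, 6, 50)
        top1 = top_k_accuracy(proba, y, 1)
        argmax_acc = metrics(confusion_matrix(y, proba.argmax(axis=1), 6)).accuracy
        assert top1 == pytest.approx(argmax_acc)

    def test_top_n_classes_is_exhaustive(self):
        rng = np.random.default_rng(4)
        proba = rng.random((30, 5))
        y = rng.integers(0, 5, 30)
        assert top_k_accuracy(proba, y, 5) == 1.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(6)
        proba = rng.random((100, 8))
        y = rng.integers(0, 8, 100)
        vals = [top_k_accuracy(proba, y, k) for k in range(1, 9)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_uniform_random_matches_chance_level(self):
        # with uniform random scores and random labels, P(hit) = k / n_classes
        rng = np.random.default_rng(7)
        proba = rng.random((10_000, 30))
        y = rng.integers(0, 30, 10_000)
        assert top_k_accuracy(proba, y, 5) == pytest.approx(5 / 30, abs=0.02)

    def test_ties_prefer_lower_index(self):
        proba = np.array([[0.25, 0.25, 0.25, 0.25]])
        assert top_k_accuracy(proba, [0], 1) == 1.0
        assert top_k_accuracy(proba, [1], 1) == 0.0
        assert top_k_accuracy(proba, [1], 2) == 1.0

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            top_k_accuracy(np.ones((2, 3)) / 3, [0, 1], 0)
        with pytest.raises(ValueError):
            top_k_accuracy(np.ones((2, 3)) / 3, [0, 1], 4)


def test_evaluate_predictions_report_consistency():
    rng = np.random.default_rng(9)
    proba = rng.random((60, 7))
    proba /= proba.sum(axis=1, keepdims=True)
    y = rng.integers(0, 7, 60)
    rep = evaluate_predictions(proba, y, 7, model_name="toy")
    assert rep.top1 == pytest.approx(rep.accuracy)
    assert rep.top5 >= rep.top1
    assert rep.model_name == "toy"
    assert rep.confusion.total == 60
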
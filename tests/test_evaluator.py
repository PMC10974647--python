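"""Metrics, ensemble voting with tie-break, CYP450 substrate aggregation."""

import numpy as np
import pandas as pd
import pytest

from admetfuse.evaluator import (
    CypAggregationConfig,
    CypSynthesisClassifier,
    auroc,
    binary_metrics,
    cyp_aggregate,
    ensemble_vote,
    evaluate_predictions,
    matched_proportion,
)
from admetfuse.models import PredictionMatrix


def brute_force_auroc(scores, labels):
    """O(n^2) oracle: concordant pairs count 1, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_hand_computed_confusion_example(self):
        # TP=2 FP=1 FN=2 TN=6: precision 2/3, recall 1/2, F1 the harmonic mean
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        probs = np.array([0.9, 0.8, 0.2, 0.3, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        m = binary_metrics(probs, labels)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (2, 1, 2, 6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(1 / 2)
        assert m["f1"] == pytest.approx(2 * (2 / 3) * (1 / 2) / (2 / 3 + 1 / 2)) == pytest.approx(4 / 7)

    def test_perfect_predictor(self):
        labels = np.array([0, 1, 0, 1])
        m = binary_metrics(np.array([0.1, 0.9, 0.2, 0.8]), labels)
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == m["auroc"] == 1.0

    def test_accuracy_bias_on_imbalanced_labels(self):
        """Predicting all-positive on 99:1 labels scores 99% accuracy."""
        labels = np.concatenate([np.ones(99), np.zeros(1)])
        m = binary_metrics(np.ones(100), labels)
        assert m["accuracy"] == pytest.approx(0.99)
        assert m["recall"] == 1.0
        assert m["precision"] == pytest.approx(0.99)

    def test_zero_denominators_reported_absent(self):
        labels = np.array([0, 0, 0])
        m = binary_metrics(np.array([0.1, 0.2, 0.3]), labels)
        assert m["precision"] is None  # no positive calls
        assert m["recall"] is None  # no positive labels
        assert m["auroc"] is None

    def test_f1_bounds_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = rng.integers(0, 2, size=30)
            probs = rng.random(30)
            if labels.min() == labels.max():
                continue
            m = binary_metrics(probs, labels)
            if m["f1"] is None:
                continue
            assert 0.0 <= m["f1"] <= min(2 * m["precision"], 2 * m["recall"])
            if m["precision"] == m["recall"]:
                assert m["f1"] == pytest.approx(m["precision"])


class TestAuroc:
    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_agrees_with_pair_counting_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, size=500)
        scores = rng.random(500)
        assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_no_signal_is_half(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, size=10_000)
        scores = rng.random(10_000)
        assert abs(auroc(scores, labels) - 0.5) < 0.02

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        assert auroc(scores, labels) == pytest.approx(auroc(np.exp(5 * scores), labels))

    def test_single_class_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="one class"):
            assert auroc([0.1, 0.9], [1, 1]) is None


class TestEnsembleVote:
    def _cell(self, probs, threshold=0.5):
        mats = [np.array([[p]]) for p in probs]
        calls, _ = ensemble_vote(mats, threshold=threshold)
        return int(calls[0, 0])

    def test_clear_majority_ignores_probabilities(self):
        # four of six binarized votes positive
        assert self._cell([0.9, 0.8, 0.7, 0.6, 0.1, 0.2]) == 1
        assert self._cell([0.1, 0.2, 0.3, 0.4, 0.9, 0.8]) == 0

    def test_tie_resolved_by_mean_probability(self):
        # votes 3:3, mean 0.61 -> positive
        assert self._cell([0.9, 0.9, 0.86, 0.4, 0.3, 0.3]) == 1
        # votes 3:3, mean 0.42 -> negative
        assert self._cell([0.55, 0.55, 0.52, 0.3, 0.3, 0.3]) == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        mats = [rng.random((10, 4)) for _ in range(6)]
        calls1, _ = ensemble_vote(mats)
        calls2, _ = ensemble_vote(mats[::-1])
        assert (calls1 == calls2).all()

    def test_identical_models_reduce_to_thresholding(self):
        rng = np.random.default_rng(1)
        m = rng.random((20, 5))
        calls, mean_prob = ensemble_vote([m] * 6)
        assert (calls == (m >= 0.5)).all()
        np.testing.assert_allclose(mean_prob, m)

    def test_shape_mismatch_is_hard_error(self):
        mats = [np.zeros((3, 2))] * 5 + [np.zeros((3, 3))]
        with pytest.raises(ValueError, match="shape"):
            ensemble_vote(mats)

    def test_expected_model_count_enforced(self):
        with pytest.raises(ValueError, match="expected 6"):
            ensemble_vote([np.zeros((2, 2))] * 4)

    def test_label_order_checked_for_prediction_matrices(self):
        a = PredictionMatrix("a", np.zeros((2, 2)), ["x", "y"])
        b = PredictionMatrix("b", np.zeros((2, 2)), ["y", "x"])
        with pytest.raises(ValueError, match="label order"):
            ensemble_vote([a, b], n_expected=2)


class TestCypAggregation:
    def frame(self, p2c9, p2d6, p3a4):
        return pd.DataFrame(
            {
                "cyp450_2c9_substrate": [p2c9],
                "cyp450_2d6_substrate": [p2d6],
                "cyp450_3a4_substrate": [p3a4],
            }
        )

    def test_weighted_soft_vote_hand_examples(self):
        config = CypAggregationConfig(method="weighted_soft_vote")
        calls, scores = cyp_aggregate(self.frame(1.0, 1.0, 0.0), config)
        assert scores[0] == pytest.approx((0.12 + 0.04) / 0.46, abs=1e-9)
        assert calls[0] == 0
        calls, scores = cyp_aggregate(self.frame(0.0, 0.0, 1.0), config)
        assert scores[0] == pytest.approx(0.30 / 0.46, abs=1e-9)
        assert calls[0] == 1

    def test_equal_weights_is_unweighted_mean(self):
        config = CypAggregationConfig(
            method="weighted_soft_vote",
            weights={"cyp450_2c9_substrate": 1.0, "cyp450_2d6_substrate": 1.0, "cyp450_3a4_substrate": 1.0},
        )
        _, scores = cyp_aggregate(self.frame(0.2, 0.4, 0.9), config)
        assert scores[0] == pytest.approx((0.2 + 0.4 + 0.9) / 3)

    def test_single_weight_is_passthrough(self):
        config = CypAggregationConfig(
            method="weighted_soft_vote",
            weights={"cyp450_2c9_substrate": 0.0, "cyp450_2d6_substrate": 0.0, "cyp450_3a4_substrate": 1.0},
        )
        _, scores = cyp_aggregate(self.frame(0.2, 0.4, 0.9), config)
        assert scores[0] == pytest.approx(0.9)

    def test_cyp3a4_direct(self):
        config = CypAggregationConfig(method="cyp3a4_direct")
        calls, scores = cyp_aggregate(self.frame(0.1, 0.1, 0.9), config)
        assert scores[0] == pytest.approx(0.9)
        assert calls[0] == 1

    def test_missing_column_is_hard_error(self):
        frame = pd.DataFrame({"cyp450_3a4_substrate": [0.5]})
        with pytest.raises(KeyError, match="cyp450_2c9_substrate"):
            cyp_aggregate(frame, CypAggregationConfig())

    def test_dnn_synthesis_learns_a_separable_rule(self):
        rng = np.random.default_rng(0)
        X = rng.random((400, 3))
        y = (X @ np.array([0.2, 0.1, 0.7]) > 0.5).astype(int)
        clf = CypSynthesisClassifier(random_state=0).fit(X[:300], y[:300])
        scores = clf.predict_proba(X[300:])
        assert auroc(scores, y[300:]) > 0.9
        frame = pd.DataFrame(X[300:], columns=list(CypAggregationConfig().weights))
        calls, agg_scores = cyp_aggregate(frame, CypAggregationConfig(method="dnn_synthesis"), synthesizer=clf)
        np.testing.assert_allclose(agg_scores, scores)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            CypAggregationConfig(weights={"cyp450_3a4_substrate": -0.1})


class TestMatchedProportion:
    def test_boundary_cases(self):
        assert matched_proportion([1, 0, 1], [1, 0, 1]) == 1.0
        assert matched_proportion([1, 0, 1], [0, 1, 0]) == 0.0

    def test_reported_external_style_value(self):
        """53 agreements out of 84 compounds gives 0.631 to three decimals."""
        calls = np.zeros(84, dtype=int)
        reference = np.concatenate([np.zeros(53, dtype=int), np.ones(31, dtype=int)])
        assert matched_proportion(calls, reference) == pytest.approx(53 / 84)
        assert round(matched_proportion(calls, reference), 3) == 0.631

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            matched_proportion([1, 0], [1, 0, 1])


class TestEvaluatePredictions:
    def test_report_shapes_and_macro(self):
        rng = np.random.default_rng(3)
        probs = rng.random((50, 4))
        labels = rng.integers(0, 2, size=(50, 4))
        report = evaluate_predictions(probs, labels, ["a", "b", "c", "d"])
        assert list(report.per_label.index) == ["a", "b", "c", "d"]
        macro = report.macro()
        assert set(macro) == {"accuracy", "auroc", "f1", "precision", "recall"}
        assert all(v is None or 0 <= v <= 1 for v in macro.values())

    def test_json_and_csv_outputs(self, tmp_path):
        rng = np.random.default_rng(4)
        report = evaluate_predictions(rng.random((20, 2)), rng.integers(0, 2, size=(20, 2)), ["p", "q"])
        report.to_json(tmp_path / "m.json")
        report.to_csv(tmp_path / "m.csv")
        assert (tmp_path / "m.json").stat().st_size > 0
        assert (tmp_path / "m.csv").stat().st_size > 0
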
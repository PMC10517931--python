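"""Patient voting, balanced metrics and the flat baseline."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef

from expertdt.evaluation import (
    balanced_accuracy,
    confusion_matrix_from,
    evaluate_cohort,
    matthews_cc,
    patient_vote,
)
from expertdt.labels import NOT_TUMOR, NO_TUMOR, SUBTYPES


class TestPatientVote:
    def test_not_tumor_tiles_are_excluded(self):
        votes = ["ccRCC"] * 10 + ["papRCC"] * 5 + [NOT_TUMOR] * 100
        assert patient_vote(votes) == "ccRCC"

    def test_only_not_tumor_gives_no_tumor_outcome(self):
        assert patient_vote([NOT_TUMOR] * 50) == NO_TUMOR

    def test_tie_breaks_by_prevalence_order(self, caplog):
        with caplog.at_level("WARNING"):
            winner = patient_vote(["chrRCC"] * 7 + ["ONCO"] * 7)
        assert winner == "chrRCC"
        assert "tie" in caplog.text

    def test_invariant_to_order_and_extra_nt(self):
        rng = np.random.default_rng(0)
        votes = ["papRCC"] * 8 + ["ccRCC"] * 5
        shuffled = list(rng.permutation(votes)) + [NOT_TUMOR] * 37
        assert patient_vote(votes) == patient_vote(shuffled) == "papRCC"

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            patient_vote([])


class TestBalancedAccuracy:
    def test_perfect_diagonal_on_uneven_counts(self):
        cm = np.diag([23, 7, 3, 4])
        ba, std = balanced_accuracy(cm)
        assert ba == 1.0 and std == 0.0

    def test_hand_computed_two_class_case(self):
        ba, _ = balanced_accuracy(np.array([[2, 0], [1, 1]]))
        assert ba == pytest.approx(0.75)

    def test_invariant_under_class_permutation(self):
        rng = np.random.default_rng(3)
        cm = rng.integers(1, 20, (4, 4))
        perm = rng.permutation(4)
        ba1, _ = balanced_accuracy(cm)
        ba2, _ = balanced_accuracy(cm[np.ix_(perm, perm)])
        assert ba1 == pytest.approx(ba2)

    def test_empty_true_class_raises(self):
        cm = np.array([[3, 0], [0, 0]])
        with pytest.raises(ValueError, match="1"):
            balanced_accuracy(cm)

    def test_std_is_population_not_sample(self):
        cm = np.array([[1, 1], [0, 2]])  # recalls 0.5, 1.0
        _, std = balanced_accuracy(cm)
        assert std == pytest.approx(0.25)


class TestMatthewsCC:
    def test_perfect_diagonal_is_exactly_one(self):
        assert matthews_cc(np.diag([23, 7, 3, 4])) == 1.0

    def test_independence_is_zero(self):
        assert matthews_cc(np.array([[5, 5], [5, 5]])) == 0.0

    def test_degenerate_matrix_returns_zero_with_warning(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[1, 1] = 10  # all mass in one true AND one predicted class
        with pytest.warns(UserWarning, match="degenerate"):
            assert matthews_cc(cm) == 0.0

    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            truth = rng.integers(0, k, 60)
            pred = rng.integers(0, k, 60)
            classes = [str(i) for i in range(k)]
            cm = confusion_matrix_from(
                [classes[t] for t in truth], [classes[p] for p in pred], classes
            )
            expected = matthews_corrcoef(truth, pred)
            assert matthews_cc(cm) == pytest.approx(expected, abs=1e-12)

    def test_balanced_accuracy_matches_sklearn(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            truth = rng.integers(0, k, 80)
            pred = rng.integers(0, k, 80)
            if len(set(truth)) < k:
                continue
            classes = [str(i) for i in range(k)]
            cm = confusion_matrix_from(
                [classes[t] for t in truth], [classes[p] for p in pred], classes
            )
            ba, _ = balanced_accuracy(cm)
            assert ba == pytest.approx(balanced_accuracy_score(truth, pred), abs=1e-12)


class TestEvaluateCohort:
    def _cohort(self):
        truth = {}
        for i, s in enumerate(SUBTYPES):
            for j in range(3):
                truth[f"{s}{j}"] = s
        return truth

    def test_all_correct_has_empty_misclassified_list(self):
        truth = self._cohort()
        report = evaluate_cohort(dict(truth), truth)
        assert report.misclassified == []
        assert report.balanced_accuracy == 1.0
        assert report.mcc == 1.0
        assert report.confusion.sum() == len(truth)

    def test_misclassified_patients_are_listed(self):
        truth = self._cohort()
        preds = dict(truth)
        for j in range(2):
            preds[f"ccRCC{j}"] = "papRCC"
        report = evaluate_cohort(preds, truth)
        assert sorted(report.misclassified) == ["ccRCC0", "ccRCC1"]
        assert report.confusion[0, 1] == 2

    def test_swapping_arguments_transposes_the_matrix(self):
        truth = self._cohort()
        rng = np.random.default_rng(4)
        preds = {pid: str(rng.choice(SUBTYPES)) for pid in truth}
        a = evaluate_cohort(preds, truth)
        b = evaluate_cohort(truth, preds)
        assert np.array_equal(a.confusion, b.confusion.T)

    def test_no_tumor_counts_reported_separately_and_penalize_recall(self):
        truth = self._cohort()
        preds = dict(truth)
        preds["ONCO0"] = NO_TUMOR
        report = evaluate_cohort(preds, truth)
        assert report.no_tumor_counts.tolist() == [0, 0, 0, 1]
        assert report.confusion.sum() == len(truth) - 1
        onco = list(SUBTYPES).index("ONCO")
        assert report.per_class_recall[onco] == pytest.approx(2 / 3)

    def test_patient_id_mismatch_raises_listing_offenders(self):
        truth = self._cohort()
        preds = dict(truth)
        preds.pop("ONCO0")
        with pytest.raises(ValueError, match="ONCO0"):
            evaluate_cohort(preds, truth)


class TestFlatBaseline:
    def test_predicts_above_chance_on_separable_cohort(self, small_cohort, small_baseline):
        from expertdt.pipeline import evaluate_predictions, predict_cohort

        preds, _ = predict_cohort(small_baseline, small_cohort.test, small_cohort)
        report = evaluate_predictions(preds, small_cohort)
        assert report.balanced_accuracy > 0.25

    def test_missing_class_raises(self):
        from expertdt.classifiers import TrainingConfig
        from expertdt.evaluation import flat_baseline
        from test_classifiers import texture_set

        tiles = texture_set({"ccRCC": 20, "fiber": 20})
        with pytest.raises(ValueError, match="lacks"):
            flat_baseline(tiles, TrainingConfig(seed=0))
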
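"""Confusion-matrix decomposition and metric correctness."""

import numpy as np
import pytest

from dermattn.metrics import confusion_matrix, metric_report, per_class_counts, roc_auc_ovr

A_EXAMPLE = np.array([[2, 1, 0], [0, 3, 1], [1, 0, 2]])


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self, rng):
        y = rng.integers(0, 4, 50)
        mat = confusion_matrix(y, y, 4)
        assert np.all(mat == np.diag(np.bincount(y, minlength=4)))

    def test_hand_count(self):
        mat = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(mat, [[1, 1], [0, 1]])

    def test_matches_loop_oracle(self, rng):
        t = rng.integers(0, 5, 1000)
        p = rng.integers(0, 5, 1000)
        mat = confusion_matrix(t, p, 5)
        oracle = np.zeros((5, 5), dtype=int)
        for a, b in zip(t, p):
            oracle[a, b] += 1
        np.testing.assert_array_equal(mat, oracle)

    def test_out_of_range_label_error(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)


class TestPerClassCounts:
    def test_hand_counting_oracle(self):
        c = per_class_counts(A_EXAMPLE)
        np.testing.assert_array_equal(c.tp, [2, 3, 2])
        np.testing.assert_array_equal(c.fp, [1, 1, 1])
        np.testing.assert_array_equal(c.fn, [1, 1, 1])
        np.testing.assert_array_equal(c.tn, [6, 5, 6])

    def test_perfect_classifier_no_errors(self):
        c = per_class_counts(np.diag([4, 2, 9]))
        assert c.fp.sum() == 0 and c.fn.sum() == 0

    def test_conservation_identity(self, rng):
        mat = rng.integers(0, 20, size=(6, 6))
        c = per_class_counts(mat)
        np.testing.assert_array_equal(c.tp + c.fp + c.fn + c.tn, mat.sum())


class TestMetricReport:
    def test_hand_arithmetic_example(self):
        rep = metric_report(A_EXAMPLE)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.sensitivity[0] == pytest.approx(2 / 3)
        assert rep.specificity[0] == pytest.approx(6 / 7)
        assert rep.f1[0] == pytest.approx(2 / 3)

    def test_perfect_classifier_all_ones(self):
        rep = metric_report(np.diag([5, 5, 5]))
        for v in (rep.sensitivity, rep.specificity, rep.precision, rep.f1):
            np.testing.assert_allclose(v, 1.0)
        assert rep.accuracy == 1.0 and rep.balanced_accuracy == 1.0

    def test_degenerate_single_class_predictor(self):
        mat = confusion_matrix([0] * 10 + [1] * 10, [0] * 20, 2)
        rep = metric_report(mat)
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.balanced_accuracy == pytest.approx(0.5)
        assert rep.warnings  # zero-denominator cells flagged

    def test_f1_tn_compatibility_variant(self):
        rep = metric_report(A_EXAMPLE, f1_includes_tn=True)
        # 2TP/(2TP+FP+FN+TN) for class 0: 4/(4+1+1+6)
        assert rep.f1[0] == pytest.approx(4 / 12)

    def test_confusion_csv_round_trip(self, tmp_path):
        rep = metric_report(A_EXAMPLE)
        rep.save_confusion_csv(tmp_path / "cm.csv")
        back = np.loadtxt(tmp_path / "cm.csv", delimiter=",", dtype=int)
        np.testing.assert_array_equal(back, A_EXAMPLE)

    def test_permutation_invariance(self, rng):
        t = rng.integers(0, 3, 300)
        p = rng.integers(0, 3, 300)
        perm = np.array([2, 0, 1])
        rep = metric_report(confusion_matrix(t, p, 3))
        rep_p = metric_report(confusion_matrix(perm[t], perm[p], 3))
        assert rep.accuracy == pytest.approx(rep_p.accuracy)
        assert rep.macro_f1 == pytest.approx(rep_p.macro_f1)
        # class k's metrics move to position perm[k]
        np.testing.assert_allclose(rep_p.sensitivity[perm], rep.sensitivity, atol=1e-12)
        np.testing.assert_allclose(rep_p.precision[perm], rep.precision, atol=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        aucs, macro = roc_auc_ovr(y, s)
        np.testing.assert_allclose(aucs, 1.0)
        assert macro == 1.0

    def test_toy_pair_counting_oracle(self):
        y = np.array([0, 0, 1, 1])
        s1 = np.array([0.1, 0.4, 0.35, 0.8])
        s = np.column_stack([1 - s1, s1])
        # exhaustive concordant-pair oracle for class 1
        pos, neg = s1[y == 1], s1[y == 0]
        oracle = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        aucs, _ = roc_auc_ovr(y, s)
        assert aucs[1] == pytest.approx(oracle) == pytest.approx(0.75)

    def test_label_independent_scores_near_half(self, rng):
        n = 2000
        y = rng.integers(0, 2, n)
        s1 = rng.random(n)
        aucs, _ = roc_auc_ovr(y, np.column_stack([1 - s1, s1]))
        assert abs(aucs[1] - 0.5) < 0.05

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            roc_auc_ovr([1, 1], np.array([[0.4, 0.6], [0.3, 0.7]]))


class TestReferenceAgreement:
    """Agreement with scikit-learn on random multiclass problems."""

    def test_against_sklearn_100_problems(self, rng):
        from sklearn.metrics import (
            accuracy_score, confusion_matrix as sk_confusion,
            precision_recall_fscore_support, roc_auc_score,
        )
        for _ in range(100):
            c = int(rng.integers(2, 6))
            n = int(rng.integers(30, 120))
            t = rng.integers(0, c, n)
            while len(np.unique(t)) < c:  # every class present
                t = rng.integers(0, c, n)
            p = rng.integers(0, c, n)
            logits = rng.normal(size=(n, c))
            scores = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)

            mat = confusion_matrix(t, p, c)
            np.testing.assert_array_equal(mat, sk_confusion(t, p, labels=range(c)))
            rep = metric_report(mat, scores=scores, true_labels=t)
            prec, rec, f1, _ = precision_recall_fscore_support(
                t, p, labels=range(c), zero_division=0)
            np.testing.assert_allclose(rep.precision, prec, atol=1e-10)
            np.testing.assert_allclose(rep.sensitivity, rec, atol=1e-10)
            np.testing.assert_allclose(rep.f1, f1, atol=1e-10)
            assert rep.accuracy == pytest.approx(accuracy_score(t, p), abs=1e-10)
            sk_auc = [roc_auc_score((t == k).astype(int), scores[:, k]) for k in range(c)]
            np.testing.assert_allclose(rep.auc, sk_auc, atol=1e-10)
            # specificity is recall of the complementary binary problem
            sk_spec = [precision_recall_fscore_support(
                (t != k).astype(int), (p != k).astype(int), labels=[1],
                zero_division=0)[1][0] for k in range(c)]
            np.testing.assert_allclose(rep.specificity, sk_spec, atol=1e-10)
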
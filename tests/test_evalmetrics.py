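import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from savehsi.evalmetrics import (
    ConfusionMatrix,
    balanced_accuracy,
    classification_report,
    cohen_kappa,
    compare_accuracies,
    cv_mean_accuracy,
    macro_f1,
    wilson_ci,
)


def _cm_to_labels(cm: ConfusionMatrix):
    y_true, y_pred = [], []
    for i, t in enumerate(cm.class_names):
        for j, p in enumerate(cm.class_names):
            y_true += [t] * cm.counts[i, j]
            y_pred += [p] * cm.counts[i, j]
    return y_true, y_pred


HAND_CM = ConfusionMatrix(counts=[[20, 5], [10, 15]], class_names=["a", "b"])


class TestClassificationReport:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(counts=np.diag([5, 7, 9]))
        report = classification_report(cm)
        assert report["accuracy"] == 1.0
        assert all(c["precision"] == c["recall"] == c["f1"] == 1.0 for c in report["per_class"].values())

    def test_hand_computed_two_class_example(self):
        report = classification_report(HAND_CM)
        a = report["per_class"]["a"]
        assert a["precision"] == pytest.approx(20 / 30)
        assert a["recall"] == pytest.approx(0.8)
        assert a["f1"] == pytest.approx(2 * (2 / 3) * 0.8 / (2 / 3 + 0.8))
        assert report["accuracy"] == pytest.approx(0.70)

    def test_matches_sklearn_on_random_matrices(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 30, size=(3, 3))
            counts[np.diag_indices(3)] += 1  # keep every class present
            cm = ConfusionMatrix(counts=counts)
            y_true, y_pred = _cm_to_labels(cm)
            p, r, f, _ = precision_recall_fscore_support(y_true, y_pred, labels=cm.class_names, zero_division=0)
            report = classification_report(cm)
            for i, name in enumerate(cm.class_names):
                assert report["per_class"][name]["precision"] == pytest.approx(p[i])
                assert report["per_class"][name]["recall"] == pytest.approx(r[i])
                assert report["per_class"][name]["f1"] == pytest.approx(f[i])

    def test_degenerate_class_precision_warns_zero(self):
        cm = ConfusionMatrix(counts=[[0, 3], [0, 4]])
        with pytest.warns(UserWarning, match="no predicted positives"):
            report = classification_report(cm)
        assert report["per_class"]["0"]["precision"] == 0.0


class TestWilson:
    def test_boundary_proportion_collapses_to_zero(self):
        lo, hi = wilson_ci(0.0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_reproduces_printed_svm_interval(self):
        lo, hi = wilson_ci(0.794, 161)
        assert round(100 * lo, 1) == 72.5
        assert round(100 * hi, 1) == 84.9

    def test_width_shrinks_with_n(self):
        w100 = np.diff(wilson_ci(0.5, 100))[0]
        w400 = np.diff(wilson_ci(0.5, 400))[0]
        assert w400 < w100

    def test_contains_shrunk_center(self, rng):
        for _ in range(50):
            p, n = rng.uniform(0, 1), int(rng.integers(1, 500))
            lo, hi = wilson_ci(p, n)
            z2 = 1.959963984540054**2
            center = (p + z2 / (2 * n)) / (1 + z2 / n)
            assert lo - 1e-12 <= center <= hi + 1e-12

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 400))
            k = int(rng.integers(0, n + 1))
            lo, hi = wilson_ci(k / n, n)
            lo_sm, hi_sm = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(lo_sm, abs=1e-10)
            assert hi == pytest.approx(hi_sm, abs=1e-10)

    def test_coverage_in_binomial_simulation(self):
        # nominal 95% interval at p = 0.8, n = 161: empirical coverage over
        # 2000 seeded draws must stay above 93%
        rng = np.random.default_rng(2024)
        p, n, covered = 0.8, 161, 0
        for _ in range(2000):
            k = rng.binomial(n, p)
            lo, hi = wilson_ci(k / n, n)
            covered += lo <= p <= hi
        assert covered / 2000 >= 0.93

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0.5, 0)
        with pytest.raises(ValueError):
            wilson_ci(1.2, 10)


class TestKappa:
    def test_perfect_and_chance_agreement(self):
        assert cohen_kappa(ConfusionMatrix(counts=np.diag([4, 6]))) == 1.0
        assert cohen_kappa(ConfusionMatrix(counts=[[1, 1], [1, 1]])) == 0.0

    def test_hand_computed_example(self):
        assert cohen_kappa(HAND_CM) == pytest.approx(0.4)

    def test_matches_sklearn(self, rng):
        for _ in range(10):
            counts = rng.integers(1, 30, size=(3, 3))
            cm = ConfusionMatrix(counts=counts)
            y_true, y_pred = _cm_to_labels(cm)
            assert cohen_kappa(cm) == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(ConfusionMatrix(counts=[[5, 0], [0, 0]]))


class TestMacroMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(counts=np.diag([3, 3, 3]))
        assert macro_f1(cm) == 1.0 and balanced_accuracy(cm) == 1.0

    def test_hand_computed_balanced_accuracy(self):
        assert balanced_accuracy(HAND_CM) == pytest.approx((0.8 + 0.6) / 2)

    def test_class_permutation_invariance(self, rng):
        counts = rng.integers(1, 25, size=(3, 3))
        cm = ConfusionMatrix(counts=counts, class_names=["a", "b", "c"])
        perm = [2, 0, 1]
        cm_perm = ConfusionMatrix(counts=counts[np.ix_(perm, perm)], class_names=["c", "a", "b"])
        assert macro_f1(cm) == pytest.approx(macro_f1(cm_perm))
        assert balanced_accuracy(cm) == pytest.approx(balanced_accuracy(cm_perm))


class TestCompareAccuracies:
    def test_identical_proportions(self):
        assert compare_accuracies(80, 100, 80, 100) == pytest.approx(1.0)

    def test_clear_difference_is_significant(self):
        assert compare_accuracies(150, 161, 161, 161) < 0.01

    def test_symmetry(self):
        assert compare_accuracies(50, 80, 70, 90) == pytest.approx(compare_accuracies(70, 90, 50, 80))

    def test_degenerate_pooled_proportion_convention(self):
        assert compare_accuracies(0, 10, 0, 20) == 1.0
        assert compare_accuracies(10, 10, 20, 20) == 1.0

    def test_matches_statsmodels_ztest(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(20, 200)), int(rng.integers(20, 200))
            c1 = int(rng.integers(1, n1))
            c2 = int(rng.integers(1, n2))
            _, p_sm = proportions_ztest([c1, c2], [n1, n2])
            assert compare_accuracies(c1, n1, c2, n2) == pytest.approx(p_sm, abs=1e-10)


class TestCvMean:
    def test_known_values(self):
        assert cv_mean_accuracy([0.9, 0.9, 0.9]) == pytest.approx(0.9)
        assert cv_mean_accuracy([1.0, 0.0]) == pytest.approx(0.5)

    def test_matches_hand_sum(self, rng):
        vals = rng.uniform(0, 1, 7)
        assert cv_mean_accuracy(vals) == pytest.approx(sum(vals) / 7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cv_mean_accuracy([])
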
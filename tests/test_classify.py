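"""Confusion-matrix metrics, classifier training and cross-validation.

The metric operations are checked exactly against four published
confusion matrices whose overall accuracy, Cohen's kappa and per-class
sensitivities were printed alongside the raw counts (see imbef.datasets).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imbef
from imbef.datasets import (
    DRMS_AASM5,
    DRMS_RK6,
    ISRUC3_AASM5,
    SEDF_RK6,
)


class TestMetricsAgainstPublishedTables:
    @pytest.mark.parametrize("cm,accuracy_pct", [
        (DRMS_RK6, 78.92),
        (DRMS_AASM5, 79.90),
        (SEDF_RK6, 92.04),
        (ISRUC3_AASM5, 81.65),
    ])
    def test_overall_accuracy(self, cm, accuracy_pct):
        assert imbef.accuracy_from_confusion(cm) * 100 == pytest.approx(
            accuracy_pct, abs=0.005)

    @pytest.mark.parametrize("cm,kappa", [
        (SEDF_RK6, 0.8266),
        (ISRUC3_AASM5, 0.7629),
    ])
    def test_cohens_kappa(self, cm, kappa):
        assert imbef.kappa_from_confusion(cm) == pytest.approx(kappa,
                                                               abs=0.0005)

    @pytest.mark.parametrize("cm,sens_pct", [
        (DRMS_RK6, [93.68, 81.16, 14.37, 89.29, 25.71, 77.99]),
        (DRMS_AASM5, [92.89, 81.22, 17.57, 85.52, 78.79]),
        (SEDF_RK6, [99.09, 71.46, 19.32, 90.62, 46.11, 70.20]),
        (ISRUC3_AASM5, [90.31, 83.36, 57.70, 81.12, 87.50]),
    ])
    def test_per_class_sensitivity(self, cm, sens_pct):
        got = imbef.sensitivity_per_class(cm) * 100
        assert got == pytest.approx(sens_pct, abs=0.005)


class TestMetricProperties:
    def test_diagonal_matrix_metrics(self):
        cm = imbef.ConfusionMatrix(np.diag([10, 20, 30]))
        assert imbef.accuracy_from_confusion(cm) == 1.0
        assert imbef.kappa_from_confusion(cm) == pytest.approx(1.0)
        assert np.allclose(imbef.sensitivity_per_class(cm), 1.0)

    def test_uniform_matrix_kappa_zero(self):
        cm = imbef.ConfusionMatrix(np.full((4, 4), 7))
        assert imbef.kappa_from_confusion(cm) == pytest.approx(0.0, abs=1e-12)

    def test_empty_expert_row_sensitivity_missing(self):
        cm = imbef.ConfusionMatrix(np.array([[5, 1], [0, 0]]))
        sens = imbef.sensitivity_per_class(cm)
        assert np.isnan(sens[1]) and sens[0] == pytest.approx(5 / 6)

    def test_single_cell_matrix_degenerate(self):
        cm = imbef.ConfusionMatrix(np.array([[9, 0], [0, 0]]))
        with pytest.raises(ValueError, match="p_e"):
            imbef.kappa_from_confusion(cm)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=9, max_size=9),
           st.integers(0, 10))
    def test_kappa_matches_pairwise_oracle(self, cells, extra):
        # independent oracle: sklearn's kappa on the expanded label pairs
        from sklearn.metrics import cohen_kappa_score

        counts = np.array(cells, dtype=int).reshape(3, 3)
        counts[0, 0] += extra + 1  # ensure non-degenerate
        counts[1, 1] += 1
        expert, auto = [], []
        for i in range(3):
            for j in range(3):
                expert += [i] * counts[i, j]
                auto += [j] * counts[i, j]
        cm = imbef.ConfusionMatrix(counts)
        try:
            ours = imbef.kappa_from_confusion(cm)
        except ValueError:
            return  # degenerate p_e == 1; oracle undefined too
        assert ours == pytest.approx(cohen_kappa_score(expert, auto),
                                     abs=1e-12)

    def test_class_permutation_invariance(self, rng):
        counts = rng.integers(0, 40, size=(4, 4))
        counts[np.diag_indices(4)] += 10
        cm = imbef.ConfusionMatrix(counts)
        perm = rng.permutation(4)
        cm_p = imbef.ConfusionMatrix(counts[np.ix_(perm, perm)])
        assert imbef.accuracy_from_confusion(cm_p) == pytest.approx(
            imbef.accuracy_from_confusion(cm))
        assert imbef.kappa_from_confusion(cm_p) == pytest.approx(
            imbef.kappa_from_confusion(cm))
        assert np.allclose(imbef.sensitivity_per_class(cm_p),
                           imbef.sensitivity_per_class(cm)[perm])


class _Table:
    def __init__(self, matrix, labels):
        self.matrix = matrix
        self.labels = labels
        self.n_epochs = matrix.shape[0]


def _separable_table(rng, n_per_class=40, n_classes=3, dim=8, gap=8.0):
    centers = rng.standard_normal((n_classes, dim)) * gap
    X = np.vstack([centers[c] + rng.standard_normal((n_per_class, dim))
                   for c in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per_class)
    return _Table(X, y)


class TestTrainClassifier:
    def test_separable_two_class_training_accuracy(self, rng):
        table = _separable_table(rng, n_classes=2)
        clf = imbef.train_classifier(table, "bagged_trees", seed=0)
        assert np.mean(clf.predict(table.matrix) == table.labels) == 1.0

    def test_same_seed_identical_predictions(self, rng):
        table = _separable_table(rng)
        probe = rng.standard_normal((50, table.matrix.shape[1]))
        p1 = imbef.train_classifier(table, "bagged_trees", seed=7).predict(probe)
        p2 = imbef.train_classifier(table, "bagged_trees", seed=7).predict(probe)
        assert np.array_equal(p1, p2)

    def test_unknown_name_lists_supported(self, rng):
        table = _separable_table(rng)
        with pytest.raises(ValueError, match="bagged_trees"):
            imbef.train_classifier(table, "random_forest")

    def test_single_class_rejected(self, rng):
        table = _Table(rng.standard_normal((20, 4)), np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="two classes"):
            imbef.train_classifier(table, "bagged_trees")

    def test_nan_features_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        X[3, 2] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            imbef.train_classifier(_Table(X, np.arange(20) % 2),
                                   "bagged_trees")

    @pytest.mark.parametrize("name", ["linear_discriminant",
                                      "quadratic_discriminant",
                                      "quadratic_svm", "fine_knn",
                                      "bagged_trees", "rusboosted_trees"])
    def test_all_six_candidates_fit_and_predict(self, rng, name):
        table = _separable_table(rng)
        clf = imbef.train_classifier(table, name, seed=0)
        acc = np.mean(clf.predict(table.matrix) == table.labels)
        assert acc > 0.9

    def test_gui_style_alias_accepted(self, rng):
        table = _separable_table(rng)
        clf = imbef.train_classifier(table, "Bagged Trees", seed=0)
        assert clf is not None


class TestCrossValidate:
    def test_fold_partition_contract(self, rng):
        table = _separable_table(rng, n_per_class=25, n_classes=4)  # L = 100
        from sklearn.model_selection import KFold

        sizes = [len(v) for _, v in
                 KFold(10, shuffle=True, random_state=0).split(table.matrix)]
        assert sizes == [10] * 10
        report = imbef.cross_validate(table, "bagged_trees", k=10, seed=0)
        assert report.confusion.total == 100
        assert len(report.fold_accuracies) == 10

    def test_separable_data_high_pooled_accuracy(self, rng):
        table = _separable_table(rng, n_per_class=40, n_classes=3)
        report = imbef.cross_validate(table, "bagged_trees", k=10, seed=0)
        assert report.accuracy > 0.9

    def test_shuffled_labels_at_chance(self, rng):
        # Bayes-optimal accuracy is 1/C once labels are shuffled
        n_classes = 4
        X = rng.standard_normal((2000, 6))
        y = rng.permutation(np.repeat(np.arange(n_classes), 500))
        report = imbef.cross_validate(_Table(X, y), "bagged_trees", k=10,
                                      seed=1)
        assert report.accuracy == pytest.approx(1 / n_classes, abs=0.03)

    def test_accuracy_equals_trace_over_total(self, rng):
        table = _separable_table(rng, n_per_class=20)
        report = imbef.cross_validate(table, "fine_knn", k=5, seed=2)
        cm = report.confusion
        assert report.accuracy == pytest.approx(
            np.trace(cm.counts) / cm.total)

    def test_invalid_fold_counts(self, rng):
        table = _separable_table(rng, n_per_class=3, n_classes=2)
        with pytest.raises(ValueError):
            imbef.cross_validate(table, k=1)
        with pytest.raises(ValueError):
            imbef.cross_validate(table, k=50)
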
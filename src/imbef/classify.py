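"""Classifier training, k-fold cross-validation and confusion-matrix metrics.

Six candidate classifiers are supported by name: linear discriminant,
quadratic discriminant, quadratic-kernel SVM, fine (1-nearest-neighbour)
KNN, bagged decision trees (the default) and RUS-boosted trees.  Evaluation
follows plain 10-fold cross-validation with uniform random fold assignment;
the reported metrics come from the confusion matrix pooled over the ten
out-of-fold predictions.

Metrics: overall accuracy is trace/total of the confusion matrix (which
reduces to (TP+TN)/(TP+TN+FP+FN) in the two-class case); Cohen's kappa is
(p_o - p_e)/(1 - p_e) with the chance agreement p_e computed from the row
and column marginals; per-class sensitivity is the diagonal cell over its
expert-row total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = expert scoring, columns = automatic classification."""

    counts: np.ndarray
    class_names: tuple = ()

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0) or not np.all(counts == np.round(counts)):
            raise ValueError("confusion matrix entries must be counts")
        counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        if not self.class_names:
            object.__setattr__(
                self, "class_names",
                tuple(f"class{i}" for i in range(counts.shape[0])),
            )
        elif len(self.class_names) != counts.shape[0]:
            raise ValueError("one class name per row required")

    @classmethod
    def from_predictions(cls, expert, automatic, n_classes: int | None = None,
                         class_names=()):
        expert = np.asarray(expert, dtype=int)
        automatic = np.asarray(automatic, dtype=int)
        if n_classes is None:
            n_classes = int(max(expert.max(), automatic.max())) + 1
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (expert, automatic), 1)
        return cls(counts, tuple(class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]


def accuracy_from_confusion(cm: ConfusionMatrix) -> float:
    """Overall agreement fraction, trace/total."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def kappa_from_confusion(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from the matrix marginals."""
    total = cm.total
    if total < 1:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / total
    p_e = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / total ** 2
    if p_e >= 1.0:
        raise ValueError("degenerate matrix: chance agreement p_e = 1")
    return (p_o - p_e) / (1.0 - p_e)


def sensitivity_per_class(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall; NaN where the expert row is empty."""
    row_totals = cm.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.diag(cm.counts) / row_totals
    sens[row_totals == 0] = np.nan
    return sens


class RUSBoostedTrees(BaseEstimator, ClassifierMixin):
    """Boosted decision trees on a class-balanced random undersample.

    The majority classes are randomly undersampled to the minority count
    (seeded) before AdaBoost with tree learners — the usual recipe for
    boosting under class imbalance.
    """

    def __init__(self, n_estimators: int = 30, max_depth: int | None = None,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        m = counts.min()
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=m, replace=False)
            for c in classes
        ])
        keep.sort()
        self.booster_ = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=self.max_depth,
                                             random_state=0),
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )
        self.booster_.fit(X[keep], y[keep])
        self.classes_ = self.booster_.classes_
        return self

    def predict(self, X):
        return self.booster_.predict(X)


#: canonical classifier names (aliases with spaces/case accepted)
CLASSIFIER_NAMES = (
    "linear_discriminant",
    "quadratic_discriminant",
    "quadratic_svm",
    "fine_knn",
    "bagged_trees",
    "rusboosted_trees",
)

DEFAULT_CLASSIFIER = "bagged_trees"
DEFAULT_N_TREES = 30


def make_classifier(name: str, seed: int = 0, **hyper):
    """Build an unfitted classifier by (normalized) name."""
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    if key not in CLASSIFIER_NAMES:
        raise ValueError(
            f"unknown classifier {name!r}; supported: {CLASSIFIER_NAMES}"
        )
    if key == "linear_discriminant":
        return LinearDiscriminantAnalysis(**hyper)
    if key == "quadratic_discriminant":
        return QuadraticDiscriminantAnalysis(**hyper)
    if key == "quadratic_svm":
        hyper.setdefault("kernel", "poly")
        hyper.setdefault("degree", 2)
        hyper.setdefault("coef0", 1.0)
        return SVC(random_state=seed, **hyper)
    if key == "fine_knn":
        hyper.setdefault("n_neighbors", 1)
        return KNeighborsClassifier(**hyper)
    if key == "bagged_trees":
        hyper.setdefault("n_estimators", DEFAULT_N_TREES)
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=0),
            random_state=seed,
            **hyper,
        )
    return RUSBoostedTrees(random_state=seed, **hyper)


def train_classifier(ft, spec: str = DEFAULT_CLASSIFIER, seed: int = 0, **hyper):
    """Fit the named classifier on a labelled feature table."""
    if ft.labels is None:
        raise ValueError("feature table carries no labels")
    if np.unique(ft.labels).size < 2:
        raise ValueError("training requires at least two classes")
    if not np.all(np.isfinite(ft.matrix)):
        raise ValueError("feature matrix contains NaN/inf values")
    clf = make_classifier(spec, seed=seed, **hyper)
    clf.fit(ft.matrix, ft.labels)
    return clf


@dataclass(frozen=True)
class EvalReport:
    """Cross-validated evaluation summary."""

    accuracy: float  # pooled out-of-fold, fraction in [0, 1]
    kappa: float
    sensitivity: np.ndarray  # per-class fractions
    confusion: ConfusionMatrix
    fold_accuracies: tuple
    protocol: str

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "sensitivity": [None if np.isnan(s) else float(s)
                            for s in self.sensitivity],
            "confusion": self.confusion.counts.tolist(),
            "class_names": list(self.confusion.class_names),
            "fold_accuracies": list(self.fold_accuracies),
            "mean_fold_accuracy": self.mean_fold_accuracy,
            "protocol": self.protocol,
        }


def cross_validate(ft, spec: str = DEFAULT_CLASSIFIER, k: int = 10,
                   seed: int = 0, stratified: bool = False,
                   class_names=(), **hyper) -> EvalReport:
    """k-fold cross-validation with a pooled out-of-fold confusion matrix.

    Every epoch is validated exactly once; fold sizes differ by at most one.
    """
    if ft.labels is None:
        raise ValueError("feature table carries no labels")
    L = ft.n_epochs
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > L:
        raise ValueError(f"k={k} folds but only {L} epochs")
    X, y = ft.matrix, ft.labels
    n_classes = int(y.max()) + 1
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=k, shuffle=True, random_state=seed
    )
    predictions = np.empty(L, dtype=int)
    fold_accs = []
    split_args = (X, y) if stratified else (X,)
    for train_idx, val_idx in splitter.split(*split_args):
        clf = make_classifier(spec, seed=seed, **hyper)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[val_idx])
        predictions[val_idx] = pred
        fold_accs.append(float(np.mean(pred == y[val_idx])))
    cm = ConfusionMatrix.from_predictions(y, predictions, n_classes=n_classes,
                                          class_names=class_names)
    return EvalReport(
        accuracy=accuracy_from_confusion(cm),
        kappa=kappa_from_confusion(cm),
        sensitivity=sensitivity_per_class(cm),
        confusion=cm,
        fold_accuracies=tuple(fold_accs),
        protocol=f"{k}-fold CV, {'stratified' if stratified else 'uniform'} "
                 f"random folds, seed={seed}, classifier={spec}",
    )
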
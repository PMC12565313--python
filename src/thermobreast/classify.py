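"""Classifier training and stratified k-fold evaluation.

Four classical model families are supported, chosen for interpretability
on small imbalanced tabular cohorts:

``l-svm``
    Support vector machine with a linear kernel (unit box constraint).
``q-svm``
    SVM with an inhomogeneous degree-2 polynomial kernel, i.e. a
    quadratic decision surface.
``lr``
    Plain binary logistic regression fitted by maximum likelihood
    (negligible regularization).
``ct``
    A "coarse" CART decision tree capped at 4 internal splits (Gini
    impurity), deliberately shallow to favour generalization.

SVMs and logistic regression standardize features to zero mean and unit
variance *within each training fold*; the tree is scale-invariant and
trains on raw features.  The positive class is ``"A"`` (thermal anomaly),
so recall tracks cancer sensitivity.

Evaluation metrics follow the confusion-count forms

    accuracy    = (TP + TN) / (TN + FP + FN + TP)
    precision   = TP / (FP + TP)
    recall      = TP / (FN + TP)
    specificity = TN / (TN + FP)
    F1          = TP / (TP + (FP + FN) / 2)

with an undefined ratio (zero denominator) reported as 0 and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_KINDS",
    "POSITIVE_LABEL",
    "FoldPlan",
    "ConfusionCounts",
    "MetricSet",
    "CvRun",
    "make_classifier",
    "stratified_kfold",
    "compute_metrics",
    "cross_validate",
]

CLASSIFIER_KINDS: tuple[str, ...] = ("l-svm", "q-svm", "lr", "ct")
POSITIVE_LABEL = "A"
METRIC_NAMES: tuple[str, ...] = ("accuracy", "precision", "recall", "specificity", "f1")

#: internal splits allowed in the coarse tree (= max_leaf_nodes - 1)
COARSE_TREE_MAX_SPLITS = 4


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition of the samples into k folds.

    ``assignments[i]`` is the fold index of sample ``i``.  ``grouping``
    records whether folds were stratified per breast sample or kept whole
    subjects together (leakage-free mode).
    """

    k: int
    assignments: np.ndarray
    seed: int
    grouping: Literal["sample", "subject"] = "sample"

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(
        cls, y_true: Sequence, y_pred: Sequence, positive=POSITIVE_LABEL
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            TP=int(np.sum(yt & yp)),
            TN=int(np.sum(~yt & ~yp)),
            FP=int(np.sum(~yt & yp)),
            FN=int(np.sum(yt & ~yp)),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Metric suite from confusion counts; undefined ratios are reported
    as 0 and listed in ``undefined``."""
    if c.total <= 0:
        raise ValueError("confusion counts are empty")
    undefined: list[str] = []
    return MetricSet(
        accuracy=(c.TP + c.TN) / c.total,
        precision=_ratio(c.TP, c.FP + c.TP, "precision", undefined),
        recall=_ratio(c.TP, c.FN + c.TP, "recall", undefined),
        specificity=_ratio(c.TN, c.TN + c.FP, "specificity", undefined),
        f1=_ratio(c.TP, c.TP + (c.FP + c.FN) / 2.0, "f1", undefined),
        undefined=tuple(undefined),
    )


def make_classifier(kind: str, **hyperparams):
    """Fresh (unfitted) estimator of the requested kind.

    Keyword overrides are forwarded to the underlying scikit-learn
    estimator (e.g. ``C=10`` for the SVMs).
    """
    if kind == "l-svm":
        est = SVC(kernel="linear", C=1.0, **hyperparams)
    elif kind == "q-svm":
        est = SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, **hyperparams)
    elif kind == "lr":
        est = LogisticRegression(C=1e6, max_iter=5000, **hyperparams)
    elif kind == "ct":
        est = DecisionTreeClassifier(
            max_leaf_nodes=COARSE_TREE_MAX_SPLITS + 1,
            criterion="gini",
            random_state=0,
            **hyperparams,
        )
        return est  # trees are scale-invariant: no standardization
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def stratified_kfold(
    labels: Sequence,
    k: int = 5,
    seed: int = 20251013,
    grouping: Literal["sample", "subject"] = "sample",
    groups: Sequence | None = None,
) -> FoldPlan:
    """Deterministic class-proportional fold assignment.

    Sample-level stratification keeps every fold's class counts within one
    sample of perfect proportionality.  Subject-level grouping
    additionally keeps both breasts of a subject in the same fold
    (``groups`` = subject ids), trading exact proportionality for
    leakage-free validation.
    """
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (one fold must be held out)")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples; needs >= k={k}")
    assignments = np.empty(len(y), dtype=int)
    if grouping == "sample":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y)
    elif grouping == "subject":
        if groups is None:
            raise ValueError("subject-level grouping requires groups (subject ids)")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y, groups=np.asarray(groups))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    for fold, (_, test_idx) in enumerate(split):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed, grouping=grouping)


@dataclass
class CvRun:
    """One classifier's cross-validation outcome: per-fold confusion
    counts and metrics, their across-fold mean and standard deviation
    (sample SD over folds), and the pooled out-of-fold predictions."""

    kind: str
    plan: FoldPlan
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[MetricSet]
    predictions: pd.DataFrame  # columns: sample, fold, y_true, y_pred

    @property
    def pooled_counts(self) -> ConfusionCounts:
        total = self.fold_counts[0]
        for c in self.fold_counts[1:]:
            total = total + c
        return total

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {
            m: float(np.mean([fm.as_dict()[m] for fm in self.fold_metrics]))
            for m in METRIC_NAMES
        }

    @property
    def sd_metrics(self) -> dict[str, float]:
        return {
            m: float(np.std([fm.as_dict()[m] for fm in self.fold_metrics], ddof=1))
            for m in METRIC_NAMES
        }


def _drop_constant_columns(X_train: np.ndarray, X_test: np.ndarray, names):
    keep = X_train.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant feature column(s) dropped in fold: {dropped}")
    return X_train[:, keep], X_test[:, keep]


def cross_validate(
    kind: str,
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    plan: FoldPlan,
    positive: str = POSITIVE_LABEL,
    **hyperparams,
) -> CvRun:
    """Fit/predict the classifier across the fold plan.

    Every sample is predicted exactly once, by the model trained on the
    other k-1 folds; standardization (where applicable) is fitted on the
    training folds only.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y)
    if len(yv) != len(Xv) or len(yv) != len(plan.assignments):
        raise ValueError("fold plan does not cover the feature table")

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[MetricSet] = []
    pred_rows = []
    for fold in range(plan.k):
        test_idx = plan.test_indices(fold)
        train_idx = np.flatnonzero(plan.assignments != fold)
        if len(np.unique(yv[train_idx])) < 2:
            raise ValueError(f"fold {fold}: training data contains a single class")
        X_tr, X_te = _drop_constant_columns(Xv[train_idx], Xv[test_idx], names)
        model = make_classifier(kind, **hyperparams)
        model.fit(X_tr, yv[train_idx])
        y_pred = model.predict(X_te)
        counts = ConfusionCounts.from_predictions(yv[test_idx], y_pred, positive)
        fold_counts.append(counts)
        fold_metrics.append(compute_metrics(counts))
        pred_rows.append(
            pd.DataFrame(
                {"sample": test_idx, "fold": fold, "y_true": yv[test_idx], "y_pred": y_pred}
            )
        )
    predictions = pd.concat(pred_rows, ignore_index=True).sort_values("sample")
    predictions = predictions.reset_index(drop=True)
    return CvRun(
        kind=kind,
        plan=plan,
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        predictions=predictions,
    )
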
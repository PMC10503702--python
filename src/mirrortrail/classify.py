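"""Five classifier families under repeated hold-out and leave-one-out.

Cohort discrimination (CC vs SU, or CAARMS = 0 vs CAARMS > 0 within SU) uses
five classifier families: cosine-distance k-nearest neighbours, Gaussian
naive Bayes, linear-kernel SVM, bagged decision trees, and linear
discriminant analysis.  Every classifier consumes z-scored features; scaling
statistics, feature selection and model fitting all use the training split
only.

Feature selection per training split: ``mode=3`` keeps the feature with the
largest |Cliff's delta| from each task group (TMT, Solo, Leader-Follower);
``mode=2`` drops the Solo slot; ``mode=18`` keeps everything.  Ties within a
group resolve to the earlier feature in canonical order, deterministically.

Two evaluation protocols:

* repeated stratified 25% hold-out (8 of 32 per class held out, 1000 folds
  by default) summarised by per-metric medians and 2.5-97.5 centiles;
* leave-one-out, with per-left-out predictions pooled into one confusion
  matrix and AUC computed from the pooled scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .effects import cliffs_delta
from .errors import DegenerateInputError, InvalidArgumentError
from .records import FEATURE_GROUPS, FEATURE_NAMES

CLASSIFIER_KINDS = ("knn", "naive_bayes", "svm", "bagged_trees", "linear_discriminant")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier variant: family, feature-selection mode, hyperparameters."""

    kind: str
    feature_mode: int = 3  # 2, 3 or 18
    k: int = 1  # kNN neighbour count
    n_trees: int = 100  # bagged-trees ensemble size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise InvalidArgumentError(f"unknown classifier kind {self.kind!r}")
        if self.feature_mode not in (2, 3, 18):
            raise InvalidArgumentError("feature_mode must be 2, 3 or 18")


#: The eight variants reported in the study's results table.
CLASSIFIER_ROSTER: dict[str, ClassifierSpec] = {
    "kNN": ClassifierSpec("knn", feature_mode=18),
    "kNN3": ClassifierSpec("knn", feature_mode=3),
    "NB": ClassifierSpec("naive_bayes", feature_mode=3),
    "SVM": ClassifierSpec("svm", feature_mode=3),
    "BT": ClassifierSpec("bagged_trees", feature_mode=3),
    "LD": ClassifierSpec("linear_discriminant", feature_mode=18),
    "LD3": ClassifierSpec("linear_discriminant", feature_mode=3),
    "LD2": ClassifierSpec("linear_discriminant", feature_mode=2),
}


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    tp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.tp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tn + other.tn, self.fp + other.fp,
                               self.tp + other.tp, self.fn + other.fn)


@dataclass
class FoldRecord:
    """Everything the no-leakage audit needs to recompute one fold."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    selected_features: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    confusion: ConfusionMatrix
    metrics: dict[str, float]


@dataclass
class EvalSummary:
    """Result of one (classifier, protocol, labelling) evaluation."""

    protocol: str  # "holdout" | "loo"
    n_folds: int
    medians: dict[str, float]
    centiles_low: dict[str, float]
    centiles_high: dict[str, float]
    folds: list[FoldRecord] = field(default_factory=list)
    pooled_confusion: Optional[ConfusionMatrix] = None
    pooled_metrics: dict[str, float] = field(default_factory=dict)


METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "precision")


# --------------------------------------------------------------------------
# Elementary operations


def select_features(
    train_features: pd.DataFrame, train_labels: np.ndarray, mode: int
) -> tuple[str, ...]:
    """Feature names chosen on the training split only.

    mode 18: all features in canonical order.  mode 3: within each of TMT,
    Solo and LF, the feature maximising |Cliff's delta| between the two
    training classes.  mode 2: same but skipping the Solo group.
    """
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise DegenerateInputError("training labels must contain both classes")
    if mode == 18:
        return tuple(FEATURE_NAMES)
    groups = ["TMT", "LF"] if mode == 2 else ["TMT", "Solo", "LF"]
    chosen = []
    for group in ("TMT", "Solo", "LF"):
        if group not in groups:
            continue
        names = FEATURE_GROUPS[group]
        deltas = [
            abs(cliffs_delta(train_features[n].to_numpy()[y == classes[1]],
                             train_features[n].to_numpy()[y == classes[0]]))
            for n in names
        ]
        chosen.append(names[int(np.argmax(deltas))])  # first max wins ties
    return tuple(chosen)


def make_estimator(spec: ClassifierSpec):
    """A fresh scikit-learn estimator for the given spec."""
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="cosine")
    if spec.kind == "naive_bayes":
        return GaussianNB()
    if spec.kind == "svm":
        return SVC(kernel="linear", C=1.0)
    if spec.kind == "bagged_trees":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_features="sqrt", min_samples_leaf=1,
            bootstrap=True, random_state=spec.seed)
    if spec.kind == "linear_discriminant":
        return LinearDiscriminantAnalysis()
    raise InvalidArgumentError(spec.kind)


def train_and_score(
    spec: ClassifierSpec,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on (already z-scored, already selected) training features and
    return ``(predicted labels, scores)`` for the test rows, scores oriented
    toward the positive (larger-label) class."""
    est = make_estimator(spec)
    est.fit(train_x, train_y)
    pred = est.predict(test_x)
    pos = est.classes_[-1]
    if hasattr(est, "decision_function"):
        scores = np.asarray(est.decision_function(test_x), dtype=float)
    else:
        proba = est.predict_proba(test_x)
        scores = proba[:, list(est.classes_).index(pos)]
    return pred, scores


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision; NaN where undefined."""
    if cm.total == 0:
        raise InvalidArgumentError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
        "precision": ratio(cm.tp, cm.tp + cm.fp),
    }


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC AUC: P(score_pos > score_neg) with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidArgumentError("AUC needs both classes present")
    pos = y == classes[-1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = sstats.rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Fold machinery


def zscore_fit(train_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Training-set mean and (unbiased) std per column; zero stds guarded."""
    mean = train_x.mean(axis=0)
    std = train_x.std(axis=0, ddof=1)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def run_fold(
    features: pd.DataFrame,
    labels: np.ndarray,
    spec: ClassifierSpec,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[FoldRecord, np.ndarray, np.ndarray]:
    """Scale, select, fit and score one train/test split.

    Returns the fold record plus raw (scores, predictions) for pooling.
    """
    y = np.asarray(labels)
    train_f = features.iloc[train_idx]
    selected = select_features(train_f, y[train_idx], spec.feature_mode)
    train_x = train_f[list(selected)].to_numpy(dtype=float)
    mean, std = zscore_fit(train_x)
    train_z = (train_x - mean) / std
    test_x = features.iloc[test_idx][list(selected)].to_numpy(dtype=float)
    test_z = (test_x - mean) / std
    pred, scores = train_and_score(spec, train_z, y[train_idx], test_z)
    y_test = y[test_idx]
    pos = np.max(y)
    cm = ConfusionMatrix(
        tn=int(np.sum((y_test != pos) & (pred != pos))),
        fp=int(np.sum((y_test != pos) & (pred == pos))),
        tp=int(np.sum((y_test == pos) & (pred == pos))),
        fn=int(np.sum((y_test == pos) & (pred != pos))),
    )
    metrics = confusion_metrics(cm)
    if len(np.unique(y_test)) == 2:
        metrics["auc"] = auc(scores, y_test)
    record = FoldRecord(
        train_indices=np.asarray(train_idx),
        test_indices=np.asarray(test_idx),
        selected_features=selected,
        scaler_mean=mean,
        scaler_std=std,
        confusion=cm,
        metrics=metrics,
    )
    return record, scores, pred


def evaluate_holdout(
    features: pd.DataFrame,
    labels: np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 1000,
    per_class_holdout: int = 8,
    seed: int = 0,
) -> EvalSummary:
    """Repeated stratified hold-out: ``per_class_holdout`` participants per
    class held out at random per fold, summarised by fold-metric medians and
    2.5-97.5 centiles."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidArgumentError("labels must be binary")
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    for idx in idx_by_class:
        if len(idx) <= per_class_holdout:
            raise InvalidArgumentError("class too small for the requested hold-out")
    rng = np.random.default_rng(seed)
    folds: list[FoldRecord] = []
    for _ in range(n_folds):
        test = np.concatenate([
            rng.choice(idx, size=per_class_holdout, replace=False)
            for idx in idx_by_class
        ])
        train = np.setdiff1d(np.arange(len(y)), test)
        record, _, _ = run_fold(features, y, spec, train, test)
        folds.append(record)
    medians, lo, hi = {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array([f.metrics.get(m, np.nan) for f in folds])
        medians[m] = float(np.nanmedian(vals))
        lo[m] = float(np.nanpercentile(vals, 2.5))
        hi[m] = float(np.nanpercentile(vals, 97.5))
    return EvalSummary(protocol="holdout", n_folds=n_folds, medians=medians,
                       centiles_low=lo, centiles_high=hi, folds=folds)


def evaluate_loo(
    features: pd.DataFrame, labels: np.ndarray, spec: ClassifierSpec
) -> EvalSummary:
    """Leave-one-out: n fits, predictions pooled into one confusion matrix,
    AUC from the pooled scores."""
    y = np.asarray(labels)
    n = len(y)
    if n < 4 or len(np.unique(y)) != 2:
        raise InvalidArgumentError("need n >= 4 with both classes present")
    folds: list[FoldRecord] = []
    scores = np.empty(n)
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        test = np.array([i])
        train = np.setdiff1d(np.arange(n), test)
        record, s, p = run_fold(features, y, spec, train, test)
        folds.append(record)
        scores[i] = s[0]
        preds[i] = p[0]
    pos = np.max(y)
    cm = ConfusionMatrix(
        tn=int(np.sum((y != pos) & (preds != pos))),
        fp=int(np.sum((y != pos) & (preds == pos))),
        tp=int(np.sum((y == pos) & (preds == pos))),
        fn=int(np.sum((y == pos) & (preds != pos))),
    )
    metrics = confusion_metrics(cm)
    metrics["auc"] = auc(scores, y)
    return EvalSummary(protocol="loo", n_folds=n, medians={}, centiles_low={},
                       centiles_high={}, folds=folds, pooled_confusion=cm,
                       pooled_metrics=metrics)
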
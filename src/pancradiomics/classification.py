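"""Seven-classifier bank with recursive feature elimination (RFE).

The bank trains Naive Bayes, k-nearest-neighbor, a nearest-class-centroid
rule (the supervised reading of "K-Means"), a linear-kernel SVM, linear
regression thresholded at 0.5 on a 0/1 response, bagged decision trees
(50 trees) and linear discriminant analysis.  Features are z-scored with
training-set statistics inside every model (the test set is transformed
with the training mean/SD only, so no information leaks across the split).

RFE iteratively drops the lowest-ranked features until at most
``max_features`` (default 5) survive, then refits on the survivors.  The
ranking rule is the absolute standardized model coefficient where the
method has coefficients (SVM, linear regression, LDA), impurity importance
for the bagged trees, and the absolute Welch t statistic of each feature
for the coefficient-free methods (Naive Bayes, KNN, nearest centroid).

The positive class throughout is ``head``; a decision score of exactly 0.5
classifies as head.  Reported percentages are rounded half-up to integers;
full precision is retained internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC

from .feature_grid import FeatureTable
from .io_preprocess import ValidationError

__all__ = [
    "METHODS",
    "RFEConfig",
    "ClassifierSpec",
    "FittedModel",
    "EvaluationReport",
    "BankResult",
    "train_with_rfe",
    "predict",
    "evaluate",
    "report_from_confusion",
    "run_bank",
    "round_half_up",
]

METHODS = (
    "naive_bayes",
    "knn",
    "kmeans",
    "svm",
    "linear_regression",
    "bagged_trees",
    "lda",
)

_COEF_METHODS = {"svm", "linear_regression", "lda"}
_UNIVARIATE_METHODS = {"naive_bayes", "knn", "kmeans"}

POSITIVE_CLASS = "head"
NEGATIVE_CLASS = "body_tail"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (87.5 -> 88)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class RFEConfig:
    """``step`` is the number of features removed per iteration; a float in
    (0, 1) removes that fraction of the remaining features instead (useful
    on very wide tables)."""

    max_features: int = 5
    step: int | float = 1

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ValidationError("max_features must be >= 1")
        if isinstance(self.step, float):
            if not 0 < self.step < 1:
                raise ValidationError("fractional step must be in (0, 1)")
        elif self.step < 1:
            raise ValidationError("integer step must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    method: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")


def _make_estimator(spec: ClassifierSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.method == "naive_bayes":
        return GaussianNB(**hp)
    if spec.method == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if spec.method == "kmeans":
        return NearestCentroid(**hp)
    if spec.method == "svm":
        hp.setdefault("kernel", "linear")
        hp.setdefault("C", 1.0)
        return SVC(random_state=seed, **hp)
    if spec.method == "linear_regression":
        return LinearRegression(**hp)
    if spec.method == "bagged_trees":
        hp.setdefault("n_estimators", 50)
        hp.setdefault("max_features", 1.0)  # no feature subsampling: pure bagging
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.method == "lda":
        return LinearDiscriminantAnalysis(**hp)
    raise ValidationError(spec.method)


@dataclass
class FittedModel:
    """A trained classifier restricted to its RFE-selected features."""

    spec: ClassifierSpec
    selected_features: tuple[str, ...]
    mean: np.ndarray  # train-set mean per selected feature
    scale: np.ndarray  # train-set SD per selected feature
    estimator: object
    seed: int


def _zscore_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    if np.any(scale == 0):
        raise ValidationError("zero-variance feature reached training; filter first")
    return mean, scale


def _rank_features(method: str, est, xz: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Smaller rank value = less crucial (eliminated first)."""
    if method in _COEF_METHODS:
        est.fit(xz, y)
        coef = est.coef_
        return np.abs(np.ravel(coef))
    if method == "bagged_trees":
        est.fit(xz, y)
        return np.asarray(est.feature_importances_)
    # univariate class-separation score
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(xz[y == 1], xz[y == 0], axis=0, equal_var=False)
    t = np.nan_to_num(np.asarray(t), nan=0.0, posinf=np.finfo(float).max, neginf=-np.finfo(float).max)
    return np.abs(t)


def _labels_to_binary(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if lab == POSITIVE_CLASS else 0 for lab in labels])
    bad = [lab for lab in labels if lab not in (POSITIVE_CLASS, NEGATIVE_CLASS)]
    if bad:
        raise ValidationError(f"unknown labels: {sorted(set(bad))}")
    return y


def train_with_rfe(
    train_table: FeatureTable,
    labels: Sequence[str],
    spec: ClassifierSpec = ClassifierSpec("naive_bayes"),
    rfe: RFEConfig = RFEConfig(),
    seed: int = 0,
) -> FittedModel:
    """Recursive feature elimination down to ``rfe.max_features``, then a
    final fit on the surviving features.  Deterministic given the seed.

    If the table has fewer features than the cap, all are used (with a
    warning).  Requires a filtered table (finite, non-constant columns) and
    at least two cases per class.
    """
    if len(labels) != train_table.n_cases:
        raise ValidationError("label count does not match case count")
    y = _labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValidationError("need at least 2 cases per class")
    x = train_table.values
    if not np.isfinite(x).all():
        raise ValidationError("training table contains non-finite values; filter first")
    mean, scale = _zscore_stats(x)
    xz = (x - mean) / scale

    n_features = x.shape[1]
    if n_features < rfe.max_features:
        warnings.warn(
            f"table has {n_features} features, fewer than max_features={rfe.max_features}; using all",
            stacklevel=2,
        )
    active = np.arange(n_features)
    while active.size > rfe.max_features:
        est = _make_estimator(spec, seed)
        ranking = _rank_features(spec.method, est, xz[:, active], y, seed)
        if isinstance(rfe.step, float):
            n_remove = max(1, int(rfe.step * active.size))
        else:
            n_remove = rfe.step
        n_remove = min(n_remove, active.size - rfe.max_features)
        drop = np.argsort(ranking, kind="stable")[:n_remove]
        active = np.delete(active, drop)

    est = _make_estimator(spec, seed)
    est.fit(xz[:, active], y)
    cols = train_table.columns
    return FittedModel(
        spec=spec,
        selected_features=tuple(cols[i] for i in active),
        mean=mean[active],
        scale=scale[active],
        estimator=est,
        seed=seed,
    )


def _head_scores(model: FittedModel, xz: np.ndarray) -> np.ndarray:
    est = model.estimator
    method = model.spec.method
    if method in ("naive_bayes", "knn", "bagged_trees", "lda"):
        proba = est.predict_proba(xz)
        col = list(est.classes_).index(1)
        return proba[:, col]
    if method == "svm":
        dec = est.decision_function(xz)
        return 1.0 / (1.0 + np.exp(-dec))
    if method == "linear_regression":
        return np.clip(est.predict(xz), 0.0, 1.0)
    if method == "kmeans":
        centroids = est.centroids_
        classes = list(est.classes_)
        d = np.linalg.norm(xz[:, None, :] - centroids[None, :, :], axis=2)
        d_head = d[:, classes.index(1)]
        d_other = d[:, classes.index(0)]
        denom = d_head + d_other
        out = np.full(len(xz), 0.5)
        np.divide(d_other, denom, out=out, where=denom > 0)
        return out
    raise ValidationError(method)


def predict(model: FittedModel, test_table: FeatureTable) -> tuple[list[str], np.ndarray]:
    """Per-case predicted label and head-probability score.

    Label is ``head`` iff score >= 0.5; missing selected descriptors raise.
    """
    missing = [c for c in model.selected_features if c not in test_table.columns]
    if missing:
        raise ValidationError(f"test table lacks selected descriptors: {missing}")
    x = test_table.subset_columns(list(model.selected_features)).values
    if not np.isfinite(x).all():
        raise ValidationError("test table contains non-finite values")
    xz = (x - model.mean) / model.scale
    scores = np.asarray(_head_scores(model, xz), dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValidationError("non-finite decision scores")
    labels = [POSITIVE_CLASS if s >= 0.5 else NEGATIVE_CLASS for s in scores]
    return labels, scores


@dataclass
class EvaluationReport:
    """Confusion matrix (predicted x true, classes head / body_tail),
    accuracy / sensitivity / specificity in percent, ROC points and AUC."""

    confusion: np.ndarray  # [[TP, FP], [FN, TN]]
    accuracy: float  # percent, full precision
    sensitivity: float
    specificity: float
    roc: np.ndarray  # (n, 2) ordered (FPR, TPR)
    auc: Optional[float]

    @property
    def rounded(self) -> dict[str, int]:
        return {
            "accuracy": round_half_up(self.accuracy),
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
        }

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "rounded": self.rounded,
            "auc": self.auc,
        }


def report_from_confusion(tp: int, fp: int, fn: int, tn: int) -> EvaluationReport:
    """Derive the metrics from a printed confusion matrix (no ROC)."""
    total = tp + fp + fn + tn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    pos = tp + fn
    neg = tn + fp
    return EvaluationReport(
        confusion=np.array([[tp, fp], [fn, tn]], dtype=np.int64),
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=100.0 * tp / pos if pos else float("nan"),
        specificity=100.0 * tn / neg if neg else float("nan"),
        roc=np.empty((0, 2)),
        auc=None,
    )


def _roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Score-threshold sweep ROC and its trapezoid AUC."""
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.array([[0.0, 0.0], [1.0, 1.0]]), float("nan")
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(~pos[order])
    # collapse tied scores to one operating point
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate(
    pred_labels: Sequence[str],
    scores: Sequence[float],
    truth: Sequence[str],
) -> EvaluationReport:
    """Confusion matrix, percent metrics, ROC and AUC against ground truth."""
    if not (len(pred_labels) == len(scores) == len(truth)):
        raise ValidationError("predictions, scores and truth must have equal length")
    y_true = _labels_to_binary(truth)
    y_pred = _labels_to_binary(pred_labels)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    base = report_from_confusion(tp, fp, fn, tn)
    roc, auc = _roc_points(np.asarray(scores, dtype=np.float64), y_true)
    base.roc = roc
    base.auc = auc
    return base


@dataclass
class BankResult:
    reports: dict[str, EvaluationReport]
    models: dict[str, FittedModel]
    best_method: str

    @property
    def best_report(self) -> EvaluationReport:
        return self.reports[self.best_method]


def run_bank(
    train_table: FeatureTable,
    train_labels: Sequence[str],
    test_table: FeatureTable,
    test_labels: Sequence[str],
    rfe: RFEConfig = RFEConfig(),
    seed: int = 0,
    specs: Optional[Sequence[ClassifierSpec]] = None,
) -> BankResult:
    """Train all seven classifiers with RFE and evaluate each on the
    held-out table; ``best_method`` is the argmax-accuracy method (ties go
    to the earlier method in the canonical order)."""
    if specs is None:
        specs = [ClassifierSpec(m) for m in METHODS]
    reports: dict[str, EvaluationReport] = {}
    models: dict[str, FittedModel] = {}
    for cs in specs:
        model = train_with_rfe(train_table, train_labels, cs, rfe, seed)
        labels, scores = predict(model, test_table)
        reports[cs.method] = evaluate(labels, scores, test_labels)
        models[cs.method] = model
    best = max(reports, key=lambda m: reports[m].accuracy)
    return BankResult(reports, models, best)
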
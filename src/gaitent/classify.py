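"""Classifier suite and evaluation for the 16-feature gait table.

The suite mirrors the model families commonly offered by point-and-click
learner tools: Gaussian-kernel SVM, logistic regression, cosine-distance KNN
(k = 10), a wide single-hidden-layer neural network, a decision tree,
kernel-density naive Bayes, quadratic discriminant analysis, bagged trees and
a kernel-approximation SVM.  Features are median-imputed and standardized
inside each training fold; evaluation is stratified k-fold cross-validation
(default k = 10) or a stratified holdout split, with the diseased class as
positive for sensitivity, F1 and MCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn import metrics as _skm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.impute import SimpleImputer
from sklearn.kernel_approximation import Nystroem as _SkNystroem
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier as _SkKNN
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .entropy import FEATURE_COLUMNS

__all__ = [
    "CLASSIFIER_NAMES",
    "EvalConfig",
    "ConfusionMatrix",
    "Metrics",
    "ClassifierReport",
    "EvaluationReport",
    "build_classifier",
    "compute_metrics",
    "roc_curve",
    "train_evaluate",
]

POSITIVE_LABEL = "diseased"

CLASSIFIER_NAMES = (
    "svm_gaussian",
    "logistic_regression",
    "knn_cosine",
    "neural_net_wide",
    "decision_tree",
    "naive_bayes_kernel",
    "quadratic_discriminant",
    "ensemble_bagged_tree",
    "kernel_svm",
)


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Each class-conditional feature density is a 1-D KDE; features are assumed
    conditionally independent.  Constant features fall back to a narrow
    Gaussian around the observed value.
    """

    def __init__(self, bw_method: str | float = "scott"):
        self.bw_method = bw_method

    def fit(self, X, y):
        X, y = np.asarray(X, dtype=float), np.asarray(y)
        self.classes_ = np.unique(y)
        self._priors = {}
        self._kdes: dict = {}
        for c in self.classes_:
            Xc = X[y == c]
            self._priors[c] = len(Xc) / len(X)
            cols = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) == 0 or len(col) < 2:
                    cols.append(("norm", float(col.mean()), 1e-3))
                else:
                    cols.append(("kde", gaussian_kde(col, bw_method=self.bw_method), None))
            self._kdes[c] = cols
        return self

    def _joint_log_density(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for ci, c in enumerate(self.classes_):
            logp = np.full(X.shape[0], math.log(self._priors[c]))
            for j, (kind, a, b) in enumerate(self._kdes[c]):
                if kind == "kde":
                    dens = a(X[:, j])
                else:
                    dens = np.exp(-0.5 * ((X[:, j] - a) / b) ** 2) / (b * math.sqrt(2 * math.pi))
                logp += np.log(np.clip(dens, 1e-300, None))
            out[:, ci] = logp
        return out

    def predict_proba(self, X):
        lp = self._joint_log_density(X)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_density(X), axis=1)]


class KNeighborsClassifier(_SkKNN):
    """KNN that clamps the neighbour count to the training-set size."""

    def fit(self, X, y):
        self.n_neighbors = min(self.n_neighbors, len(y))
        return super().fit(X, y)


class Nystroem(_SkNystroem):
    """Kernel approximation clamped to the training-set size."""

    def fit(self, X, y=None):
        self.n_components = min(self.n_components, len(X))
        return super().fit(X, y)


def build_classifier(name: str, seed: int = 0) -> Pipeline:
    """A fold-safe pipeline: median imputation, standardization, classifier."""
    estimators = {
        "svm_gaussian": lambda: SVC(kernel="rbf", C=1.0, gamma="scale"),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000),
        "knn_cosine": lambda: KNeighborsClassifier(n_neighbors=10, metric="cosine"),
        "neural_net_wide": lambda: MLPClassifier(
            hidden_layer_sizes=(100,), max_iter=3000, random_state=seed
        ),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "naive_bayes_kernel": lambda: KernelNaiveBayes(),
        # Ledoit-Wolf shrinkage keeps class covariances invertible when the
        # per-class sample count is close to the 16-feature dimension
        "quadratic_discriminant": lambda: QuadraticDiscriminantAnalysis(
            solver="eigen", shrinkage="auto"
        ),
        "ensemble_bagged_tree": lambda: BaggingClassifier(
            DecisionTreeClassifier(random_state=seed), n_estimators=30, random_state=seed
        ),
        "kernel_svm": lambda: Pipeline(
            [
                ("nystroem", Nystroem(n_components=30, random_state=seed)),
                ("linear", LogisticRegression(max_iter=2000)),
            ]
        ),
    }
    if name not in estimators:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", estimators[name]()),
        ]
    )


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation scheme: stratified k-fold CV (default) or a holdout split."""

    scheme: str = "kfold"
    k: int = 10
    holdout_fraction: float = 0.25
    stratified: bool = True
    rng_seed: int = 0
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "holdout"):
            raise ValueError("scheme must be 'kfold' or 'holdout'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with 'diseased' as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tn + other.tn, self.fp + other.fp, self.fn + other.fn, self.tp + other.tp
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        pos_t, pos_p = y_true == POSITIVE_LABEL, y_pred == POSITIVE_LABEL
        return cls(
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tp=int(np.sum(pos_t & pos_p)),
        )


@dataclass(frozen=True)
class Metrics:
    """Scalar summaries of a confusion matrix; undefined ratios are NaN-flagged."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()


def _ratio(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return float("nan")
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity, specificity, F1 and MCC from first principles."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tn, fp, fn, tp = cm.tn, cm.fp, cm.fn, cm.tp
    flags: list[str] = []
    accuracy = (tp + tn) / cm.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", flags)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)
    return Metrics(accuracy, sensitivity, specificity, f1, mcc, tuple(flags))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC with trapezoidal AUC; ties share a threshold.

    Returns (fpr, tpr, thresholds, auc); scores are larger-means-diseased.
    """
    labels = np.asarray(labels)
    y = (labels == POSITIVE_LABEL).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


@dataclass
class ClassifierReport:
    """Cross-validated outcome of one classifier."""

    name: str
    fold_matrices: list[ConfusionMatrix]
    fold_accuracies: list[float]
    pooled: ConfusionMatrix
    metrics: Metrics
    roc: tuple[np.ndarray, np.ndarray, np.ndarray, float] | None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def auc(self) -> float:
        return self.roc[3] if self.roc is not None else float("nan")


@dataclass
class EvaluationReport:
    """Suite-wide evaluation: one ClassifierReport per requested classifier."""

    config: EvalConfig
    per_classifier: dict[str, ClassifierReport] = field(default_factory=dict)

    def best(self) -> tuple[str, float]:
        """Name and mean CV accuracy of the best classifier."""
        name = max(self.per_classifier, key=lambda n: self.per_classifier[n].mean_accuracy)
        return name, self.per_classifier[name].mean_accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.per_classifier.items():
            m = rep.metrics
            rows.append(
                {
                    "classifier": name,
                    "accuracy_pct": 100 * rep.mean_accuracy,
                    "sensitivity_pct": 100 * m.sensitivity,
                    "specificity_pct": 100 * m.specificity,
                    "f1": m.f1,
                    "mcc": m.mcc,
                    "auc": rep.auc,
                }
            )
        return pd.DataFrame(rows).sort_values("accuracy_pct", ascending=False, ignore_index=True)


def _splitter(config: EvalConfig, y: np.ndarray):
    if config.scheme == "holdout":
        return StratifiedShuffleSplit(
            n_splits=1, test_size=config.holdout_fraction, random_state=config.rng_seed
        )
    if config.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < config.k:
            raise ValueError(
                f"stratified {config.k}-fold needs >= {config.k} subjects per class "
                f"(have {counts.min()}); reduce k or add subjects"
            )
        return StratifiedKFold(n_splits=config.k, shuffle=True, random_state=config.rng_seed)
    return KFold(n_splits=config.k, shuffle=True, random_state=config.rng_seed)


def _scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Larger-means-diseased score for ROC."""
    clf = model.named_steps["clf"]
    classes = list(getattr(clf, "classes_", []))
    if hasattr(clf, "decision_function"):
        s = model.decision_function(X)
        # decision_function is oriented toward classes_[1]
        return s if classes and classes[1] == POSITIVE_LABEL else -s
    proba = model.predict_proba(X)
    return proba[:, classes.index(POSITIVE_LABEL)]


def train_evaluate(features: pd.DataFrame, config: EvalConfig | None = None) -> EvaluationReport:
    """Cross-validate the classifier suite on a feature table.

    ``features`` must carry a ``label`` column ('healthy'/'diseased') and the
    16 feature columns.  Deterministic given ``config.rng_seed``.
    """
    config = config or EvalConfig()
    missing_cols = [c for c in FEATURE_COLUMNS + ["label"] if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    for cls in ("healthy", POSITIVE_LABEL):
        if np.sum(y == cls) < 2:
            raise ValueError(f"need >= 2 subjects of class {cls!r}")

    splits = list(_splitter(config, y).split(X, y))
    report = EvaluationReport(config=config)
    for name in config.classifiers:
        fold_cms, fold_acc = [], []
        oof_scores = np.full(len(y), np.nan)
        oof_pred = np.empty(len(y), dtype=object)
        tested = np.zeros(len(y), dtype=bool)
        for train_idx, test_idx in splits:
            model = clone(build_classifier(name, seed=config.rng_seed))
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            cm = ConfusionMatrix.from_predictions(y[test_idx], pred)
            fold_cms.append(cm)
            fold_acc.append((cm.tp + cm.tn) / cm.total)
            oof_scores[test_idx] = _scores(model, X[test_idx])
            oof_pred[test_idx] = pred
            tested[test_idx] = True
        pooled = ConfusionMatrix.from_predictions(y[tested], oof_pred[tested])
        try:
            roc = roc_curve(oof_scores[tested], y[tested])
        except ValueError:
            roc = None
        report.per_classifier[name] = ClassifierReport(
            name, fold_cms, fold_acc, pooled, compute_metrics(pooled), roc
        )
    return report
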
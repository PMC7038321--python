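"""Spectral features and the binary tremor classifier benchmark.

The feature vector for one measurement is the one-sided amplitude spectrum
of the preprocessed hold window resampled onto a fixed 41-point grid over
the 3.5–7.5 Hz tremor band (0.1 Hz spacing).  Four classifiers are
benchmarked with stratified fivefold cross-validation:

* RBF-kernel support vector machine (gamma = 6.4), standardized inputs
* kernel-density naive Bayes (per-feature Gaussian KDE, Silverman bandwidth)
* decision tree (Gini split criterion, at most 100 leaf nodes)
* k-nearest neighbours (k = 13, cosine distance), standardized inputs

Metrics treat the disease class (label 1) as the target:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP),
F1 = 2 * sensitivity * precision / (sensitivity + precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .spectral import Spectrum

__all__ = [
    "FEATURE_GRID_HZ",
    "FeatureVector",
    "ClassifierSpec",
    "MetricsReport",
    "KernelDensityNB",
    "extract_features",
    "feature_matrix",
    "standardize_columns",
    "make_classifier",
    "crossvalidate",
    "metrics_from_confusion",
]

# 41 grid points, 3.5 to 7.5 Hz at 0.1 Hz spacing, shared across a dataset.
FEATURE_GRID_HZ = np.round(np.linspace(3.5, 7.5, 41), 2)


@dataclass
class FeatureVector:
    """41 resampled amplitude-spectrum values with an optional class label."""

    values: np.ndarray
    label: int | None = None
    grid_hz: np.ndarray = field(default_factory=lambda: FEATURE_GRID_HZ.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid_hz.shape:
            raise ValueError(
                f"expected {self.grid_hz.size} feature values, got {self.values.size}"
            )
        if np.any(self.values < 0):
            raise ValueError("amplitude features must be non-negative")


def extract_features(spectrum: Spectrum, label: int | None = None) -> FeatureVector:
    """Resample an amplitude spectrum onto the fixed 41-point band grid.

    Linear interpolation of the piecewise-linear amplitude curve at 3.5,
    3.6, ..., 7.5 Hz.
    """
    if spectrum.kind != "amplitude":
        raise ValueError("feature extraction expects an amplitude spectrum")
    f = spectrum.freqs_hz
    if f[0] > FEATURE_GRID_HZ[0] or f[-1] < FEATURE_GRID_HZ[-1]:
        raise ValueError(
            f"spectrum support [{f[0]:g}, {f[-1]:g}] Hz does not cover the "
            f"3.5-7.5 Hz feature band"
        )
    return FeatureVector(values=np.interp(FEATURE_GRID_HZ, f, spectrum.values), label=label)


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y); y entries are -1 where unlabelled."""
    X = np.vstack([fv.values for fv in features])
    y = np.array([-1 if fv.label is None else int(fv.label) for fv in features])
    return X, y


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scoring: subtract the column mean, divide by the column
    standard deviation.  Constant columns map to all zeros."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardization needs a 2-D matrix with >= 2 rows")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = X - mu
    nonzero = sd > 0
    out[:, nonzero] /= sd[nonzero]
    out[:, ~nonzero] = 0.0
    return out


class KernelDensityNB(ClassifierMixin, BaseEstimator):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Each feature's class-conditional density is a kernel density estimate
    with Gaussian kernels; the bandwidth follows Silverman's rule,
    ``h = 0.9 * min(sd, IQR/1.34) * m**(-1/5)`` per feature and class.
    Class priors are the training frequencies.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    class_log_prior_ : ndarray
        Log of the empirical class frequencies.
    """

    def __init__(self, min_bandwidth: float = 1e-9):
        self.min_bandwidth = min_bandwidth

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size < 2:
            raise ValueError("KernelDensityNB needs at least two classes")
        self.class_log_prior_ = np.log(counts / counts.sum())
        self.train_values_ = []
        self.bandwidths_ = []
        for c in self.classes_:
            Xc = X[y == c]
            m = Xc.shape[0]
            sd = Xc.std(axis=0, ddof=1) if m > 1 else np.zeros(Xc.shape[1])
            q75, q25 = np.percentile(Xc, [75, 25], axis=0)
            spread = np.minimum(sd, (q75 - q25) / 1.34)
            spread = np.where(spread > 0, spread, np.where(sd > 0, sd, 1.0))
            h = 0.9 * spread * m ** (-0.2)
            self.train_values_.append(Xc)
            self.bandwidths_.append(np.maximum(h, self.min_bandwidth))
        return self

    def _joint_log_likelihood(self, X):
        jll = np.empty((X.shape[0], self.classes_.size))
        for j, (Xc, h) in enumerate(zip(self.train_values_, self.bandwidths_)):
            # per feature d: log( mean_i N(x | Xc[i,d], h[d]) ), summed over d
            z = (X[:, None, :] - Xc[None, :, :]) / h  # (n, m, d)
            log_k = -0.5 * z**2 - np.log(h * math.sqrt(2 * math.pi))
            feat_ll = logsumexp(log_k, axis=1) - math.log(Xc.shape[0])
            jll[:, j] = self.class_log_prior_[j] + feat_ll.sum(axis=1)
        return jll

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        jll = self._joint_log_likelihood(X)
        jll -= logsumexp(jll, axis=1, keepdims=True)
        return np.exp(jll)


@dataclass
class ClassifierSpec:
    """One benchmark entry: classifier kind plus its fixed hyperparameters."""

    kind: str  # svm_rbf | naive_bayes_kernel | decision_tree | knn
    svm_gamma: float = 6.4
    tree_max_nodes: int = 100
    knn_k: int = 13
    standardize: bool | None = None  # None -> per-kind default

    KINDS = ("svm_rbf", "naive_bayes_kernel", "decision_tree", "knn")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if self.standardize is None:
            self.standardize = self.kind in ("svm_rbf", "knn")


def make_classifier(spec: ClassifierSpec, seed: int | None = None):
    """Build the sklearn estimator (wrapped in a scaler pipeline if the
    spec standardizes its inputs)."""
    if spec.kind == "svm_rbf":
        clf = SVC(kernel="rbf", gamma=spec.svm_gamma)
    elif spec.kind == "naive_bayes_kernel":
        clf = KernelDensityNB()
    elif spec.kind == "decision_tree":
        clf = DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=spec.tree_max_nodes, random_state=seed
        )
    else:
        clf = KNeighborsClassifier(n_neighbors=spec.knn_k, metric="cosine")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


@dataclass
class MetricsReport:
    """Benchmark metrics with the disease class (1) as target.

    Ratios that are undefined for the given counts (zero denominator) are
    reported as NaN.  ``fold_confusions`` holds per-fold (tp, fp, tn, fn).
    """

    val_accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    fold_confusions: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "val_accuracy": self.val_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def f1_score_from(sensitivity: float, precision: float) -> float:
    """F1 = 2 * sensitivity * precision / (sensitivity + precision)."""
    den = sensitivity + precision
    return 2 * sensitivity * precision / den if den > 0 else float("nan")


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int, val_accuracy: float | None = None
) -> MetricsReport:
    """Derive the benchmark metrics from pooled confusion counts."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("confusion counts must be non-negative with a positive total")
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    acc = (tp + tn) / (tp + fp + tn + fn) if val_accuracy is None else val_accuracy
    f1 = f1_score_from(sens, prec) if not (math.isnan(sens) or math.isnan(prec)) else float("nan")
    return MetricsReport(
        val_accuracy=acc, sensitivity=sens, specificity=spec, precision=prec,
        f1=f1, tp=tp, fp=fp, tn=tn, fn=fn,
    )


def _make_splitter(y: np.ndarray, k: int, seed: int | None, groups):
    if groups is not None:
        return StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    min_class = np.bincount(y).min() if y.size else 0
    if k > min_class:
        # stratification impossible (e.g. leave-one-out); plain shuffled folds
        return KFold(n_splits=k, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int | None = 0,
    groups: np.ndarray | None = None,
) -> MetricsReport:
    """Stratified k-fold benchmark of one classifier.

    ``val_accuracy`` is the mean per-fold accuracy; sensitivity,
    specificity, precision and F1 come from the confusion counts pooled
    across the validation folds.  Pass ``groups`` (e.g. subject ids) for
    grouped splitting that keeps a subject's measurements in one fold;
    the default measurement-level split matches the benchmark framing but
    lets subject identity leak across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("cross-validation needs both classes present")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    splitter = _make_splitter(y, k, seed, groups)
    split_args = (X, y) if groups is None else (X, y, groups)

    fold_acc = []
    fold_confusions = []
    tp = fp = tn = fn = 0
    for train_idx, val_idx in splitter.split(*split_args):
        fold_spec = spec
        if spec.kind == "knn" and spec.knn_k > train_idx.size:
            # tiny training folds cannot supply k neighbours; cap k
            fold_spec = ClassifierSpec(
                kind=spec.kind, knn_k=int(train_idx.size), standardize=spec.standardize
            )
        clf = make_classifier(fold_spec, seed=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[val_idx])
        truth = y[val_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        ftp = int(np.sum((pred == 1) & (truth == 1)))
        ffp = int(np.sum((pred == 1) & (truth == 0)))
        ftn = int(np.sum((pred == 0) & (truth == 0)))
        ffn = int(np.sum((pred == 0) & (truth == 1)))
        fold_confusions.append((ftp, ffp, ftn, ffn))
        tp, fp, tn, fn = tp + ftp, fp + ffp, tn + ftn, fn + ffn

    report = metrics_from_confusion(tp, fp, tn, fn, val_accuracy=float(np.mean(fold_acc)))
    report.fold_confusions = fold_confusions
    return report
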
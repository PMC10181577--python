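"""Multi-classifier benchmark under a stratified 80:20 + 10-fold protocol.

Twelve classifier configurations mirroring the common "preset" suites of
interactive model-comparison tools: a Gini decision tree, pooled-covariance
LDA, a kernel naive Bayes, six SVM variants (linear / quadratic / cubic
polynomial and fine / medium / coarse Gaussian kernel scales) and three
Euclidean KNNs (k = 1, 10, 100).  Evaluation uses a stratified 80:20 outer
split; held-out accuracy is measured on the 20 % partition and a stratified
10-fold cross-validation accuracy on the 80 % partition.  Features are
z-scored inside each training fold only, so no test statistics leak into
training.

The per-suite accuracies are aggregated as mean +/- population standard
deviation (divide by N), the convention that reproduces a "mean across all
models" row recomputable from the 12 per-model values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "CLASSIFIER_IDS",
    "ClassifierSpec",
    "EvalProtocol",
    "ModelResult",
    "BenchmarkResult",
    "KernelNaiveBayes",
    "make_classifier_suite",
    "build_estimator",
    "train_evaluate",
    "run_benchmark",
    "aggregate",
]

#: Canonical row order of the comparison table.
CLASSIFIER_IDS = (
    "DT", "LDA", "KNB", "LSVM", "QSVM", "CSVM",
    "FGSVM", "MGSVM", "CGSVM", "FKNN", "MKNN", "CKNN",
)


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Class-conditional densities are products of univariate KDEs with
    Silverman's bandwidth ``0.9 * min(sd, iqr/1.34) * n**(-1/5)`` per
    class and feature (floored to avoid degenerate spikes).
    """

    def __init__(self, bandwidth_floor: float = 1e-9):
        self.bandwidth_floor = bandwidth_floor

    def fit(self, X, y):
        X = validate_data(self, X, dtype=float)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        self.train_ = []
        self.bandwidths_ = []
        self.log_priors_ = []
        for c in self.classes_:
            Xc = X[y == c]
            n = Xc.shape[0]
            sd = Xc.std(axis=0, ddof=1) if n > 1 else np.zeros(Xc.shape[1])
            q75, q25 = np.percentile(Xc, [75, 25], axis=0)
            spread = np.minimum(sd, (q75 - q25) / 1.34)
            spread = np.where(spread > 0, spread, np.maximum(sd, 1.0))
            h = 0.9 * spread * n ** (-0.2)
            self.train_.append(Xc)
            self.bandwidths_.append(np.maximum(h, self.bandwidth_floor))
            self.log_priors_.append(np.log(n / X.shape[0]))
        return self

    def _joint_log_likelihood(self, X):
        jll = np.empty((X.shape[0], len(self.classes_)))
        for k, (Xc, h, lp) in enumerate(
            zip(self.train_, self.bandwidths_, self.log_priors_)
        ):
            z = (X[:, None, :] - Xc[None, :, :]) / h[None, None, :]
            dens = np.exp(-0.5 * z**2).mean(axis=1) / (np.sqrt(2 * np.pi) * h)
            jll[:, k] = lp + np.log(np.maximum(dens, 1e-300)).sum(axis=1)
        return jll

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark entry: a canonical id plus its hyperparameters."""

    id: str
    hyperparameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EvalProtocol:
    """Stratified 80:20 split with 10-fold CV inside the training portion."""

    train_fraction: float = 0.8
    test_fraction: float = 0.2
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("train and test fractions must sum to 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ModelResult:
    id: str
    holdout_accuracy: float  # percent, on the 20 % partition
    cv_accuracy: float  # percent, mean 10-fold CV on the 80 % partition


@dataclass
class BenchmarkResult:
    """Per-model accuracies for one feature set plus their aggregate."""

    feature_set: str
    per_model: list[ModelResult]
    mean_accuracy: float
    std_accuracy: float
    cv_mean_accuracy: float
    cv_std_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": r.id,
                "holdout_accuracy_pct": r.holdout_accuracy,
                "cv_accuracy_pct": r.cv_accuracy,
            }
            for r in self.per_model
        ]
        rows.append(
            {
                "model": "Mean across all models",
                "holdout_accuracy_pct": self.mean_accuracy,
                "cv_accuracy_pct": self.cv_mean_accuracy,
            }
        )
        return pd.DataFrame(rows)


def make_classifier_suite() -> list[ClassifierSpec]:
    """The 12 classifier configurations in canonical table order."""
    return [
        ClassifierSpec("DT", {"criterion": "gini", "max_splits": 100}),
        ClassifierSpec("LDA", {"solver": "svd"}),
        ClassifierSpec("KNB", {"kernel": "gaussian", "bandwidth": "silverman"}),
        ClassifierSpec("LSVM", {"kernel": "linear", "C": 1.0}),
        ClassifierSpec("QSVM", {"kernel": "poly", "degree": 2, "C": 1.0}),
        ClassifierSpec("CSVM", {"kernel": "poly", "degree": 3, "C": 1.0}),
        ClassifierSpec("FGSVM", {"kernel": "rbf", "kernel_scale": "sqrt(P)/4"}),
        ClassifierSpec("MGSVM", {"kernel": "rbf", "kernel_scale": "sqrt(P)"}),
        ClassifierSpec("CGSVM", {"kernel": "rbf", "kernel_scale": "4*sqrt(P)"}),
        ClassifierSpec("FKNN", {"n_neighbors": 1, "metric": "euclidean"}),
        ClassifierSpec("MKNN", {"n_neighbors": 10, "metric": "euclidean"}),
        ClassifierSpec("CKNN", {"n_neighbors": 100, "metric": "euclidean"}),
    ]


def build_estimator(spec: ClassifierSpec, n_features: int, seed: int = 0):
    """Instantiate the sklearn estimator for a spec (kernel scales need P)."""
    p = n_features
    if spec.id == "DT":
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=100 + 1, random_state=seed
        )
    if spec.id == "LDA":
        return LinearDiscriminantAnalysis()
    if spec.id == "KNB":
        return KernelNaiveBayes()
    if spec.id == "LSVM":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if spec.id == "QSVM":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma=1.0 / p, C=1.0,
                   random_state=seed)
    if spec.id == "CSVM":
        return SVC(kernel="poly", degree=3, coef0=1.0, gamma=1.0 / p, C=1.0,
                   random_state=seed)
    if spec.id in ("FGSVM", "MGSVM", "CGSVM"):
        scale = {"FGSVM": np.sqrt(p) / 4, "MGSVM": np.sqrt(p), "CGSVM": 4 * np.sqrt(p)}
        return SVC(kernel="rbf", gamma=1.0 / scale[spec.id] ** 2, C=1.0,
                   random_state=seed)
    if spec.id in ("FKNN", "MKNN", "CKNN"):
        k = {"FKNN": 1, "MKNN": 10, "CKNN": 100}[spec.id]
        return KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    raise ValueError(f"unknown classifier id {spec.id!r}")


def _as_xy(features, labels):
    X = np.asarray(
        features.values if isinstance(features, pd.DataFrame) else features,
        dtype=float,
    )
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite entries")
    y = np.asarray([getattr(v, "value", v) for v in labels])
    return X, y


def split_indices(n: int, y: np.ndarray, protocol: EvalProtocol):
    """The outer train/test index split the protocol uses (exposed for audits)."""
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=protocol.test_fraction,
        stratify=y if protocol.stratified else None,
        random_state=protocol.seed,
    )
    return train_idx, test_idx


def train_evaluate(
    features, labels, spec: ClassifierSpec, protocol: EvalProtocol
) -> ModelResult:
    """Fit one spec under the protocol; returns held-out and CV accuracy (%)."""
    X, y = _as_xy(features, labels)
    train_idx, test_idx = split_indices(X.shape[0], y, protocol)
    classes, counts = np.unique(y[train_idx], return_counts=True)
    if len(classes) < len(np.unique(y)) or np.any(counts < 2):
        raise ValueError("every class needs at least 2 training samples (stratification)")

    est = build_estimator(spec, X.shape[1], seed=protocol.seed)
    steps = ([("scale", StandardScaler())] if protocol.standardize else []) + [
        ("clf", est)
    ]
    pipe = Pipeline(steps)

    cv = StratifiedKFold(
        n_splits=protocol.cv_folds, shuffle=True, random_state=protocol.seed
    )
    cv_scores = cross_val_score(
        clone(pipe), X[train_idx], y[train_idx], cv=cv, scoring="accuracy"
    )
    pipe.fit(X[train_idx], y[train_idx])
    holdout = float(np.mean(pipe.predict(X[test_idx]) == y[test_idx]))
    return ModelResult(
        id=spec.id,
        holdout_accuracy=100.0 * holdout,
        cv_accuracy=100.0 * float(np.mean(cv_scores)),
    )


def _benchmark_one(features, labels, protocol: EvalProtocol, name: str) -> BenchmarkResult:
    results = [
        train_evaluate(features, labels, spec, protocol)
        for spec in make_classifier_suite()
    ]
    mean, std = aggregate([r.holdout_accuracy for r in results])
    cv_mean, cv_std = aggregate([r.cv_accuracy for r in results])
    return BenchmarkResult(name, results, mean, std, cv_mean, cv_std)


def run_benchmark(handcrafted, dws, labels, protocol: EvalProtocol):
    """Benchmark both feature tables over the same windows and labels."""
    Xh, _ = _as_xy(handcrafted, labels)
    Xd, _ = _as_xy(dws, labels)
    if Xh.shape[0] != Xd.shape[0]:
        raise ValueError("handcrafted and scattering tables have mismatched rows")
    if Xh.shape[0] != len(labels):
        raise ValueError("feature tables and labels have mismatched rows")
    return {
        "handcrafted": _benchmark_one(handcrafted, labels, protocol, "handcrafted"),
        "dws": _benchmark_one(dws, labels, protocol, "dws"),
    }


def aggregate(accuracies) -> tuple[float, float]:
    """Mean and population standard deviation (divide by N) of the 12 accuracies."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size != len(CLASSIFIER_IDS):
        raise ValueError(f"expected {len(CLASSIFIER_IDS)} accuracies, got {acc.size}")
    if np.any(acc < 0) or np.any(acc > 100):
        raise ValueError("accuracies must lie in [0, 100]")
    return float(acc.mean()), float(acc.std(ddof=0))
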
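"""Classifiers, stratified k-fold cross-validation, and pooled metrics.

Six classifier families are supported:

* ``knn``  — K-nearest neighbors with city-block (L1) distance, K in 1..9.
* ``svm``  — support vector machine with an RBF kernel parameterized by the
  kernel width ``sigma`` (gamma = 1/(2*sigma^2)), sigma in 0.1..1.5.
* ``ffnn`` — feed-forward network: one hidden layer of 10 tan-sigmoid
  units, logistic output.
* ``cfnn`` — cascade-forward network: the FFNN plus a direct input-to-
  output connection.
* ``grnn`` — generalized regression network: Gaussian-kernel regression on
  the training set with a fixed spread (default 1).
* ``rnn``  — Elman-style recurrent network: the hidden layer is unrolled
  for two passes over the static feature vector, the context fed by the
  first pass's hidden state.

Networks are trained by minimizing the regularized cross-entropy with a
quasi-Newton (L-BFGS) optimizer; weights are drawn from the run seed so
training is deterministic.

Evaluation pools the confusion counts over all folds of a stratified
k-fold partition before computing accuracy, sensitivity and specificity
(percent); the focal class is the positive class, so sensitivity is the
focal detection rate and specificity the nonfocal detection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "Metrics",
    "CLASSIFIER_FAMILIES",
    "fit_classifier",
    "predict",
    "compute_metrics",
    "cross_validate",
    "grid_search",
    "KNN_K_GRID",
    "SVM_SIGMA_GRID",
]

CLASSIFIER_FAMILIES = ("knn", "svm", "ffnn", "cfnn", "grnn", "rnn")

KNN_K_GRID = tuple(range(1, 10))
SVM_SIGMA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 16))


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameters and seed."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {CLASSIFIER_FAMILIES}"
            )


@dataclass
class ConfusionCounts:
    """Pooled confusion counts (focal = positive class)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity, specificity — percentages in [0, 100]."""

    acc: float
    sen: float
    spe: float


class UndefinedMetricError(ZeroDivisionError):
    pass


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """ACC/SEN/SPE from pooled counts.

    ACC = (TP+TN)/(TP+TN+FP+FN)*100, SEN = TP/(TP+FN)*100,
    SPE = TN/(TN+FP)*100.
    """
    if c.total == 0:
        raise UndefinedMetricError("ACC undefined: no evaluated records")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("SEN undefined: no positive (focal) records")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("SPE undefined: no negative (nonfocal) records")
    return Metrics(
        acc=100.0 * (c.tp + c.tn) / c.total,
        sen=100.0 * c.tp / (c.tp + c.fn),
        spe=100.0 * c.tn / (c.tn + c.fp),
    )


# --------------------------------------------------------------------------
# Small neural networks (FFNN / CFNN / Elman) on numpy + L-BFGS
# --------------------------------------------------------------------------


class _NeuralNetClassifier:
    """One-hidden-layer tanh network with optional input->output skip
    (cascade-forward) or a two-pass Elman context loop."""

    def __init__(
        self,
        arch: str,
        hidden: int = 10,
        seed: int = 0,
        max_iter: int = 200,
        l2: float = 1e-4,
    ):
        assert arch in ("ffnn", "cfnn", "rnn")
        self.arch = arch
        self.hidden = hidden
        self.seed = seed
        self.max_iter = max_iter
        self.l2 = l2

    def _shapes(self, d: int) -> list[tuple[str, tuple[int, ...]]]:
        h = self.hidden
        shapes = [("W1", (d, h)), ("b1", (h,)), ("w2", (h,)), ("b2", (1,))]
        if self.arch == "cfnn":
            shapes.append(("ws", (d,)))
        if self.arch == "rnn":
            shapes.append(("Wc", (h, h)))
        return shapes

    def _unpack(self, vec: np.ndarray, d: int) -> dict[str, np.ndarray]:
        params = {}
        ofs = 0
        for name, shape in self._shapes(d):
            size = int(np.prod(shape))
            params[name] = vec[ofs : ofs + size].reshape(shape)
            ofs += size
        return params

    def _forward(self, p: dict, X: np.ndarray):
        a1 = X @ p["W1"] + p["b1"]
        h1 = np.tanh(a1)
        if self.arch == "rnn":
            a2 = X @ p["W1"] + h1 @ p["Wc"] + p["b1"]
            h = np.tanh(a2)
        else:
            h = h1
        z = h @ p["w2"] + p["b2"][0]
        if self.arch == "cfnn":
            z = z + X @ p["ws"]
        return h1, h, z

    def _loss_grad(self, vec: np.ndarray, X: np.ndarray, y: np.ndarray):
        n, d = X.shape
        p = self._unpack(vec, d)
        h1, h, z = self._forward(p, X)
        prob = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        loss += 0.5 * self.l2 * np.sum(vec * vec)

        dz = (prob - y) / n
        g = {name: np.zeros(shape) for name, shape in self._shapes(d)}
        g["w2"] = h.T @ dz
        g["b2"] = np.array([dz.sum()])
        if self.arch == "cfnn":
            g["ws"] = X.T @ dz
        dh = np.outer(dz, p["w2"])
        if self.arch == "rnn":
            da2 = dh * (1.0 - h * h)
            g["W1"] += X.T @ da2
            g["b1"] += da2.sum(axis=0)
            g["Wc"] = h1.T @ da2
            dh1 = da2 @ p["Wc"].T
            da1 = dh1 * (1.0 - h1 * h1)
            g["W1"] += X.T @ da1
            g["b1"] += da1.sum(axis=0)
        else:
            da1 = dh * (1.0 - h * h)
            g["W1"] = X.T @ da1
            g["b1"] = da1.sum(axis=0)
        grad = np.concatenate([g[name].ravel() for name, _ in self._shapes(d)])
        grad += self.l2 * vec
        return loss, grad

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_NeuralNetClassifier":
        X = np.asarray(X, dtype=float)
        y01 = np.asarray(y01, dtype=float)
        n, d = X.shape
        self._d = d
        rng = np.random.default_rng(self.seed)
        vec0 = np.concatenate(
            [
                rng.normal(0.0, 1.0 / np.sqrt(max(shape[0], 1)), int(np.prod(shape)))
                for _, shape in self._shapes(d)
            ]
        )
        res = minimize(
            self._loss_grad,
            vec0,
            args=(X, y01),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter},
        )
        self._vec = res.x
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._d:
            raise ValueError(
                f"feature count {X.shape[1]} does not match training ({self._d})"
            )
        p = self._unpack(self._vec, self._d)
        _, _, z = self._forward(p, X)
        return 1.0 / (1.0 + np.exp(-z))

    def predict01(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


class _GRNNClassifier:
    """Generalized regression network: Gaussian-kernel (Nadaraya-Watson)
    regression of the 0/1 class indicator with a fixed spread."""

    def __init__(self, spread: float = 1.0):
        if spread <= 0:
            raise ValueError("spread must be positive")
        self.spread = spread

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_GRNNClassifier":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y01, dtype=float)
        self._d = self._X.shape[1]
        return self

    def predict01(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self._d:
            raise ValueError(
                f"feature count {X.shape[1]} does not match training ({self._d})"
            )
        d2 = cdist(X, self._X, metric="sqeuclidean")
        w = np.exp(-d2 / (2.0 * self.spread**2))
        denom = w.sum(axis=1)
        out = np.empty(len(X), dtype=int)
        ok = denom > 0
        out[ok] = (w[ok] @ self._y / denom[ok] >= 0.5).astype(int)
        if (~ok).any():  # all kernels underflowed: fall back to 1-NN
            nearest = np.argmin(d2[~ok], axis=1)
            out[~ok] = self._y[nearest].astype(int)
        return out


# --------------------------------------------------------------------------
# Unified fit / predict over string-labeled data
# --------------------------------------------------------------------------

POSITIVE_LABEL = "focal"


class Model:
    """A trained classifier closed over its label encoding."""

    def __init__(self, impl, classes: np.ndarray, kind: str):
        self._impl = impl
        self.classes_ = classes  # classes_[1] is the positive class
        self._kind = kind
        self.n_features_ = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (
            self.n_features_ is not None and X.shape[1] != self.n_features_
        ):
            raise ValueError(
                f"expected 2-D input with {self.n_features_} features, "
                f"got shape {X.shape}"
            )
        if self._kind == "sklearn":
            y01 = self._impl.predict(X)
        else:
            y01 = self._impl.predict01(X)
        return self.classes_[np.asarray(y01, dtype=int)]


def _encode_labels(y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if len(classes) != 2:
        raise ValueError(f"binary classification only, got classes {list(classes)}")
    # focal is the positive class when present
    if POSITIVE_LABEL in classes and classes[1] != POSITIVE_LABEL:
        classes = classes[::-1].copy()
    y01 = (y == classes[1]).astype(int)
    return y01, classes


def fit_classifier(spec: ClassifierSpec, X, y) -> Model:
    """Train one classifier on a feature table (rows) and labels."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (records x features)")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    y01, classes = _encode_labels(y)
    if min(np.bincount(y01)) < 1:
        raise ValueError("each class needs at least one training row")

    hp = dict(spec.hyperparams)
    family = spec.family
    if family == "knn":
        k = int(hp.get("k", 1))
        if not 1 <= k <= 9:
            raise ValueError(f"KNN K must be in 1..9, got {k}")
        impl = KNeighborsClassifier(n_neighbors=k, metric="manhattan").fit(X, y01)
        kind = "sklearn"
    elif family == "svm":
        sigma = float(hp.get("sigma", 1.0))
        if not 0.1 - 1e-9 <= sigma <= 1.5 + 1e-9:
            raise ValueError(f"SVM sigma must be in 0.1..1.5, got {sigma}")
        gamma = 1.0 / (2.0 * sigma**2)
        impl = SVC(kernel="rbf", gamma=gamma, C=hp.get("C", 1.0)).fit(X, y01)
        kind = "sklearn"
    elif family in ("ffnn", "cfnn", "rnn"):
        impl = _NeuralNetClassifier(
            arch=family,
            hidden=int(hp.get("hidden", 10)),
            seed=spec.seed,
            max_iter=int(hp.get("max_iter", 200)),
        ).fit(X, y01)
        kind = "net"
    elif family == "grnn":
        impl = _GRNNClassifier(spread=float(hp.get("spread", 1.0))).fit(X, y01)
        kind = "net"
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(family)
    model = Model(impl, classes, kind)
    model.n_features_ = X.shape[1]
    return model


def predict(model: Model, X) -> np.ndarray:
    """Predict one label per row (functional alias for ``model.predict``)."""
    return model.predict(X)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


@dataclass
class CVResult:
    metrics: Metrics
    counts: ConfusionCounts
    fold_counts: list[ConfusionCounts]
    spec: ClassifierSpec
    folds: int
    seed: int


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def cross_validate(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> CVResult:
    """Stratified k-fold CV with confusion counts pooled over folds.

    Every record is tested exactly once; features are z-scored with
    statistics fit on each training split only.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(matrix.labels)
    y01, classes = _encode_labels(y)
    counts_per_class = np.bincount(y01)
    if counts_per_class.min() < folds:
        raise ValueError(
            f"smallest class ({counts_per_class.min()} records) is smaller "
            f"than the fold count {folds}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts()
    fold_counts = []
    X = matrix.values
    for train_idx, test_idx in skf.split(X, y01):
        Xtr, Xte = X[train_idx], X[test_idx]
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        model = fit_classifier(spec, Xtr, y[train_idx])
        pred = model.predict(Xte)
        truth = y[test_idx]
        pos = classes[1]
        fc = ConfusionCounts(
            tp=int(np.sum((truth == pos) & (pred == pos))),
            tn=int(np.sum((truth != pos) & (pred != pos))),
            fp=int(np.sum((truth != pos) & (pred == pos))),
            fn=int(np.sum((truth == pos) & (pred != pos))),
        )
        fold_counts.append(fc)
        pooled = pooled + fc
    return CVResult(
        metrics=compute_metrics(pooled),
        counts=pooled,
        fold_counts=fold_counts,
        spec=spec,
        folds=folds,
        seed=seed,
    )


def grid_search(
    family: str,
    matrix: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
    grid: Sequence | None = None,
) -> tuple[ClassifierSpec, CVResult, list[tuple[float, CVResult]]]:
    """Best hyperparameter on the family's grid by pooled accuracy.

    KNN scans K in 1..9; SVM scans sigma in 0.1..1.5 (step 0.1).  All grid
    points share one CV partition (same seed), mirroring a
    "best value on the grid" report — optimistic relative to nested CV.
    Families without a grid are evaluated once.
    """
    if family == "knn":
        values = grid if grid is not None else KNN_K_GRID
        specs = [(v, ClassifierSpec("knn", {"k": int(v)}, seed)) for v in values]
    elif family == "svm":
        values = grid if grid is not None else SVM_SIGMA_GRID
        specs = [(v, ClassifierSpec("svm", {"sigma": float(v)}, seed)) for v in values]
    else:
        specs = [(None, ClassifierSpec(family, {}, seed))]
    results = []
    for value, spec in specs:
        results.append((value, cross_validate(spec, matrix, folds=folds, seed=seed)))
    best_value, best_res = max(results, key=lambda vr: vr[1].metrics.acc)
    best_spec = dict(specs)[best_value]
    return best_spec, best_res, results
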
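"""RBF-kernel SVM training, grid search, and per-frame prediction.

Features are standardized (training-set mean/sd) before the Gaussian kernel
K(x, y) = exp(-||x - y||^2 / (2 sigma^2)); hyperparameters (box constraint c,
kernel width sigma) come from a stratified-CV grid search.  Training is
delegated to scikit-learn's SVC, but the fitted model is stored explicitly —
support vectors, dual coefficients, bias, scaler — and prediction recomputes
the kernel sum from those, so a serialized model is self-contained.

The positive class is "wheeze"; the decision threshold is 0 on the signed
decision value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FEATURE_NAMES, FeatureVector, canonical_feature_names

__all__ = [
    "LABEL_WHEEZE",
    "LABEL_NORMAL",
    "DEFAULT_FEATURE_SET",
    "SvmModel",
    "GridSpec",
    "train_svm",
    "grid_search",
    "predict",
]

LABEL_WHEEZE = "wheeze"
LABEL_NORMAL = "normal"
DEFAULT_FEATURE_SET = ("p_t", "p_s")


def _as_matrix(features, feature_set) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=np.float64)
    return np.array([fv.as_array(feature_set) for fv in features], dtype=np.float64)


def _as_signs(labels) -> np.ndarray:
    y = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab in (LABEL_WHEEZE, 1, +1):
            y[i] = 1
        elif lab in (LABEL_NORMAL, -1, 0):
            y[i] = -1
        else:
            raise ValueError(f"unknown label {lab!r}")
    return y


@dataclass
class GridSpec:
    """Hyperparameter grid for cross-validated search."""

    c_values: tuple[float, ...] = tuple(2.0**k for k in range(-3, 8))
    sigma_values: tuple[float, ...] = tuple(2.0**k for k in range(-4, 5))
    folds: int = 5

    def __post_init__(self) -> None:
        if not self.c_values or not self.sigma_values:
            raise ValueError("grids must be non-empty")
        if self.folds < 2:
            raise ValueError("cross-validation needs at least 2 folds")


@dataclass
class SvmModel:
    """A trained RBF-SVM stored explicitly for self-contained prediction."""

    support_vectors: np.ndarray  # (m, d), in standardized feature space
    dual_coefs: np.ndarray  # (m,) signed alpha_i * y_i
    bias: float
    sigma: float
    c: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_set: tuple[str, ...] = DEFAULT_FEATURE_SET

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=np.float64)
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=np.float64).ravel()
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=np.float64)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=np.float64)
        self.feature_set = tuple(self.feature_set)
        if len(self.dual_coefs) != len(self.support_vectors):
            raise ValueError("one dual coefficient per support vector required")

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self.scaler_mean) / self.scaler_scale

    def decision_value(self, fv: FeatureVector | np.ndarray) -> float:
        """Sum_i alpha_i K(sv_i, x) + bias, recomputed from stored vectors."""
        x = fv.as_array(self.feature_set) if isinstance(fv, FeatureVector) else np.asarray(fv, float)
        if x.shape != (self.support_vectors.shape[1],):
            raise ValueError(
                f"feature dimension {x.shape} does not match model "
                f"({self.support_vectors.shape[1]} features: {self.feature_set})"
            )
        z = self._scale(x)
        sq = np.sum((self.support_vectors - z) ** 2, axis=1)
        k = np.exp(-sq / (2.0 * self.sigma**2))
        return float(self.dual_coefs @ k + self.bias)

    def predict(self, fv: FeatureVector | np.ndarray) -> tuple[str, float]:
        dv = self.decision_value(fv)
        return (LABEL_WHEEZE if dv > 0 else LABEL_NORMAL), dv

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefs": self.dual_coefs.tolist(),
            "bias": self.bias,
            "sigma": self.sigma,
            "c": self.c,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "feature_set": list(self.feature_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        return cls(
            support_vectors=np.array(d["support_vectors"]),
            dual_coefs=np.array(d["dual_coefs"]),
            bias=float(d["bias"]),
            sigma=float(d["sigma"]),
            c=float(d["c"]),
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            feature_set=tuple(d["feature_set"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fit(X: np.ndarray, y: np.ndarray, c: float, sigma: float, feature_set) -> SvmModel:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant features pass through unscaled
    Xs = (X - mean) / scale
    svc = SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * sigma**2))
    svc.fit(Xs, y)
    # classes_ is sorted [-1, +1], so positive decision values mean "wheeze"
    return SvmModel(
        support_vectors=svc.support_vectors_,
        dual_coefs=svc.dual_coef_[0],
        bias=float(svc.intercept_[0]),
        sigma=sigma,
        c=c,
        scaler_mean=mean,
        scaler_scale=scale,
        feature_set=tuple(feature_set),
    )


def train_svm(
    features,
    labels,
    c: float = 10.0,
    sigma: float = 1.0,
    feature_set=DEFAULT_FEATURE_SET,
) -> SvmModel:
    """Train a soft-margin RBF-SVM on standardized features.

    *features* may be FeatureVector objects (projected onto *feature_set*) or
    a ready (n, d) array; *labels* are "wheeze"/"normal" (or +/-1).
    """
    feature_set = canonical_feature_names(feature_set)
    X = _as_matrix(features, feature_set)
    y = _as_signs(labels)
    return _fit(X, y, c, sigma, feature_set)


def grid_search(
    features,
    labels,
    grid: GridSpec = GridSpec(),
    seed: int = 0,
    feature_set=DEFAULT_FEATURE_SET,
) -> tuple[float, float, np.ndarray]:
    """Stratified k-fold CV accuracy over the (c, sigma) grid.

    Returns (best_c, best_sigma, surface) where surface[i, j] is the CV
    accuracy at (c_values[i], sigma_values[j]).  Ties resolve to the smallest
    c, then the largest sigma.  The same seeded folds are reused for every
    grid point.
    """
    feature_set = canonical_feature_names(feature_set)
    X = _as_matrix(features, feature_set)
    y = _as_signs(labels)
    class_sizes = [int((y == v).sum()) for v in (-1, 1)]
    if min(class_sizes) < grid.folds:
        raise ValueError(
            f"fold count {grid.folds} exceeds smallest class size {min(class_sizes)}"
        )
    skf = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    surface = np.zeros((len(grid.c_values), len(grid.sigma_values)))
    for i, c in enumerate(grid.c_values):
        for j, sigma in enumerate(grid.sigma_values):
            correct = total = 0
            for train_idx, val_idx in splits:
                model = _fit(X[train_idx], y[train_idx], c, sigma, feature_set)
                for x, truth in zip(X[val_idx], y[val_idx]):
                    pred = 1 if model.decision_value(x) > 0 else -1
                    correct += int(pred == truth)
                    total += 1
            surface[i, j] = correct / total

    best_c, best_sigma, best_acc = None, None, -1.0
    for i, c in enumerate(grid.c_values):  # ascending c wins ties
        for j in range(len(grid.sigma_values) - 1, -1, -1):  # descending sigma
            if surface[i, j] > best_acc + 1e-12:
                best_acc = surface[i, j]
                best_c, best_sigma = c, grid.sigma_values[j]
    return float(best_c), float(best_sigma), surface


def predict(model: SvmModel, fv: FeatureVector | np.ndarray) -> tuple[str, float]:
    """(label, decision_value) for one feature vector."""
    return model.predict(fv)
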
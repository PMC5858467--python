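"""Linear maximum-margin classifier with squared-hinge loss.

The classifier minimizes an L2 penalty plus a C-weighted squared-hinge
term over the training rows,

    0.5 ||w||^2  +  C * sum_i max(0, 1 - y_i (<w, x_i> - b))^2,

with labels handled internally as +-1 and a linear (identity) feature
map.  The solve is delegated to liblinear in its primal mode (appropriate
when samples outnumber features, as here), which also L2-regularizes the
intercept via its augmented-feature trick; the convexity and oracle tests
account for that.

Features are standardized per column (center/scale learned on the
training rows only) before fitting unless ``standardize=False`` — band
powers span orders of magnitude and an unscaled linear margin would be
dominated by the largest band.  The stored weights refer to the
standardized space; ``decision_values`` applies the stored scaling to new
rows, so callers never see the internal representation.

Decision convention: ``f(x) = <w, x> - b``; ``predict`` assigns class 1
iff the decision value is >= 0 (ties go to the positive class, matching
the >= convention used throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .preprocessing import FeatureMatrix


@dataclass
class LinearModel:
    w: np.ndarray
    b: float
    C: float
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.w) != len(self.feature_names):
            raise ValueError("weight vector length must match feature count")
        if not np.isfinite(self.w).all() or not np.isfinite(self.b):
            raise ValueError("model parameters must be finite")

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": float(self.b),
            "C": float(self.C),
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "standardize": bool(self.standardize),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            np.asarray(d["w"], dtype=float),
            float(d["b"]),
            float(d["C"]),
            list(d["feature_names"]),
            np.asarray(d["center"], dtype=float),
            np.asarray(d["scale"], dtype=float),
            bool(d["standardize"]),
        )


def _as_array(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, FeatureMatrix):
        return X.values.to_numpy(dtype=float), X.feature_names
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    names = feature_names or [f"x{i}" for i in range(arr.shape[1])]
    return arr, list(names)


def fit(X, y, C: float = 1.0, standardize: bool = True, feature_names=None) -> LinearModel:
    """Train the linear squared-hinge SVM; deterministic given (X, y, C)."""
    arr, names = _as_array(X, feature_names)
    y = np.asarray(y, dtype=int)
    if len(y) != len(arr):
        raise ValueError("X and y must have equal row counts")
    if not np.isfinite(arr).all():
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training targets contain a single class ({classes.tolist()})")
    if standardize:
        center = arr.mean(axis=0)
        scale = arr.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        center = np.zeros(arr.shape[1])
        scale = np.ones(arr.shape[1])
    Z = (arr - center) / scale
    clf = LinearSVC(
        C=C,
        loss="squared_hinge",
        penalty="l2",
        dual=False,
        tol=1e-6,
        max_iter=50_000,
        fit_intercept=True,
    )
    clf.fit(Z, y)
    w = clf.coef_.ravel().astype(float)
    b = -float(clf.intercept_[0])  # decision = <w, z> - b
    # liblinear orients the hyperplane toward clf.classes_[1]; our targets
    # are already {0, 1} so classes_[1] == 1 and no flip is needed, but we
    # guard against label encodings where it is not.
    if clf.classes_[1] != 1:
        w, b = -w, -b
    return LinearModel(w, b, C, names, center, scale, standardize)


def _check_columns(model: LinearModel, names: list[str]) -> None:
    if names != model.feature_names:
        missing = [n for n in model.feature_names if n not in names]
        extra = [n for n in names if n not in model.feature_names]
        raise ValueError(
            f"feature columns do not match training metadata "
            f"(missing: {missing}, unexpected: {extra}, order matters)"
        )


def decision_values(model: LinearModel, X) -> np.ndarray:
    """Signed distance surrogate ``<w, x> - b`` per row."""
    arr, names = _as_array(X, model.feature_names)
    _check_columns(model, names)
    Z = (arr - model.center) / model.scale
    return Z @ model.w - model.b


def predict(model: LinearModel, X) -> np.ndarray:
    """Class 1 iff the decision value is >= 0."""
    return (decision_values(model, X) >= 0.0).astype(int)


def squared_hinge_objective(w: np.ndarray, b_aug: float, Z: np.ndarray, y_pm: np.ndarray, C: float) -> float:
    """The solver's convex objective, intercept regularized as liblinear does.

    liblinear appends a constant-1 feature whose weight is the intercept,
    so the penalty term is ``0.5 (||w||^2 + b^2)``.  Exposed for the
    convexity/oracle tests.
    """
    margins = y_pm * (Z @ w + b_aug)
    hinge = np.maximum(0.0, 1.0 - margins)
    return 0.5 * (w @ w + b_aug * b_aug) + C * float(hinge @ hinge)
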
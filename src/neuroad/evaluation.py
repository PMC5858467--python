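"""Evaluation protocol: 90/10 in-sample runs, leave-one-subject-out,
threshold-grid scans and learning curves.

The protocol mirrors the study design: one subject is always held out
untouched (out-of-sample); the remaining subjects' trials are dealt into
ten ratio-preserving folds; nine folds are augmented (Gaussian bootstrap
plus combinatorial expansion) and used for training; the tenth fold is
the in-sample test set.  Augmented rows never enter any test set — every
run proves it via the provenance tags before fitting.

Leave-one-subject-out repeats the procedure once per subject and
macro-averages the per-subject metrics (micro-averaging over pooled
trials is available by flag).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, recall_score

from . import modeling
from .augmentation import (
    BootstrapSpec,
    combinatorial_expand,
    duplicate_labels,
    gaussian_bootstrap_columns,
    stratified_tenfold,
)
from .labeling import BinarizationScheme, LabelTable, build_targets
from .preprocessing import (
    DEFAULT_FEATURES,
    FeatureMatrix,
    extract_band_series,
    flatten_trials,
    reject_abnormal,
    trim_to_category_minimum,
)

logger = logging.getLogger(__name__)


class LeakageError(AssertionError):
    """An augmented row would have reached a test set."""


@dataclass
class Dataset:
    """Aligned design matrix and questionnaire table, one row per trial."""

    X: FeatureMatrix
    labels: LabelTable

    def __post_init__(self) -> None:
        if len(self.X) != len(self.labels):
            raise ValueError("feature matrix and label table differ in length")
        if not np.array_equal(self.X.trial_ids, self.labels.trial_ids):
            raise ValueError("feature matrix and label table rows are not aligned")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.X.meta["subject_id"].unique())

    def subset(self, mask) -> "Dataset":
        idx = np.flatnonzero(mask)
        return Dataset(self.X.take(idx), self.labels.take(idx))

    def restrict_category(self, category: str) -> "Dataset":
        return self.subset((self.X.meta["category"] == category).to_numpy())

    def permuted_labels(self, seed: int) -> "Dataset":
        return Dataset(self.X, self.labels.permuted(seed))


def build_dataset(
    recordings,
    labels: LabelTable,
    bands=None,
    window_seconds: float = 1.0,
    features=None,
    flatten: str = "mean",
    quality_cut: int = 50,
    max_bad_fraction: float = 0.1,
    trim_overrides: dict | None = None,
) -> Dataset:
    """Full preprocessing path: reject, extract, trim, flatten, align."""
    from .bands import DEVICE_BANDS

    bands = bands or DEVICE_BANDS
    kept = reject_abnormal(recordings, quality_cut, max_bad_fraction)
    series = [extract_band_series(r, bands, window_seconds) for r in kept]
    series = trim_to_category_minimum(series, trim_overrides)
    X = flatten_trials(series, mode=flatten, feature_names=features)
    # align label rows to the surviving trials, in feature-matrix order
    key = pd.DataFrame({"subject_id": X.meta["subject_id"], "ad_id": X.meta["ad_id"]})
    lab = pd.concat([labels.meta, labels.answers], axis=1)
    merged = key.merge(lab, on=["subject_id", "ad_id"], how="left")
    if merged["category"].isna().any():
        missing = key[merged["category"].isna()]
        raise ValueError(f"no questionnaire rows for trials: {missing.to_dict('records')}")
    aligned = LabelTable(
        merged[[c for c in labels.answers.columns]],
        merged[["subject_id", "ad_id", "category"]],
    )
    return Dataset(X, aligned)


@dataclass
class EvaluationReport:
    accuracy: float
    recall: float
    f_score: float
    per_category: dict[str, float]
    n_train: int
    n_test: int
    scheme: BinarizationScheme
    seed: int
    accuracy_std: float = 0.0
    n_subjects: int = 1
    leakage_checked: bool = False

    def __post_init__(self) -> None:
        for name in ("accuracy", "recall", "f_score"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "f_score": self.f_score,
            "per_category": dict(self.per_category),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "accuracy_std": self.accuracy_std,
            "n_subjects": self.n_subjects,
            "leakage_checked": self.leakage_checked,
            "seed": self.seed,
            "scheme": self.scheme.__dict__.copy(),
        }
        return d


@dataclass
class LearningCurve:
    """Train/test score trajectories with dispersion bands."""

    points: pd.DataFrame  # columns: train_size, train_mean, train_std, test_mean, test_std

    def __post_init__(self) -> None:
        sizes = self.points["train_size"].to_numpy()
        if not np.all(np.diff(sizes) > 0):
            raise ValueError("train sizes must be strictly increasing")
        if (self.points[["train_std", "test_std"]].to_numpy() < 0).any():
            raise ValueError("standard deviations must be non-negative")

    @property
    def final_gap(self) -> float:
        last = self.points.iloc[-1]
        return float(abs(last["train_mean"] - last["test_mean"]))


def compute_metrics(predicted, truth) -> dict[str, float]:
    """Accuracy, positive-class recall and F1 (F = 0 when degenerate)."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal lengths")
    if len(truth) < 1:
        raise ValueError("need at least one prediction")
    return {
        "accuracy": float(accuracy_score(truth, predicted)),
        "recall": float(recall_score(truth, predicted, zero_division=0)),
        "f_score": float(f1_score(truth, predicted, zero_division=0)),
    }


def assert_no_leakage(
    augmented: FeatureMatrix, train_ids: np.ndarray, test_ids: np.ndarray
) -> None:
    """Prove every augmented row traces to a training-fold original."""
    train_set, test_set = set(train_ids), set(test_ids)
    if train_set & test_set:
        raise LeakageError(f"train/test overlap: {sorted(train_set & test_set)[:5]}")
    aug_ids = augmented.trial_ids
    bad = set(aug_ids) - train_set
    if bad:
        raise LeakageError(
            f"augmented rows trace to non-training trials: {sorted(bad)[:5]}"
        )
    if "provenance" not in augmented.meta.columns:
        raise LeakageError("augmented matrix lacks provenance tags")


def _train_augmented(
    dataset: Dataset,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_ids: np.ndarray,
    spec: BootstrapSpec,
    C: float,
    augment: bool,
):
    """Fit the classifier on (optionally augmented) training rows."""
    X_train = dataset.X.take(train_idx)
    y_train = y[train_idx]
    if augment:
        X_boot = gaussian_bootstrap_columns(X_train, spec)
        X_aug = combinatorial_expand(X_train, X_boot, spec)
        copies = len(X_aug) // len(X_train) - 1
        y_aug = duplicate_labels(y_train, copies)
        if len(y_aug) != len(X_aug):
            raise ValueError("duplicated labels do not align with expanded matrix")
        assert_no_leakage(X_aug, X_train.trial_ids, test_ids)
        return modeling.fit(X_aug, y_aug, C)
    return modeling.fit(X_train, y_train, C)


def in_sample_run(
    dataset: Dataset,
    scheme: BinarizationScheme | None = None,
    spec: BootstrapSpec | None = None,
    seed: int = 0,
    C: float = 1.0,
    holdout_subject: str | None = None,
    augment: bool = True,
) -> EvaluationReport:
    """One 90/10 in-sample evaluation.

    The held-out subject's rows never enter this run at all; the remaining
    trials are ten-folded, folds 1-9 are augmented and used for training,
    and metrics are computed on fold 10 only.
    """
    scheme = scheme or BinarizationScheme()
    spec = spec or BootstrapSpec(seed=seed)
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for an in-sample run")
    holdout = holdout_subject if holdout_subject is not None else subjects[-1]
    inner = dataset.subset((dataset.X.meta["subject_id"] != holdout).to_numpy())
    y = build_targets(inner.labels, scheme)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate targets: single class under this scheme")
    folds = stratified_tenfold(y, seed)
    test_idx = folds.indices(10)
    train_idx = np.flatnonzero(folds.fold_of != 10)
    test_ids = inner.X.take(test_idx).trial_ids
    model = _train_augmented(inner, y, train_idx, test_ids, spec, C, augment)
    X_test = inner.X.take(test_idx)
    pred = modeling.predict(model, X_test)
    truth = y[test_idx]
    core = compute_metrics(pred, truth)
    per_cat: dict[str, float] = {}
    cats = X_test.meta["category"].to_numpy()
    for cat in sorted(set(cats)):
        m = cats == cat
        per_cat[cat] = float(accuracy_score(truth[m], pred[m]))
    return EvaluationReport(
        accuracy=core["accuracy"],
        recall=core["recall"],
        f_score=core["f_score"],
        per_category=per_cat,
        n_train=len(train_idx),
        n_test=len(test_idx),
        scheme=scheme,
        seed=seed,
        leakage_checked=augment,
    )


def leave_one_subject_out(
    dataset: Dataset,
    scheme: BinarizationScheme | None = None,
    spec: BootstrapSpec | None = None,
    seed: int = 0,
    C: float = 1.0,
    augment: bool = True,
    micro: bool = False,
) -> EvaluationReport:
    """Average of per-subject out-of-sample evaluations.

    For each subject s the model is trained exactly as in
    :func:`in_sample_run` on all other subjects (ten-fold, folds 1-9
    augmented) and evaluated on s's trials.  Macro-averaging over subjects
    is the default; ``micro=True`` pools all out-of-sample trials instead.
    """
    scheme = scheme or BinarizationScheme()
    spec = spec or BootstrapSpec(seed=seed)
    subjects = dataset.subjects
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for leave-one-subject-out")
    per_subject: list[dict[str, float]] = []
    per_cat_acc: dict[str, list[float]] = {}
    pooled_pred: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    y_all = build_targets(dataset.labels, scheme)
    n_test_total = 0
    for s in subjects:
        mask_out = (dataset.X.meta["subject_id"] == s).to_numpy()
        if not mask_out.any():
            warnings.warn(f"subject {s} has zero trials; skipped")
            continue
        inner = dataset.subset(~mask_out)
        y = build_targets(inner.labels, scheme)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate targets: single class under this scheme")
        folds = stratified_tenfold(y, seed)
        train_idx = np.flatnonzero(folds.fold_of != 10)
        out = dataset.subset(mask_out)
        model = _train_augmented(inner, y, train_idx, out.X.trial_ids, spec, C, augment)
        pred = modeling.predict(model, out.X)
        truth = y_all[mask_out]
        per_subject.append(compute_metrics(pred, truth))
        pooled_pred.append(pred)
        pooled_truth.append(truth)
        n_test_total += len(truth)
        cats = out.X.meta["category"].to_numpy()
        for cat in sorted(set(cats)):
            m = cats == cat
            per_cat_acc.setdefault(cat, []).append(float(accuracy_score(truth[m], pred[m])))
    if not per_subject:
        raise ValueError("no subject produced an evaluation")
    if micro:
        pred = np.concatenate(pooled_pred)
        truth = np.concatenate(pooled_truth)
        core = compute_metrics(pred, truth)
        acc_std = 0.0
    else:
        core = {
            k: float(np.mean([m[k] for m in per_subject]))
            for k in ("accuracy", "recall", "f_score")
        }
        acc_std = float(np.std([m["accuracy"] for m in per_subject]))
    per_cat = {cat: float(np.mean(v)) for cat, v in per_cat_acc.items()}
    return EvaluationReport(
        accuracy=core["accuracy"],
        recall=core["recall"],
        f_score=core["f_score"],
        per_category=per_cat,
        n_train=len(dataset) - n_test_total // max(len(per_subject), 1),
        n_test=n_test_total,
        scheme=scheme,
        seed=seed,
        accuracy_std=acc_std,
        n_subjects=len(per_subject),
        leakage_checked=augment,
    )


def threshold_grid_scan(
    dataset: Dataset,
    ranked_set,
    binary_set,
    dataset_set,
    label_group: str = "combined",
    spec: BootstrapSpec | None = None,
    seed: int = 0,
    C: float = 1.0,
    augment: bool = True,
    include_categories: bool = True,
) -> pd.DataFrame:
    """In-sample accuracy over the full Cartesian threshold grid.

    Returns a long-form table with one row per (scope, ranked, binary,
    dataset-threshold) cell; degenerate cells (single-class targets) are
    NA.  ``grid_table`` pivots a scope into the published row/column
    layout.
    """
    if not (len(list(ranked_set)) and len(list(binary_set)) and len(list(dataset_set))):
        raise ValueError("threshold sets must be nonempty")
    scopes = ["all"]
    if include_categories:
        scopes += sorted(dataset.X.meta["category"].unique())
    rows = []
    for scope in scopes:
        ds = dataset if scope == "all" else dataset.restrict_category(scope)
        for rt in ranked_set:
            for bt in binary_set:
                for dt in dataset_set:
                    scheme = BinarizationScheme(
                        ranked_threshold=rt,
                        binary_threshold=bt,
                        dataset_threshold=dt,
                        label_group=label_group,
                    )
                    try:
                        rep = in_sample_run(
                            ds, scheme, spec, seed=seed, C=C, augment=augment
                        )
                        acc = rep.accuracy
                    except ValueError:
                        acc = np.nan
                    rows.append(
                        {
                            "scope": scope,
                            "ranked_threshold": rt,
                            "binary_threshold": bt,
                            "dataset_threshold": dt,
                            "accuracy": acc,
                        }
                    )
    return pd.DataFrame(rows)


def grid_table(grid: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Pivot one scope of a grid scan into rows (ranked, binary) x dataset."""
    sub = grid[grid["scope"] == scope]
    return sub.pivot_table(
        index=["ranked_threshold", "binary_threshold"],
        columns="dataset_threshold",
        values="accuracy",
        dropna=False,
    )


def _stratified_subsample(
    idx: np.ndarray, y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Class-proportional subsample keeping at least one row per class."""
    take: list[np.ndarray] = []
    for cls in np.unique(y[idx]):
        cls_idx = idx[y[idx] == cls]
        k = max(1, int(round(fraction * len(cls_idx))))
        take.append(rng.permutation(cls_idx)[:k])
    return np.sort(np.concatenate(take))


def learning_curve(
    dataset: Dataset,
    scheme: BinarizationScheme | None = None,
    sizes=(0.2, 0.4, 0.6, 0.8, 1.0),
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> LearningCurve:
    """Cross-validated train/test accuracy versus training-set size.

    Folds reuse the stratified ten-fold construction (the first
    ``n_folds`` folds rotate as test sets); per size, the training pool is
    subsampled class-proportionally.  The x-axis counts pre-augmentation
    training rows; no augmentation is applied inside the curve.
    """
    scheme = scheme or BinarizationScheme()
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])) or not sizes:
        raise ValueError("sizes must be strictly increasing and nonempty")
    if not 1 <= n_folds <= 10:
        raise ValueError("n_folds must lie in 1..10")
    y = build_targets(dataset.labels, scheme)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate targets: single class under this scheme")
    folds = stratified_tenfold(y, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1C]))
    records = []
    for frac in sizes:
        tr_scores, te_scores, n_used = [], [], []
        for f in range(1, n_folds + 1):
            test_idx = folds.indices(f)
            pool = np.flatnonzero(folds.fold_of != f)
            sub = _stratified_subsample(pool, y, frac, rng)
            if len(np.unique(y[sub])) < 2 or len(np.unique(y[test_idx])) < 1:
                continue
            model = modeling.fit(dataset.X.take(sub), y[sub], C)
            tr_scores.append(
                float(accuracy_score(y[sub], modeling.predict(model, dataset.X.take(sub))))
            )
            te_scores.append(
                float(accuracy_score(y[test_idx], modeling.predict(model, dataset.X.take(test_idx))))
            )
            n_used.append(len(sub))
        if not tr_scores:
            warnings.warn(f"size {frac}: no fold had both classes; skipped")
            continue
        records.append(
            {
                "train_size": int(round(np.mean(n_used))),
                "train_mean": float(np.mean(tr_scores)),
                "train_std": float(np.std(tr_scores)),
                "test_mean": float(np.mean(te_scores)),
                "test_std": float(np.std(te_scores)),
            }
        )
    if not records:
        raise ValueError("no learning-curve point could be computed")
    return LearningCurve(pd.DataFrame(records))
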
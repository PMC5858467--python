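"""Resampling algorithms for sparse trial tables.

Three bespoke procedures expand a small trials-by-features design matrix
before classifier training:

1. **Ratio-preserving ten-fold construction** — indices of each class are
   shuffled and dealt so folds 1-9 each receive ``round(ones/10)`` positive
   and ``round(zeros/10)`` negative trials; fold 10 holds all leftovers.
2. **Per-column scaled Gaussian bootstrap** — each entry is perturbed by
   ``scale * g`` where ``scale = 0.5 * (col_min + col_max)`` and ``g`` is a
   standard normal truncated to the open interval (-1, 1).  The
   perturbation is therefore bounded by the scale, leaving the column's
   spread intact.
3. **Combinatorial column-replacement expansion** — for each subset of
   feature columns (sizes in ``r_range``, enumeration capped), a copy of
   the original matrix is emitted with those columns replaced by their
   bootstrapped versions; labels are duplicated row-for-row to match.

All randomness flows from a single seed via numpy ``SeedSequence``
spawning, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .preprocessing import FeatureMatrix

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of trial indices into ten folds preserving class ratio."""

    fold_of: np.ndarray          # index -> fold id in 1..10
    ratio: float                 # positive-class proportion of the input
    ones_per_fold: int           # planned positives in folds 1..9
    zeros_per_fold: int          # planned negatives in folds 1..9

    def __post_init__(self) -> None:
        fold_of = np.asarray(self.fold_of, dtype=int)
        object.__setattr__(self, "fold_of", fold_of)
        if fold_of.min() < 1 or fold_of.max() > 10:
            raise ValueError("fold ids must lie in 1..10")

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def counts(self, targets: np.ndarray) -> pd.DataFrame:
        """Per-fold one/zero counts for inspection."""
        targets = np.asarray(targets)
        rows = []
        for f in range(1, 11):
            idx = self.indices(f)
            rows.append(
                {"fold": f, "ones": int(targets[idx].sum()), "zeros": int((1 - targets[idx]).sum())}
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial_index": np.arange(len(self.fold_of)), "fold": self.fold_of}
        )


@dataclass(frozen=True)
class BootstrapSpec:
    """Parameters of the Gaussian bootstrap and combinatorial expansion."""

    seed: int = 0
    r_range: tuple[int, ...] = tuple(range(1, 13))
    max_copies_per_r: int = 20
    expansion_cap: int | None = None  # total augmented-row ceiling; None -> 50 * n_rows

    def __post_init__(self) -> None:
        if self.max_copies_per_r < 1:
            raise ValueError("max_copies_per_r must be >= 1")
        if self.expansion_cap is not None and self.expansion_cap < 1:
            raise ValueError("expansion_cap must be >= 1")
        if any(r < 1 for r in self.r_range):
            raise ValueError("subset sizes must be >= 1")


def stratified_tenfold(targets, seed: int) -> FoldAssignment:
    """Deal shuffled class indices into ten ratio-preserving folds.

    Folds 1-9 receive ``round(n_ones/10)`` positives and
    ``round(n_zeros/10)`` negatives each (round-half-up); fold 10 takes
    whatever is left.  When a class is so small that nine folds exhaust it
    early, later folds simply receive fewer — the slicing semantics keep
    the folds a disjoint, exhaustive partition in every case.
    """
    y = np.asarray(targets, dtype=int)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 trials to build ten folds")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("targets contain a single class; stratification undefined")
    rng = np.random.default_rng(seed)
    idx_ones = rng.permutation(np.flatnonzero(y == 1))
    idx_zeros = rng.permutation(np.flatnonzero(y == 0))
    n_ones, n_zeros = len(idx_ones), len(idx_zeros)
    ratio = n_ones / n
    ones = (n_ones + 5) // 10   # round-half-up of n_ones / 10
    zeros = (n_zeros + 5) // 10
    fold_of = np.empty(n, dtype=int)
    for i in range(9):
        fold_of[idx_ones[i * ones : (i + 1) * ones]] = i + 1
        fold_of[idx_zeros[i * zeros : (i + 1) * zeros]] = i + 1
    fold_of[idx_ones[9 * ones :]] = 10
    fold_of[idx_zeros[9 * zeros :]] = 10
    return FoldAssignment(fold_of, ratio, ones, zeros)


def _truncated_normal_open(rng: np.random.Generator, size: int) -> np.ndarray:
    """Standard normal truncated to (-1, 1) by rejection sampling."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        need = size - filled
        draw = rng.standard_normal(max(int(need * 1.6) + 8, 16))
        keep = draw[(draw > -1.0) & (draw < 1.0)][:need]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def gaussian_bootstrap_columns(X: FeatureMatrix, spec: BootstrapSpec) -> FeatureMatrix:
    """Perturb every entry by its column's scaled truncated-normal draw.

    ``scale = 0.5 * (col_min + col_max)``; a column with ``min + max == 0``
    (e.g. all-zero) has scale 0 and passes through unchanged.
    """
    arr = X.values.to_numpy(dtype=float)
    if arr.shape[0] < 1:
        raise ValueError("need at least one row to bootstrap")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x01]))
    out = arr.copy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        scale = 0.5 * (col.min() + col.max())
        if scale == 0.0:
            logger.info("column %s has min+max = 0; passed through", X.feature_names[j])
            continue
        g = _truncated_normal_open(rng, len(col))
        out[:, j] = col + scale * g
    return FeatureMatrix(
        pd.DataFrame(out, columns=X.feature_names), X.meta.copy()
    )


def _choose_subsets(
    k: int, r: int, cap: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Up to ``cap`` distinct r-subsets of range(k), deterministic under rng."""
    total = comb(k, r)
    if total <= cap:
        return list(combinations(range(k), r))
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < cap:
        pick = tuple(sorted(rng.choice(k, size=r, replace=False).tolist()))
        chosen.add(pick)
    return sorted(chosen)


def expansion_copy_count(n_cols: int, spec: BootstrapSpec, n_rows: int | None = None) -> int:
    """Closed-form number of emitted copies: sum_r min(C(k, r), cap), capped."""
    copies = sum(
        min(comb(n_cols, r), spec.max_copies_per_r)
        for r in spec.r_range
        if r <= n_cols
    )
    if n_rows is not None:
        cap_rows = spec.expansion_cap if spec.expansion_cap is not None else 50 * n_rows
        copies = min(copies, cap_rows // n_rows)
    return copies


def combinatorial_expand(
    X_orig: FeatureMatrix, X_boot: FeatureMatrix, spec: BootstrapSpec
) -> FeatureMatrix:
    """Original rows followed by one copy per selected column subset.

    Each copy replaces the subset's columns with their bootstrapped
    versions.  Enumeration per subset size is capped at
    ``max_copies_per_r`` (random distinct subsets under the spec seed when
    the full enumeration exceeds the cap); the total emitted copies are
    truncated at ``expansion_cap // n_rows`` whole copies.  Every copy's
    meta rows carry a ``provenance`` tag naming the replaced columns.
    """
    if X_orig.values.shape != X_boot.values.shape or X_orig.feature_names != X_boot.feature_names:
        raise ValueError("X_orig and X_boot must have identical shape and columns")
    arr_o = X_orig.values.to_numpy(dtype=float)
    arr_b = X_boot.values.to_numpy(dtype=float)
    n_rows, k = arr_o.shape
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x02]))
    max_copies = expansion_copy_count(k, spec, n_rows)

    blocks = [arr_o]
    meta_orig = X_orig.meta.copy()
    meta_orig["provenance"] = "original"
    metas = [meta_orig]
    emitted = 0
    for r in sorted(set(spec.r_range)):
        if r > k or emitted >= max_copies:
            continue
        for subset in _choose_subsets(k, r, spec.max_copies_per_r, rng):
            if emitted >= max_copies:
                break
            block = arr_o.copy()
            block[:, list(subset)] = arr_b[:, list(subset)]
            blocks.append(block)
            meta = X_orig.meta.copy()
            meta["provenance"] = f"boot:r={r}:cols={'-'.join(map(str, subset))}"
            metas.append(meta)
            emitted += 1
    values = pd.DataFrame(np.vstack(blocks), columns=X_orig.feature_names)
    meta = pd.concat(metas, ignore_index=True)
    return FeatureMatrix(values, meta)


def duplicate_labels(y, copies: int) -> np.ndarray:
    """Repeat the target vector to align with the expanded design matrix."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    y = np.asarray(y)
    return np.tile(y, copies + 1)
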
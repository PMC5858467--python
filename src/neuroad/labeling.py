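"""Questionnaire representation and threshold binarization.

Each trial carries a 22-item questionnaire: items Y1-Y11 are 7-point
ranked answers (content quality, excitement, willingness to buy, ...),
items Y12-Y22 are yes/no answers (celebrity present, story-telling, ...).
The prediction target is a single 0/1 "positive impression" flag obtained
by binarizing every answer against a per-type threshold and thresholding
the mean of the binarized answers against a dataset-level threshold.

Conventions (documented because they are interpretations, not physics):

* Binarization uses ``value >= threshold -> 1``.  At the ranked-scale
  midpoint threshold 4 this keeps the midpoint in the positive class; the
  half-integer thresholds (3.5, 4.5) are tie-free either way.
* Aggregation is the *mean* of the binarized answers in the selected
  group compared against ``dataset_threshold`` — the only reading under
  which dataset thresholds like 0.4/0.5/0.6 act as proportions.
* For the combined group the two per-type means are weighted by
  ``alpha`` (ranked) and ``beta`` (binary) with ``alpha + beta = 1``;
  ``combined_threshold`` reports the single blended threshold
  ``alpha * ranked_threshold + beta * binary_threshold``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKED_COLUMNS = [f"Y{i}" for i in range(1, 12)]
BINARY_COLUMNS = [f"Y{i}" for i in range(12, 23)]
ANSWER_COLUMNS = RANKED_COLUMNS + BINARY_COLUMNS

RANKED_SCALE = (1, 7)
BINARY_SCALE = (0, 1)


def scale_midpoint(low: float, high: float) -> float:
    """Midpoint of an answer scale, the natural default threshold."""
    return (low + high) / 2


@dataclass
class LabelTable:
    """Trials x 22 questionnaire answers with per-row trial metadata."""

    answers: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANSWER_COLUMNS if c not in self.answers.columns]
        if missing:
            raise ValueError(f"missing answer columns: {missing}")
        if len(self.answers) != len(self.meta):
            raise ValueError("answers and meta must have equal row counts")
        ranked = self.answers[RANKED_COLUMNS].to_numpy()
        binary = self.answers[BINARY_COLUMNS].to_numpy()
        if np.isnan(ranked).any() or np.isnan(binary).any():
            raise ValueError("label table contains missing values")
        if not np.array_equal(ranked, np.round(ranked)) or ranked.min() < 1 or ranked.max() > 7:
            raise ValueError("ranked answers must be integers in [1, 7]")
        if not np.isin(binary, (0, 1)).all():
            raise ValueError("binary answers must be 0 or 1")
        self.answers = self.answers.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.answers)

    @property
    def trial_ids(self) -> np.ndarray:
        return (self.meta["subject_id"] + "|" + self.meta["ad_id"]).to_numpy()

    def take(self, indices) -> "LabelTable":
        return LabelTable(
            self.answers.iloc[indices].reset_index(drop=True),
            self.meta.iloc[indices].reset_index(drop=True),
        )

    def permuted(self, seed: int) -> "LabelTable":
        """Answers shuffled across trials (metadata kept) — permutation null."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(self))
        return LabelTable(self.answers.iloc[perm].reset_index(drop=True), self.meta.copy())


@dataclass(frozen=True)
class BinarizationScheme:
    """Thresholds and weights turning 22 mixed answers into one 0/1 target."""

    ranked_threshold: float = scale_midpoint(*RANKED_SCALE)  # 4.0
    binary_threshold: float = scale_midpoint(*BINARY_SCALE)  # 0.5
    alpha: float = 0.5
    beta: float = 0.5
    dataset_threshold: float = 0.4
    label_group: str = "ranked"  # ranked | binary | combined | single:Yi

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if self.label_group == "combined" and abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("combined group requires alpha + beta = 1")
        if self.label_group not in ("ranked", "binary", "combined") and not re.fullmatch(
            r"single:Y([1-9]|1[0-9]|2[0-2])", self.label_group
        ):
            raise ValueError(f"invalid label_group {self.label_group!r}")


def binarize_ranked(value: int, threshold: float) -> int:
    """1 iff a 7-point answer meets the threshold."""
    if value != int(value) or not 1 <= value <= 7:
        raise ValueError(f"ranked answer must be an integer in [1, 7], got {value}")
    return int(value >= threshold)


def binarize_binary(value: int, threshold: float) -> int:
    """1 iff a yes/no answer meets the threshold (threshold 0 admits all)."""
    if value not in (0, 1):
        raise ValueError(f"binary answer must be 0 or 1, got {value}")
    return int(value >= threshold)


def combined_threshold(scheme: BinarizationScheme) -> float:
    """The blended per-answer threshold alpha*ranked + beta*binary."""
    if abs(scheme.alpha + scheme.beta - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    return scheme.alpha * scheme.ranked_threshold + scheme.beta * scheme.binary_threshold


def _aggregate_scores(answers: pd.DataFrame, scheme: BinarizationScheme) -> np.ndarray:
    """Per-row aggregate in [0, 1] before the dataset-level threshold."""
    ranked = answers[RANKED_COLUMNS].to_numpy(dtype=float)
    binary = answers[BINARY_COLUMNS].to_numpy(dtype=float)
    ranked_part = (ranked >= scheme.ranked_threshold).mean(axis=1)
    binary_part = (binary >= scheme.binary_threshold).mean(axis=1)
    group = scheme.label_group
    if group == "ranked":
        return ranked_part
    if group == "binary":
        return binary_part
    if group == "combined":
        return scheme.alpha * ranked_part + scheme.beta * binary_part
    # single:Yi
    col = group.split(":", 1)[1]
    vals = answers[col].to_numpy(dtype=float)
    if col in RANKED_COLUMNS:
        return (vals >= scheme.ranked_threshold).astype(float)
    return (vals >= scheme.binary_threshold).astype(float)


def aggregate_target(row, scheme: BinarizationScheme) -> int:
    """Single-trial 0/1 target from one questionnaire row.

    ``row`` is anything indexable by answer-column name (a pandas Series,
    a dict, or a one-row DataFrame slice).
    """
    if isinstance(row, pd.Series):
        frame = row.to_frame().T
    elif isinstance(row, dict):
        frame = pd.DataFrame([row])
    else:
        frame = pd.DataFrame(row)
    score = _aggregate_scores(frame, scheme)[0]
    return int(score >= scheme.dataset_threshold)


def build_targets(table: LabelTable, scheme: BinarizationScheme) -> np.ndarray:
    """Vectorized target construction for a whole label table."""
    scores = _aggregate_scores(table.answers, scheme)
    targets = (scores >= scheme.dataset_threshold).astype(int)
    if len(targets):
        logger.info(
            "targets: %d/%d positive (%.3f)", targets.sum(), len(targets), targets.mean()
        )
    return targets
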
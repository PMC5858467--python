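"""From raw single-channel voltage to the device feature schema.

The acquisition chipset emits, once per second, a 13-column record:
a timestamp, a signal-quality byte, the raw voltage, two proprietary
0-100 "mental state" scores (Attention, Meditation) and eight FFT band
powers.  This module reproduces that schema from raw voltage: trials with
too many poor-quality samples are rejected, each surviving trial is cut
into non-overlapping windows, band powers are computed from the one-sided
periodogram of each window, trials are trimmed to their category's minimum
length, and a per-trial design matrix is assembled.

Band power of band ``[low, high)`` is the sum of per-bin periodogram power
over bins whose frequency lies in the interval, normalized so that the sum
over *all* bins equals the window's signal energy (Parseval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import DEVICE_BANDS, BandDefinitions

logger = logging.getLogger(__name__)

#: The 13 per-timestamp columns of the device schema, in canonical order.
TABLE_COLUMNS = [
    "TimeStamp",
    "SignalQuality",
    "Raw",
    "Attention",
    "Meditation",
    "Delta",
    "Theta",
    "LowAlpha",
    "HighAlpha",
    "LowBeta",
    "HighBeta",
    "LowGamma",
    "HighGamma",
]

BAND_COLUMNS = TABLE_COLUMNS[5:]

#: The 11 modeling features: the eight band powers plus Raw, Attention,
#: Meditation.  TimeStamp and SignalQuality are bookkeeping, never features.
DEFAULT_FEATURES = BAND_COLUMNS + ["Raw", "Attention", "Meditation"]

META_COLUMNS = ["subject_id", "ad_id", "category"]

CATEGORIES = ("car", "clothing", "digital", "food")


@dataclass(frozen=True)
class RawRecording:
    """One trial's voltage time series with acquisition metadata."""

    subject_id: str
    ad_id: str
    category: str
    sample_rate: float
    voltage: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        voltage = np.asarray(self.voltage, dtype=float)
        quality = np.asarray(self.quality)
        object.__setattr__(self, "voltage", voltage)
        object.__setattr__(self, "quality", quality)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if voltage.shape != quality.shape or voltage.ndim != 1:
            raise ValueError("voltage and quality must be 1-D arrays of equal length")
        if quality.size and (quality.min() < 0 or quality.max() > 255):
            raise ValueError("quality values must lie in [0, 255]")

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}|{self.ad_id}"

    @property
    def duration(self) -> float:
        return len(self.voltage) / self.sample_rate


@dataclass
class BandFeatureSeries:
    """Per-timestamp feature records for one trial (device schema)."""

    subject_id: str
    ad_id: str
    category: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        ts = self.data["TimeStamp"].to_numpy()
        if len(ts) and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        bands = self.data[BAND_COLUMNS].to_numpy()
        if len(bands) and bands.min() < 0:
            raise ValueError("band powers must be non-negative")
        esense = self.data[["Attention", "Meditation"]].to_numpy()
        if len(esense) and (esense.min() < 0 or esense.max() > 100):
            raise ValueError("Attention/Meditation must lie in [0, 100]")

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}|{self.ad_id}"

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FeatureMatrix:
    """Trials x selected-features design matrix with per-row metadata.

    ``values`` holds one row per trial and one numeric column per feature;
    ``meta`` holds the aligned subject/ad/category columns (plus an optional
    ``provenance`` column added by augmentation).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta must have equal row counts")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("feature matrix contains non-finite values")
        self.values = self.values.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def trial_ids(self) -> np.ndarray:
        return (self.meta["subject_id"] + "|" + self.meta["ad_id"]).to_numpy()

    def __len__(self) -> int:
        return len(self.values)

    def take(self, indices) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.iloc[indices].reset_index(drop=True),
            self.meta.iloc[indices].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.meta, self.values], axis=1)


def reject_abnormal(
    recordings,
    quality_cut: int = 50,
    max_bad_fraction: float = 0.1,
):
    """Drop trials whose poor-quality sample fraction exceeds the cutoff.

    A sample is "bad" when its quality byte exceeds ``quality_cut`` (higher
    quality values mean worse contact on this device family); a trial is
    rejected when its bad fraction exceeds ``max_bad_fraction``.
    """
    if not 0 <= max_bad_fraction <= 1:
        raise ValueError("max_bad_fraction must lie in [0, 1]")
    survivors, dropped = [], []
    for rec in recordings:
        bad = float(np.mean(np.asarray(rec.quality) > quality_cut))
        if bad > max_bad_fraction:
            dropped.append(rec.trial_id)
        else:
            survivors.append(rec)
    if dropped:
        logger.info("rejected %d trials for voltage abnormality: %s", len(dropped), dropped)
    if not survivors:
        raise ValueError(
            f"all {len(dropped)} trials rejected "
            f"(quality_cut={quality_cut}, max_bad_fraction={max_bad_fraction})"
        )
    return survivors


def periodogram_power(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided per-bin power of a real segment, summing to its energy.

    Returns (freqs, power) such that ``power.sum() == (segment ** 2).sum()``
    exactly (up to float rounding) — the discrete Parseval identity.  The
    frequency axis assumes unit sample spacing; scale by the sample rate
    outside.
    """
    n = len(segment)
    spec = np.fft.rfft(segment)
    power = np.abs(spec) ** 2 / n
    # double interior bins of the one-sided spectrum (DC and, for even n,
    # Nyquist appear once in the full spectrum)
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n)
    return freqs, power


def _esense_proxy(delta_row: dict) -> tuple[float, float]:
    """Bounded [0, 100] Attention/Meditation proxies from band ratios.

    The device's eSense formulas are proprietary and unpublished; any
    bounded monotone function of the Beta-vs-(Alpha+Theta) and
    Alpha-vs-Beta balance serves the pipeline.  We use energy fractions,
    which are monotone in the corresponding ratios and naturally bounded.
    """
    alpha = delta_row["LowAlpha"] + delta_row["HighAlpha"]
    beta = delta_row["LowBeta"] + delta_row["HighBeta"]
    theta = delta_row["Theta"]
    denom_a = beta + alpha + theta
    attention = 100.0 * beta / denom_a if denom_a > 0 else 0.0
    denom_m = alpha + beta
    meditation = 100.0 * alpha / denom_m if denom_m > 0 else 0.0
    return attention, meditation


def extract_band_series(
    raw: RawRecording,
    bands: BandDefinitions = DEVICE_BANDS,
    window_seconds: float = 1.0,
) -> BandFeatureSeries:
    """FFT band powers per non-overlapping window of one recording.

    One output record ("timestamp") per full window.  Band power is the sum
    of one-sided periodogram bins with frequency in ``[low, high)``; the
    ``Raw`` column is the window-mean voltage and ``SignalQuality`` the
    window-mean quality byte.  Attention/Meditation are bounded band-ratio
    proxies (see :func:`_esense_proxy`).
    """
    n_win = int(round(window_seconds * raw.sample_rate))
    if n_win < 2:
        raise ValueError("window must span at least 2 samples")
    n_windows = len(raw.voltage) // n_win
    if n_windows == 0:
        raise ValueError(
            f"recording {raw.trial_id} shorter ({len(raw.voltage)} samples) "
            f"than one window ({n_win} samples)"
        )
    nyquist = raw.sample_rate / 2.0
    capped = bands.capped(nyquist)
    rows = []
    for w in range(n_windows):
        seg = raw.voltage[w * n_win : (w + 1) * n_win]
        qual = raw.quality[w * n_win : (w + 1) * n_win]
        freqs, power = periodogram_power(seg)
        freqs_hz = freqs * raw.sample_rate
        row = {
            "TimeStamp": w,
            "SignalQuality": float(np.mean(qual)),
            "Raw": float(np.mean(seg)),
        }
        for name in BAND_COLUMNS:
            try:
                low, high = capped.edges(name)
            except KeyError:
                row[name] = 0.0
                continue
            mask = (freqs_hz >= low) & (freqs_hz < high)
            row[name] = float(power[mask].sum())
        row["Attention"], row["Meditation"] = _esense_proxy(row)
        rows.append(row)
    data = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return BandFeatureSeries(raw.subject_id, raw.ad_id, raw.category, data)


def trim_to_category_minimum(series_list, overrides: dict | None = None):
    """Truncate every trial to its category's minimum timestamp count.

    ``overrides`` maps category -> target length (e.g. the study's published
    per-category lengths); an override longer than some trial is an error.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no series to trim")
    lengths: dict[str, int] = {}
    for s in series_list:
        lengths[s.category] = min(lengths.get(s.category, len(s)), len(s))
    if overrides:
        for cat, target in overrides.items():
            if cat not in lengths:
                raise ValueError(f"override for unknown category {cat!r}")
            for s in series_list:
                if s.category == cat and len(s) < target:
                    raise ValueError(
                        f"override {target} for category {cat!r} exceeds "
                        f"trial {s.trial_id} length {len(s)}"
                    )
            lengths[cat] = target
    out = []
    for s in series_list:
        target = lengths[s.category]
        out.append(
            BandFeatureSeries(
                s.subject_id, s.ad_id, s.category, s.data.iloc[:target].reset_index(drop=True)
            )
        )
    return out


def select_features(series: BandFeatureSeries, feature_names=None) -> pd.DataFrame:
    """Column-subset of a trial's records, in the requested order.

    TimeStamp and SignalQuality are bookkeeping columns and are rejected.
    """
    names = list(DEFAULT_FEATURES if feature_names is None else feature_names)
    valid = set(TABLE_COLUMNS) - {"TimeStamp", "SignalQuality"}
    bad = [n for n in names if n not in valid]
    if bad:
        raise ValueError(f"unknown or excluded feature(s) {bad}; valid features: {sorted(valid)}")
    return series.data[names].copy()


def flatten_trials(series_list, mode: str = "mean", feature_names=None) -> FeatureMatrix:
    """One row per trial from per-timestamp records.

    ``mean`` averages each feature over timestamps (fixed width, categories
    poolable); ``concat`` concatenates feature x timestamp (width differs by
    category, so mixing categories is rejected).
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("no series to flatten")
    if mode not in ("mean", "concat"):
        raise ValueError(f"unknown flatten mode {mode!r}")
    names = list(DEFAULT_FEATURES if feature_names is None else feature_names)
    if mode == "concat":
        cats = {s.category for s in series_list}
        if len(cats) > 1:
            raise ValueError(
                f"concat mode cannot pool categories of different trimmed "
                f"lengths (got {sorted(cats)}); flatten per category or use mode='mean'"
            )
        lengths = {len(s) for s in series_list}
        if len(lengths) > 1:
            raise ValueError("concat mode requires trimmed (equal-length) trials")
    rows, meta = [], []
    for s in series_list:
        sel = select_features(s, names)
        if mode == "mean":
            rows.append(sel.mean(axis=0).to_numpy())
        else:
            rows.append(sel.to_numpy().T.ravel())  # feature-major: f0 t0..tn, f1 t0..tn, ...
        meta.append({"subject_id": s.subject_id, "ad_id": s.ad_id, "category": s.category})
    if mode == "mean":
        columns = names
    else:
        n_t = len(series_list[0])
        columns = [f"{f}_t{t}" for f in names for t in range(n_t)]
    values = pd.DataFrame(np.asarray(rows), columns=columns)
    return FeatureMatrix(values, pd.DataFrame(meta))
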
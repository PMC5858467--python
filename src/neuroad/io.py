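"""CSV/JSON file formats and run configuration.

All tabular artifacts are plain headered CSV (UTF-8, "." decimal): the
acquisition device emits tabular per-second records, not clinical EEG
containers, so CSV round-trips the data losslessly.  Every file written
here starts with a provenance comment line carrying the config hash and
seed; readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augmentation import BootstrapSpec, FoldAssignment
from .labeling import ANSWER_COLUMNS, BINARY_COLUMNS, RANKED_COLUMNS, BinarizationScheme, LabelTable
from .modeling import LinearModel
from .preprocessing import (
    META_COLUMNS,
    TABLE_COLUMNS,
    BandFeatureSeries,
    FeatureMatrix,
    RawRecording,
)
from .synthetic import SyntheticConfig

RAW_COLUMNS = META_COLUMNS + ["sample_rate", "voltage", "quality"]


def _provenance_line(config_hash: str | None, seed: int | None) -> str:
    return f"# neuroad config_hash={config_hash or 'none'} seed={'none' if seed is None else seed}\n"


def _write_csv(df: pd.DataFrame, path, config_hash=None, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(config_hash, seed))
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} in column "
                f"{col!r}, data row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path}: missing value in column {col!r}, data row {row}")
        out[col] = coerced
    return out


# ---------------------------------------------------------------- band series

def write_band_series_csv(series_list, path, config_hash=None, seed=None) -> None:
    frames = []
    for s in series_list:
        df = s.data.copy()
        for col, val in zip(META_COLUMNS, (s.subject_id, s.ad_id, s.category)):
            df.insert(0, col, val) if col not in df.columns else None
        df = df[META_COLUMNS + TABLE_COLUMNS]
        frames.append(df)
    _write_csv(pd.concat(frames, ignore_index=True), path, config_hash, seed)


def read_band_series_csv(path) -> list[BandFeatureSeries]:
    df = _read_csv(path)
    _require_columns(df, META_COLUMNS + TABLE_COLUMNS, path)
    df = _require_numeric(df, TABLE_COLUMNS, path)
    out = []
    for (subject, ad, cat), grp in df.groupby(META_COLUMNS, sort=False):
        out.append(
            BandFeatureSeries(subject, ad, cat, grp[TABLE_COLUMNS].reset_index(drop=True))
        )
    return out


# ------------------------------------------------------------------- raw dump

def write_raw_csv(recordings, path, config_hash=None, seed=None) -> None:
    frames = []
    for r in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": r.subject_id,
                    "ad_id": r.ad_id,
                    "category": r.category,
                    "sample_rate": r.sample_rate,
                    "voltage": r.voltage,
                    "quality": r.quality,
                }
            )
        )
    _write_csv(pd.concat(frames, ignore_index=True), path, config_hash, seed)


def read_raw_csv(path) -> list[RawRecording]:
    df = _read_csv(path)
    _require_columns(df, RAW_COLUMNS, path)
    df = _require_numeric(df, ["sample_rate", "voltage", "quality"], path)
    out = []
    for (subject, ad, cat), grp in df.groupby(META_COLUMNS, sort=False):
        out.append(
            RawRecording(
                subject,
                ad,
                cat,
                float(grp["sample_rate"].iloc[0]),
                grp["voltage"].to_numpy(),
                grp["quality"].to_numpy(),
            )
        )
    return out


# --------------------------------------------------------------------- labels

def write_label_csv(table: LabelTable, path, config_hash=None, seed=None) -> None:
    _write_csv(pd.concat([table.meta, table.answers], axis=1), path, config_hash, seed)


def read_label_csv(path) -> LabelTable:
    df = _read_csv(path)
    _require_columns(df, META_COLUMNS + ANSWER_COLUMNS, path)
    df = _require_numeric(df, ANSWER_COLUMNS, path)
    for col in RANKED_COLUMNS:
        vals = df[col]
        bad = ~vals.isin(range(1, 8))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: ranked column {col!r} value {vals.iloc[row]!r} outside 1..7, "
                f"data row {row}"
            )
    for col in BINARY_COLUMNS:
        vals = df[col]
        bad = ~vals.isin((0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: binary column {col!r} value {vals.iloc[row]!r} not in {{0, 1}}, "
                f"data row {row}"
            )
    return LabelTable(df[ANSWER_COLUMNS].astype(int), df[META_COLUMNS])


# ------------------------------------------------------------- feature matrix

def write_feature_csv(X: FeatureMatrix, path, config_hash=None, seed=None) -> None:
    _write_csv(X.to_frame(), path, config_hash, seed)


def read_feature_csv(path) -> FeatureMatrix:
    df = _read_csv(path)
    _require_columns(df, META_COLUMNS, path)
    meta_cols = META_COLUMNS + (["provenance"] if "provenance" in df.columns else [])
    feat_cols = [c for c in df.columns if c not in meta_cols]
    df = _require_numeric(df, feat_cols, path)
    return FeatureMatrix(df[feat_cols], df[meta_cols])


def write_folds_csv(folds: FoldAssignment, path, config_hash=None, seed=None) -> None:
    _write_csv(folds.to_frame(), path, config_hash, seed)


# ----------------------------------------------------------------- JSON blobs

def write_model_json(model: LinearModel, path, config_hash=None, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = model.to_dict()
    payload["config_hash"] = config_hash
    payload["seed"] = seed
    path.write_text(json.dumps(payload, indent=2))


def read_model_json(path) -> LinearModel:
    payload = json.loads(Path(path).read_text())
    return LinearModel.from_dict(payload)


def write_report_json(report_dict: dict, path, config_hash=None, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(report_dict)
    payload["config_hash"] = config_hash
    if seed is not None:
        payload.setdefault("seed", seed)
    path.write_text(json.dumps(payload, indent=2, default=float))


# --------------------------------------------------------------------- config

@dataclass
class RunConfig:
    """Everything one pipeline run needs, resolvable from a YAML file."""

    seed: int
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    bands_preset: str = "device"
    window_seconds: float = 1.0
    features: list[str] | None = None
    flatten: str = "mean"
    scheme: BinarizationScheme = field(default_factory=BinarizationScheme)
    bootstrap: BootstrapSpec = field(default_factory=BootstrapSpec)
    C: float = 1.0
    mode: str = "in_sample"  # in_sample | loso | grid | curve
    quality_cut: int = 50
    max_bad_fraction: float = 0.1
    out_dir: str = "neuroad_out"

    def __post_init__(self) -> None:
        from .bands import BAND_PRESETS

        if self.bands_preset not in BAND_PRESETS:
            raise ValueError(
                f"unknown bands preset {self.bands_preset!r}; available: "
                f"{sorted(BAND_PRESETS)}"
            )
        if self.mode not in ("in_sample", "loso", "grid", "curve"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in raw:
        raise ValueError(f"{path}: config must state a seed")
    seed = int(raw.pop("seed"))
    syn = raw.pop("synthetic", {})
    if "categories" in syn:
        syn["categories"] = tuple((str(c), int(k)) for c, k in syn["categories"])
    if "trial_duration_range" in syn:
        syn["trial_duration_range"] = tuple(syn["trial_duration_range"])
    syn.setdefault("seed", seed)
    scheme = raw.pop("scheme", {})
    boot = raw.pop("bootstrap", {})
    if "r_range" in boot:
        boot["r_range"] = tuple(boot["r_range"])
    boot.setdefault("seed", seed)
    return RunConfig(
        seed=seed,
        synthetic=SyntheticConfig(**syn),
        scheme=BinarizationScheme(**scheme),
        bootstrap=BootstrapSpec(**boot),
        **raw,
    )


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
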
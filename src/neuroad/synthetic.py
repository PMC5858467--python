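"""Synthetic cohort generator.

The generator emulates the study design the pipeline assumes: ~30 subjects
each watching ~15 short (15-20 s) advertisements from four product
categories, single-electrode EEG at 512 Hz per trial, and a 22-item
questionnaire per trial.  EEG and questionnaire are statistically coupled
through a latent per-trial emotion scalar ``e ~ N(0, 1)``:

* **Voltage** is a sum of eight band-centered sinusoids with random phases
  plus white noise.  In the emotion-linked bands (Theta and both Beta
  bands, per the EEG-emotion literature) the amplitude is
  ``baseline * max(0, 1 + effect_size * e)``; other bands are fixed.
  ``effect_size = 0`` therefore decouples the EEG from the answers
  entirely.
* **Ranked answers** are a monotone noisy map of ``e`` onto {1..7}:
  ``clip(round(3.5 + balance_shift + 1.5 e + sigma z), 1, 7)`` with
  ``sigma = 2 * label_noise``.  The intercept 3.5 centers the default
  midpoint binarization at ``e = 0`` so the aggregate target is roughly
  class-balanced out of the box.
* **Binary answers** are thresholded noisy indicators of ``e`` with
  per-item offsets spread symmetrically around zero, flipped with
  probability ``label_noise``.

The answer map's gain is fixed: ``effect_size`` controls only how strongly
the EEG reflects ``e``, so the decoupled limit still produces balanced,
varying labels (a classifier can then only reach chance — the property the
recovery tests rely on).

Voltage abnormality (the reason trials get rejected in acquisition) is
emulated as hard amplitude clipping over a contiguous segment, with the
quality byte driven to 200 there so the preprocessing rejection filter
catches exactly the planted trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import labeling
from .labeling import ANSWER_COLUMNS, BinarizationScheme, LabelTable
from .preprocessing import RawRecording

#: Baseline sinusoid amplitude per band, microvolts.
BAND_BASELINES = {
    "Delta": 20.0,
    "Theta": 10.0,
    "LowAlpha": 8.0,
    "HighAlpha": 8.0,
    "LowBeta": 6.0,
    "HighBeta": 5.0,
    "LowGamma": 3.0,
    "HighGamma": 2.0,
}

#: Tone frequency per band (Hz); integers so a 1 s window at 512 Hz puts
#: each tone in a single FFT bin inside its device band.
BAND_TONES = {
    "Delta": 2.0,
    "Theta": 5.0,
    "LowAlpha": 8.0,
    "HighAlpha": 11.0,
    "LowBeta": 13.0,
    "HighBeta": 16.0,
    "LowGamma": 50.0,
    "HighGamma": 100.0,
}

#: Bands whose amplitude scales with the latent emotion.
EMOTION_BANDS = ("Theta", "LowBeta", "HighBeta")

ANSWER_GAIN = 1.5        # fixed latent-to-answer gain
RANKED_INTERCEPT = 3.5   # centers midpoint binarization at e = 0
BINARY_OFFSETS = np.linspace(-0.6, 0.6, 11)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort generation parameters; defaults are the study conditions."""

    n_subjects: int = 30
    trials_per_subject: int = 15
    total_trials: int | None = 454  # dealt evenly; None -> n_subjects * trials_per_subject
    categories: tuple[tuple[str, int], ...] = (
        ("car", 55),
        ("clothing", 55),
        ("digital", 55),
        ("food", 55),
    )
    sample_rate: float = 512.0
    trial_duration_range: tuple[float, float] = (15.0, 20.0)
    effect_size: float = 1.0
    label_noise: float = 0.1
    rejection_rate: float = 4 / 454
    balance_shift: float = 0.0
    noise_sd: float = 2.0       # white-noise amplitude, microvolts
    clip_ceiling: float = 60.0  # abnormal-trial clipping level, microvolts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must lie in [0, 1]")
        if not 0 <= self.rejection_rate < 1:
            raise ValueError("rejection_rate must lie in [0, 1)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = self.trial_duration_range
        if not 0 < lo <= hi:
            raise ValueError("trial_duration_range must satisfy 0 < min <= max")

    @property
    def n_trials(self) -> int:
        return self.total_trials if self.total_trials is not None else (
            self.n_subjects * self.trials_per_subject
        )


@dataclass(frozen=True)
class LatentEmotion:
    """The hidden per-trial emotion scalar bridging EEG and answers."""

    trial_id: str
    e: float


def _sample_answers(e: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the 22 questionnaire answers given latent emotions ``e``."""
    n = len(e)
    sigma = 2.0 * config.label_noise
    shifted = e + config.balance_shift / ANSWER_GAIN  # shift acts on the latent scale
    ranked_lat = (
        RANKED_INTERCEPT
        + ANSWER_GAIN * shifted[:, None]
        + sigma * rng.standard_normal((n, 11))
    )
    ranked = np.clip(np.floor(ranked_lat + 0.5), 1, 7).astype(int)
    binary_lat = shifted[:, None] + sigma * rng.standard_normal((n, 11))
    binary = (binary_lat > BINARY_OFFSETS[None, :]).astype(int)
    flips = rng.random((n, 11)) < config.label_noise
    binary = np.where(flips, 1 - binary, binary)
    return pd.DataFrame(
        np.hstack([ranked, binary]), columns=ANSWER_COLUMNS
    )


def _trial_plan(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign subjects, categories and distinct ads to each trial."""
    n = config.n_trials
    base, extra = divmod(n, config.n_subjects)
    counts = [base + (1 if i < extra else 0) for i in range(config.n_subjects)]
    cat_names = [c for c, _ in config.categories]
    cat_sizes = dict(config.categories)
    rows = []
    for s_idx, count in enumerate(counts):
        subject = f"S{s_idx + 1:02d}"
        per_cat: dict[str, int] = {c: 0 for c in cat_names}
        cats = [cat_names[t % len(cat_names)] for t in range(count)]
        for cat in cats:
            per_cat[cat] += 1
        picks = {
            cat: rng.choice(cat_sizes[cat], size=k, replace=False)
            for cat, k in per_cat.items()
            if k
        }
        used = {c: 0 for c in cat_names}
        for cat in cats:
            ad = f"{cat}_{picks[cat][used[cat]] + 1:02d}"
            used[cat] += 1
            rows.append({"subject_id": subject, "ad_id": ad, "category": cat})
    return pd.DataFrame(rows)


def _synth_voltage(
    e: float,
    n_samples: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(n_samples) / config.sample_rate
    volts = config.noise_sd * rng.standard_normal(n_samples)
    gain = max(0.0, 1.0 + config.effect_size * e)
    for band, base in BAND_BASELINES.items():
        amp = base * gain if band in EMOTION_BANDS else base
        phase = rng.uniform(0, 2 * math.pi)
        volts += amp * np.sin(2 * math.pi * BAND_TONES[band] * t + phase)
    return volts


def generate_cohort(
    config: SyntheticConfig,
    keep_abnormal: bool = False,
) -> tuple[list[RawRecording], LabelTable, list[LatentEmotion]]:
    """Generate one cohort: recordings, questionnaire table, latent emotions.

    A ``round(rejection_rate * n_trials)`` subset of trials is planted as
    voltage-abnormal.  By default those trials are excluded from all three
    outputs (they would not survive acquisition); with
    ``keep_abnormal=True`` the full cohort is returned so the rejection
    filter can be exercised on it.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_plan, rng_e, rng_sig, rng_lab, rng_rej = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    plan = _trial_plan(config, rng_plan)
    n = len(plan)
    e = rng_e.standard_normal(n)
    answers = _sample_answers(e, config, rng_lab)

    n_reject = int(round(config.rejection_rate * n))
    abnormal = np.zeros(n, dtype=bool)
    if n_reject:
        abnormal[rng_rej.choice(n, size=n_reject, replace=False)] = True
    if n_reject >= n:
        raise ValueError(f"rejection_rate={config.rejection_rate} leaves zero surviving trials")

    lo, hi = config.trial_duration_range
    durations = rng_sig.uniform(lo, hi, size=n)
    recordings: list[RawRecording] = []
    emotions: list[LatentEmotion] = []
    keep_mask = np.ones(n, dtype=bool)
    for i, row in plan.iterrows():
        n_samples = int(durations[i] * config.sample_rate)
        volts = _synth_voltage(e[i], n_samples, config, rng_sig)
        quality = rng_sig.integers(0, 16, size=n_samples)
        if abnormal[i]:
            start = int(0.3 * n_samples)
            stop = start + int(0.4 * n_samples)
            volts[start:stop] = np.clip(volts[start:stop] * 6.0,
                                        -config.clip_ceiling, config.clip_ceiling)
            quality[start:stop] = 200
            if not keep_abnormal:
                keep_mask[i] = False
                continue
        rec = RawRecording(
            row["subject_id"], row["ad_id"], row["category"],
            config.sample_rate, volts, quality,
        )
        recordings.append(rec)
        emotions.append(LatentEmotion(rec.trial_id, float(e[i])))
    if keep_abnormal:
        keep_mask[:] = True
        # emotions were only collected for kept rows above; rebuild for all
        emotions = [
            LatentEmotion(f"{r['subject_id']}|{r['ad_id']}", float(e[i]))
            for i, r in plan.iterrows()
        ]
    if not recordings:
        raise ValueError(f"rejection_rate={config.rejection_rate} leaves zero surviving trials")
    labels = LabelTable(
        answers.loc[keep_mask].reset_index(drop=True),
        plan.loc[keep_mask, ["subject_id", "ad_id", "category"]].reset_index(drop=True),
    )
    return recordings, labels, emotions


def generate_sinusoid_recording(
    freq: float,
    amplitude: float,
    duration: float,
    sample_rate: float,
    subject_id: str = "FIX",
    ad_id: str = "sinusoid",
    category: str = "car",
) -> RawRecording:
    """Pure-sinusoid fixture with perfect signal quality.

    Raises for frequencies at or above Nyquist (unrepresentable).
    """
    if not 0 < freq < sample_rate / 2:
        raise ValueError(
            f"frequency {freq} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    volts = amplitude * np.sin(2 * math.pi * freq * t)
    return RawRecording(subject_id, ad_id, category, sample_rate, volts, np.zeros(n, dtype=int))


def _best_monotone_accuracy(e: np.ndarray, y: np.ndarray) -> float:
    """Accuracy of the best threshold classifier on a scalar score."""
    order = np.argsort(e, kind="stable")
    ys = np.asarray(y)[order]
    n = len(ys)
    cum1 = np.concatenate([[0], np.cumsum(ys)])
    total1 = cum1[-1]
    k = np.arange(n + 1)
    # predict 1 at/above the cut
    acc_up = ((k - cum1) + (total1 - cum1)) / n
    # predict 1 below the cut
    acc_dn = (cum1 + (n - k) - (total1 - cum1)) / n
    return float(max(acc_up.max(), acc_dn.max()))


def planted_bayes_accuracy(
    config: SyntheticConfig,
    n_mc: int = 100_000,
    scheme: BinarizationScheme | None = None,
    seed: int | None = None,
) -> float:
    """Monte-Carlo ceiling: best accuracy predicting the target from ``e``.

    Because every answer is a monotone noisy function of the latent
    emotion, the Bayes-optimal classifier given ``e`` is a threshold on
    ``e``; we estimate its accuracy by plug-in maximization over cuts of a
    large simulated sample.  Downstream classifiers see only the (noisier)
    EEG features, so this is an upper bound on achievable accuracy.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    scheme = scheme or BinarizationScheme()
    if seed is None:
        ss = np.random.SeedSequence([config.seed, 0xBA])
    else:
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    e = rng.standard_normal(n_mc)
    answers = _sample_answers(e, config, rng)
    scores = labeling._aggregate_scores(answers, scheme)
    y = (scores >= scheme.dataset_threshold).astype(int)
    return _best_monotone_accuracy(e, y)


def with_positive_rate(
    config: SyntheticConfig,
    desired: float,
    scheme: BinarizationScheme | None = None,
    n_mc: int = 20_000,
    tol: float = 0.01,
) -> SyntheticConfig:
    """Calibrate ``balance_shift`` so the target's positive rate ~ desired.

    The positive rate is monotone non-decreasing in the shift, so a
    bisection on a fixed Monte-Carlo sample converges; the returned config
    differs from the input only in ``balance_shift``.
    """
    if not 0 < desired < 1:
        raise ValueError("desired positive rate must lie in (0, 1)")
    scheme = scheme or BinarizationScheme()
    rng_master = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA]))
    e = rng_master.standard_normal(n_mc)
    answer_seed = int(rng_master.integers(2**31))

    def rate(shift: float) -> float:
        cfg = replace(config, balance_shift=shift)
        answers = _sample_answers(e, cfg, np.random.default_rng(answer_seed))
        scores = labeling._aggregate_scores(answers, scheme)
        return float((scores >= scheme.dataset_threshold).mean())

    lo, hi = -6.0, 6.0
    for _ in range(60):
        mid = (lo + hi) / 2
        r = rate(mid)
        if abs(r - desired) <= tol:
            return replace(config, balance_shift=mid)
        if r < desired:
            lo = mid
        else:
            hi = mid
    return replace(config, balance_shift=(lo + hi) / 2)
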
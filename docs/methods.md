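# Methods

This note records the model behind `neuroad`, the defaults and why they
were chosen, the interpretations made where the procedure was genuinely
open, and what the synthetic cohort does and does not establish.

## Signal model and feature extraction

A trial is a single-channel voltage series at 512 Hz lasting 15–20 s,
with a per-sample quality byte (0 = clean; higher = worse contact).
Trials whose fraction of samples with quality above `quality_cut`
(default 50) exceeds `max_bad_fraction` (default 0.1) are rejected as
voltage-abnormal. The defaults are ours: acquisition practice only says
abnormal trials are discarded, not how the cut is drawn.

Windowing is 1 s, non-overlapping (512 samples), one output record per
window — this makes the per-trial record count equal the ad length in
seconds, consistent with the published per-category trimmed lengths
(24/13/28/16 records). The windowing itself is a choice; nothing in the
source procedure states it.

Band power uses the one-sided periodogram normalized so all bins sum to
the window's energy (discrete Parseval identity); band `[lo, hi)` sums
the bins with `lo <= f < hi`. Two band presets ship:

- `device` (default): Delta 0.5–4, Theta 4–8, LowAlpha 7.5–9,
  HighAlpha 9.5–12.5, LowBeta 12–15, HighBeta 15–18, LowGamma 30–80,
  HighGamma 80–Nyquist. These are the consumer-chipset edges; note the
  deliberate overlaps (HighAlpha/LowBeta) and gaps (Theta/LowAlpha) —
  they are the device's, not ours. The Delta edge is the evident
  correction of a misprinted "> 4 Hz" to "< 4 Hz".
- `classic`: the traditional clinical list (1–3, 4–7, 8–9, 10–12,
  13–17, 18–30, 31–40, 41–50). The printed clinical list in the source
  material is garbled; we ship the evident reading verbatim rather than
  silently regularize it, and let the config choose the preset.

Attention/Meditation: the chipset's eSense formulas are proprietary and
unpublished. We compute bounded proxies — Attention =
100·β/(β+α+θ), Meditation = 100·α/(α+β) with α/β/θ the summed
alpha/beta/theta powers — monotone in the Beta-vs-(Alpha+Theta) and
Alpha-vs-Beta balances and naturally in [0, 100]. Any bounded monotone
proxy serves the pipeline; zero-signal windows get 0.

Flattening to one row per trial defaults to the per-feature mean over
windows: a single model is trained across categories whose trimmed
lengths differ, which requires a fixed-width representation, and the
mean is the minimal such reduction. `concat` mode (feature × timestamp)
exists for per-category experiments and refuses to pool categories.

## Label model

Ranked answers binarize as `value >= threshold`; at the midpoint
threshold 4 this keeps the midpoint positive (half-integer thresholds
are tie-free). The per-trial target is the mean of binarized answers in
the chosen group (ranked / binary / combined with weights α + β = 1 /
a single item) compared against a dataset-level threshold — the only
reading under which dataset thresholds of 0.4/0.5/0.6 behave as
proportions. Both published binary-threshold sets ({0, 0.5, 1} and
{0.4, 0.5, 0.6}) are accepted; neither is privileged. The grid-scan API
names its axes (`ranked_threshold`, `binary_threshold`,
`dataset_threshold`) explicitly because the published grid tables are
ambiguous about which symbol labels which axis.

## Augmentation

- *Ten-folds*: per-fold class counts use round-half-up, `(c+5)//10`
  (ordinary rounding, not banker's). The dealing is by array slices, so
  the folds are a disjoint exhaustive partition even in degenerate
  small-class cases where nine folds exhaust a class early (later folds
  shorten; fold 10 may hold no leftovers of a class). With very small
  in-sample pools (n ≲ 35) round-half-up can allocate everything to
  folds 1–9 and leave fold 10 empty, in which case an evaluation run
  fails loudly rather than test on nothing.
- *Gaussian bootstrap*: the perturbation distribution is a standard
  normal truncated to the open interval (−1, 1), drawn by rejection
  sampling; `scale = 0.5·(col_min + col_max)` multiplies it. A
  zero-mean symmetric perturbation is the only reading that leaves the
  column's spread unaffected, which is the stated intent. Columns with
  `min + max = 0` pass through unchanged (logged). Note the bound
  `|x' − x| < |scale|` is what the construction forces; for all-positive
  features (band powers) scale is positive.
- *Combinatorial expansion*: `nCr` enumeration is read as: for each
  r-subset of feature columns, emit a copy of the training matrix with
  those columns replaced by their bootstrapped versions — the only
  self-consistent reading of the listing. Full enumeration over 11
  columns would be 2¹¹−1 = 2047 copies, so per-size enumeration is
  capped (`max_copies_per_r`, default 20; random distinct subsets under
  the spec seed when the cap binds) and the total is capped at
  `expansion_cap` rows (default 50·n), truncating at whole copies so
  label duplication stays row-aligned. Copies carry `provenance` tags
  (`boot:r=...:cols=...`).
- Augmentation runs *inside* the fold loop (per training fold), never
  on data any test row will come from; `assert_no_leakage` verifies
  from the provenance tags, on every augmented run, that each augmented
  row traces to a training-fold trial and that train/test are disjoint.

All randomness descends from one seed via `SeedSequence` spawning, so
every stage is reproducible in isolation and byte-identical across
runs.

## Classifier

Linear SVM, squared-hinge loss, L2 penalty, C = 1.0 by default, solved
by liblinear in primal mode (samples outnumber features here; the
primal/dual switch has no numerical consequence at tolerance 1e-6).
liblinear also L2-regularizes the intercept through its
augmented-feature trick; the test-suite oracle (an independent BFGS
minimization of the same convex objective) accounts for that. Features
are standardized per column with statistics learned on the training
rows only — band powers span orders of magnitude and an unscaled linear
margin is degenerate; standardization is recorded in the model and can
be disabled. Ties at decision value 0 go to the positive class,
matching the `>=` convention used throughout.

## Evaluation

One subject is always held out untouched; the rest is ten-folded, folds
1–9 augmented and trained on, fold 10 is the in-sample test set.
Leave-one-subject-out repeats this per subject, evaluating on the
held-out subject's trials, and macro-averages the per-subject metrics
(micro-averaging by flag). F is F1 on the positive class. Learning
curves reuse the stratified fold construction (first `n_folds` folds
rotate as test sets), subsample the training pool class-proportionally,
apply no augmentation, and count pre-augmentation rows on the x-axis;
bands are mean ± std across folds. Grid cells with single-class targets
are reported NA.

## Synthetic cohort

The generator's defaults are the study conditions: 30 subjects, 454
recorded trials dealt as evenly as possible (26×15 + 4×16), four
product categories of 55 ads each, 512 Hz, 15–20 s trials, and a
deterministic `round(rejection_rate·n) = 4` planted-abnormal trials, so
450 survive the quality filter exactly.

Latent structure: per trial `e ~ N(0, 1)`. Voltage is a sum of eight
band-centered sinusoids (integer tone frequencies, so a 1 s window
resolves each into a single FFT bin) with random phases plus white
noise (2 µV); amplitudes in the emotion-linked bands (Theta, LowBeta,
HighBeta — the bands the EEG-emotion literature implicates) scale as
`baseline · max(0, 1 + effect_size·e)`. Ranked answers are
`clip(round(3.5 + 1.5·e + σz), 1, 7)` with `σ = 2·label_noise`; binary
answers are noisy indicators `1{e + σz > c_i}` with symmetric per-item
offsets, flipped with probability `label_noise`. The intercept 3.5
centers the default midpoint binarization at `e = 0`, so the default
target is near class-balanced; `with_positive_rate` calibrates the
`balance_shift` for any other desired rate by bisection.

A deliberate design choice: `effect_size` couples `e` to the *EEG
only*; the answer map's gain is fixed. Tying the answer gain to
`effect_size` would collapse the answers to a constant at
`effect_size = 0`, destroying the chance-level null; with the fixed
gain, `effect_size = 0` yields balanced, varying labels that the EEG
simply cannot predict — the exact decoupled limit the recovery tests
need. Abnormal trials get a contiguous 40% segment amplified and
clipped at `clip_ceiling` (60 µV) with quality driven to 200, so the
quality filter catches exactly the planted trials.

`planted_bayes_accuracy` estimates the recovery ceiling by Monte
Carlo: every answer is a monotone noisy function of `e`, so the
Bayes-optimal classifier given `e` is a threshold on `e`; plug-in
maximization over cuts of a 10⁵-trial sample estimates its accuracy
(reproducible to ±0.01 across Monte-Carlo seeds). Classifiers see only
the noisier EEG features, so this bounds what recovery can achieve; at
`label_noise = 0` the ceiling is 1, and a binary-only scheme at
`label_noise = 0.5` is pure noise with ceiling 0.5.

What the generator does **not** emulate: 1/f background spectra,
eye-blink/EMG artifacts, non-stationarity, between-subject variability
(no subject random effects — LOSO and pooled CV behave alike here), or
any psychometric structure among the 22 items beyond their common
dependence on `e`. Passing recovery tests therefore show the pipeline
is correct and information-efficient *under this coupling*; they say
nothing about effect sizes in real viewers, and the published human
accuracies are context, not targets — that data was never deposited.

## Problem sizes and numerical choices

Evaluation runs in the tests and the acceptance script use the light
expansion setting `r_range = (1,)` (11 single-column copies per
training fold; ~4,700 augmented rows from a ~390-row fold), which keeps
the 600+ model fits of a 20-seed permutation null at desk scale while
exercising the full augmentation path; the count identities and caps
are tested separately across (k, r, cap) grids. Solver tolerance is
1e-6 with 50,000 iteration cap. Band edges at bin boundaries follow the
half-open `[lo, hi)` rule; degenerate inputs (zero-length folds,
single-class targets, zero-scale columns, sub-window recordings) fail
loudly with named trials/columns rather than silently proceeding.

## Known limitations

- The combined-threshold formula blends thresholds on different scales
  (1–7 vs 0–1); it is reported as defined, but the aggregate target
  uses the per-type thresholds directly, which is the only consistent
  operationalization.
- Ranked thresholds 3.5 and 4 binarize integer answers identically
  under the `>=` convention; only 4.5 differs. Observed grid
  differences between 3.5 and 4 in published tables cannot be
  reproduced by any tie convention alone.
- With fewer than ~35 in-sample trials the ten-fold listing can leave
  fold 10 empty (see above); use more trials or evaluate per category
  with a pooled scheme.
- The eSense proxies are not the proprietary formulas; on real device
  exports the recorded Attention/Meditation columns pass through
  untouched and the proxies are never invoked.
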
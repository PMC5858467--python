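# neuroad

Predicting advertisement impact — "would this viewer buy the product?" —
from single-electrode EEG recorded while the viewer watches short video
ads.

Consumer EEG headsets emit a 13-column per-second record (raw voltage,
a signal-quality byte, proprietary Attention/Meditation scores, and
eight FFT band powers from Delta through High Gamma). After each ad the
viewer fills in a 22-item questionnaire: eleven 7-point ranked answers
(content quality, excitement, willingness to buy, ...) and eleven yes/no
answers (celebrity present, story-telling, ...). `neuroad` implements
the full analysis pipeline from these two tables to a purchase-intent
classifier, plus a synthetic cohort generator that emulates the study
design (no public dataset of this kind exists).

## The method

Per trial, EEG voltage v(t) sampled at 512 Hz is cut into 1 s windows;
band power for band [f_lo, f_hi) is the sum of one-sided periodogram
bins in that interval (the per-window powers satisfy Parseval's
identity, Σ_k P_k = Σ_t v_t²). Trials are trimmed to their category's
minimum length and reduced to an 11-feature row (8 band powers + Raw +
Attention + Meditation).

The 22 answers collapse to one binary target: each ranked answer y is
binarized as 1{y ≥ Thre₇} (Thre₇ ∈ {3.5, 4, 4.5}; 4 = (7+1)/2 is the
scale midpoint), each binary answer as 1{y ≥ Thre₂}, groups may be
blended with weights α + β = 1 (combined threshold
Thre = α·Thre₇ + β·Thre₂), and the trial is labeled positive when the
mean of binarized answers reaches a dataset-level threshold.

Because ~450 trials is sparse for training, three resampling algorithms
expand each training fold:

1. **stratified ten-folds** — class indices are shuffled and dealt so
   folds 1–9 hold round(n₁/10) positives and round(n₀/10) negatives
   each; fold 10 takes the leftovers;
2. **scaled Gaussian bootstrap** — each entry x becomes x + scale·g
   with scale = 0.5·(col_min + col_max) and g a standard normal
   truncated to (−1, 1), so |x′ − x| < scale always;
3. **combinatorial expansion** — for each subset S of feature columns,
   a copy of the training matrix with columns S replaced by their
   bootstrapped versions is appended; labels are duplicated to match.

A linear SVM with squared-hinge loss and L2 penalty,

  min_w,b 0.5‖w‖² + C Σ_i max(0, 1 − y_i(⟨w, x_i⟩ − b))²,  y_i ∈ {±1},

is trained on the augmented folds. Evaluation holds one subject out
entirely (leave-one-subject-out, averaged over all subjects), reports
accuracy / recall / F1 per category and pooled, scans the threshold
grid, and draws cross-validation learning curves (mean ± std bands) to
check for over-fitting. Augmented rows never reach a test set; every
run proves this from provenance tags.

The synthetic generator couples EEG and answers through a latent
per-trial emotion e ~ N(0,1): emotion-linked band amplitudes scale as
1 + effect_size·e, and the answers are monotone noisy maps of e. A
Monte-Carlo `planted_bayes_accuracy` oracle gives the best achievable
accuracy, so classifier recovery can be measured against a ceiling, and
`effect_size = 0` gives an exact chance-level null.

## Worked example

```python
import neuroad as na

config = na.SyntheticConfig(seed=1)                    # the study conditions
recordings, labels, _ = na.generate_cohort(config, keep_abnormal=True)
dataset = na.build_dataset(recordings, labels)         # reject -> FFT -> trim -> flatten
print(f"{len(recordings)} recorded trials, {len(dataset)} survive quality rejection")

scheme = na.BinarizationScheme()                       # ranked answers, threshold 4
spec = na.BootstrapSpec(seed=1, r_range=(1,))          # single-column replacement copies
report = na.in_sample_run(dataset, scheme, spec, seed=1)
print(f"in-sample  accuracy={report.accuracy:.3f} recall={report.recall:.3f} "
      f"F={report.f_score:.3f} (train={report.n_train}, test={report.n_test})")

loso = na.leave_one_subject_out(dataset, scheme, spec, seed=1)
print(f"out-of-sample (LOSO over {loso.n_subjects} subjects) "
      f"accuracy={loso.accuracy:.3f} +/- {loso.accuracy_std:.3f}")

bayes = na.planted_bayes_accuracy(config, n_mc=100_000)
print(f"planted Bayes ceiling: {bayes:.3f}")
```

prints

```
454 recorded trials, 450 survive quality rejection
in-sample  accuracy=1.000 recall=1.000 F=1.000 (train=396, test=39)
out-of-sample (LOSO over 30 subjects) accuracy=0.991 +/- 0.023
planted Bayes ceiling: 0.984
```

Reading: 454 trials are generated, 4 planted voltage-abnormal trials
are rejected; on the default cohort (coupling strength 1.0, label noise
0.1) the latent emotion almost fully determines the target, so the
classifier sits at the Monte-Carlo Bayes ceiling — in-sample and
out-of-sample alike. Lower `effect_size` or raise `label_noise` to make
the problem hard; at `effect_size=0` accuracy drops to chance (0.5).

A CLI mirrors the library (`neuroad simulate / extract / label /
augment / train / evaluate / grid / curve / run-all`), driven by a YAML
config with a mandatory seed; every artifact embeds the config hash.

```sh
neuroad run-all --config demo.yaml
```

## Layout

- `neuroad.synthetic` — cohort generator, latent-emotion model, Bayes oracle
- `neuroad.preprocessing` — quality rejection, FFT band powers, trimming, flattening
- `neuroad.labeling` — questionnaire schema, thresholds, target aggregation
- `neuroad.augmentation` — stratified ten-folds, Gaussian bootstrap, combinatorial expansion
- `neuroad.modeling` — linear squared-hinge SVM
- `neuroad.evaluation` — in-sample / LOSO runs, threshold grids, learning curves
- `neuroad.io`, `neuroad.cli` — CSV/JSON formats, YAML run configs, CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
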
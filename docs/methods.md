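# Methods

`eegindex` builds per-subject, model-based indices of three
cognitive/affective states — happiness, surprise, and attention — from
14-channel scalp EEG sampled at 128 Hz, and applies them to novel
recordings (TV-commercial viewing) as quarter-second time series. This
note documents the model, the numerical choices, the synthetic study
conditions, and the limits of what the synthetic tests demonstrate.

## Signal model and features

Recordings are band-pass filtered with a zero-phase (forward–backward)
4th-order Butterworth filter. The conventional EEG analysis band is
0.5–100 Hz; at a 128 Hz sampling rate the upper edge is not realizable
(Nyquist 64 Hz), so the implementation clamps it to `0.45 * rate`
(57.6 Hz) and warns. Channels are then re-referenced to the common
average (the instantaneous channel mean is subtracted), and the signal is
cut into contiguous, non-overlapping 0.25 s windows; a trailing partial
window is dropped.

Each 32-sample window is Hann-tapered and zero-padded to 256 points,
giving a periodogram on a 0.5 Hz grid. Power is averaged within six
bands — delta [0.5, 4), theta [4, 8), alpha [8, 12), low beta [12, 20),
high beta [20, 30), gamma [30, 50] — with half-open membership so shared
edges are never double-counted (12 Hz belongs to low beta; 50 Hz closes
gamma). With 14 channels this yields 84 features per window. Features
default to `log10(power + 1e-12)`: band powers are approximately
log-normal, and the log stabilizes variance for the ANOVA and the
Gaussian posterior model downstream. Raw power is available via
`log_transform=False`. Delta is poorly resolved by a 0.25 s window
(native resolution 4 Hz); no correction is applied, and delta features
should be read as broadband low-frequency leakage rather than true delta
power.

## Feature selection

For each subject and state, windows from the neutral calibration session
(label 0) and the target-state session (label 1) are pooled. A one-way
ANOVA F statistic is computed per feature (for two groups, F = t²); the
top-F feature seeds a greedy forward search. Each step adds the candidate
that maximizes stratified tenfold cross-validated accuracy of the Fisher
discriminant on the augmented subset. Fold assignment is fixed once per
search (seeded), so candidate accuracies are exact rationals over a
common denominator and are compared exactly; ties break toward the higher
F value, then the lower column index.

The search stops when the best achievable accuracy no longer *strictly*
improves on the current one. A plateau-tolerant variant
(`plateau="explore"`), which continues through equal-accuracy additions
and truncates them unless a later strict improvement occurs, is provided
for comparison; it was not made the default because on noisy data it
retains more chance-level additions and roughly doubles the chosen-set
size relative to the range the method is known to produce (means near
7–8 features). Even under the strict rule, post-selection CV accuracy is
optimistically biased on null data (≈ 0.6 rather than 0.5): each step
takes a maximum over ~83 near-chance candidates. This selection optimism
is intrinsic to wrapper selection scored on the same folds; the package
reports the final CV accuracy as the search saw it, without a nested
outer loop.

## Classifier and posterior index

The two-class Fisher discriminant maximizes
`J(w) = (w' S_B w) / (w' S_W w)` with `S_B` the between-class scatter of
the class means about the grand mean and `S_W` the within-class scatter.
The closed form `w ∝ (S_W + λI)⁻¹(μ₁ − μ₀)` is used, with a small ridge
`λ = 1e-6 · trace(S_W)/d` by default so the solve stays well-posed when
the chosen dimension approaches the window count; `w` is unit-normalized
with the sign making the target class project higher.

Posterior probabilities use one-dimensional Gaussian class-conditionals
on `z = w'x`, with per-class projected means and variances estimated on
the training data and *equal priors* — calibration sessions have
design-determined lengths that should not bias the index. This is the
minimal generative completion of the Fisher criterion; a pooled-variance
variant is available. Degenerate cases: a single zero projected variance
falls back to the pooled variance; if both are zero the posterior
hard-thresholds at the projected midpoint. A posterior of exactly 0.5
(and hence a tie) classifies as the target state, a fixed convention.

The index is `2p − 1`, the unique affine map from [0, 1] posteriors onto
[−1, 1]. Clip comparison averages the index over windows within subject,
then over subjects (mean ± SD); rank 1 is the largest group mean, ties
broken by clip label order. Elapsed-time analysis averages the series
pointwise across subjects (truncating to the shortest grid) and reports
maximal runs of consecutive windows above a threshold (default 0.5) as
peaks; adjacent supra-threshold windows merge, and an isolated window is
a valid 0.25 s peak. No temporal smoothing is applied before peak
detection (an off-by-default option exists), so reported peaks have
quarter-second granularity.

## Behavioral module

Preference/short-term-memory/recall ranks over `n` clips convert to
points `n + 1 − rank` (first of four → 4 points); purchase intention is a
1–7 Likert rating taken as-is. Group comparison is a one-way ANOVA
omnibus across clips followed by all pairwise *paired* t-tests (the
design is within-subject) with Holm adjustment, flagged at α = 0.05 and
0.01. The post-hoc procedure is a package choice — conservative and
assumption-light — and is named in the output; a rank-based alternative
(Friedman + Wilcoxon signed-rank) is available via `method="friedman"`.
Pairs with identical data return p = 1 rather than an undefined t.

## Synthetic study conditions

No EEG is bundled; the generator defines the study conditions:

- Background: Gaussian `1/f^α` noise, α = 1.0, per channel, 20 µV RMS,
  realized by spectral shaping of white noise. The shaped series is
  normalized by its *expected* standard deviation (not the realized one),
  so band powers are not contaminated by the high-variance low-frequency
  realization.
- Planted effects: additive band-limited oscillations (4th-order
  Butterworth-filtered noise confined to the named band, normalized to
  unit in-band power) whose amplitude is calibrated against the realized
  background band power so the expected power at the planted
  (channel, band) cell equals `multiplier ×` the neutral level.
  Multiplier 2.5 throughout — large enough for calibration accuracies in
  the mid-80s (comparable to what the method reports on real data),
  small enough that single windows remain ambiguous.
- Planted topography per state follows the sites the method associates
  with each index: happiness FC5 high-beta + T8 gamma; surprise AF3
  gamma + T7 high-beta + O2 gamma; attention AF3 high-beta.
- Commercial sessions modulate the planted amplitude by a
  piecewise-linear state-intensity trajectory in [0, 1] (power
  interpolates linearly between neutral and the full multiplier); the
  per-window mean intensity is returned as ground truth.
- Study sizes: 40 s calibration sessions (160 windows per class), 20 s
  clips, 6 subjects, 4 clips, one clip planted. These sizes keep a full
  multi-seed study tractable on one core while leaving ≥ 16 windows per
  CV fold.
- No inter-channel correlation, no artifacts (blinks, EMG), no
  nonstationary baselines, no volume conduction.

All randomness derives from one integer seed through
`SeedSequence(seed, spawn_key=...)` with CRC-32-hashed string keys, so
identical (config, seed) pairs regenerate bit-identical sessions and
byte-identical output tables.

Because the generator plants stationary, perfectly band-confined,
channel-independent effects, passing recovery tests shows that the
pipeline finds the right cells, ranks a planted clip first, and tracks a
scripted trajectory — it does not show robustness to artifacts, volume
conduction, inter-subject topographic variability, or non-stationarity,
all of which real EEG has.

## Numerical notes

- Accuracy comparisons in the greedy search are exact (no tolerance);
  all other floating comparisons in tests use explicit tolerances.
- TSV/CSV output uses a fixed `%.10g` float format, making reruns
  byte-identical.
- EDF recordings are readable (via `mne` when installed); no EDF writer
  backend is declared, so recordings are written as CSV.
- The CSV reader validates timestamp regularity to 1 ppm and infers the
  rate from timestamps.

## Known limitations

- Post-selection CV accuracy is reported un-nested and is optimistic
  (see above); on null data expect ≈ 0.55–0.65, not 0.50.
- The greedy search under pure noise typically retains 4–8 features
  before stopping; wrapper selection on 84 candidates cannot terminate
  much faster when scored at 1/n accuracy granularity.
- The Gaussian posterior is a modeling choice; scores are monotone in
  `w'x` either way, so rankings are insensitive to it, but absolute
  index magnitudes are not calibrated probabilities.
- With 0.25 s windows, delta- and theta-band features are heavily
  influenced by spectral leakage from the taper and zero-padding.
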
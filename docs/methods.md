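# Methods

## Problem and scope

The subcutaneous ICD (S-ICD) senses cardiac rhythm through one of three
extra-cardiac vectors (primary, alternate, secondary).  A vector whose
T-wave amplitude exceeds one third of its R-wave amplitude risks T-wave
oversensing — the device double-counts beats and may deliver inappropriate
shocks — so the T:R amplitude ratio against the 1:3 cut-off is the central
screening quantity.  Conventional screening is a snapshot of a few seconds;
this package implements a long-duration alternative: estimate T:R for every
10-s segment of a 24-h, 500 Hz, 3-channel Holter recording (channels A/B/C
as surrogates of the three vectors), characterise its dynamics, and compare
patient groups.  T:R, not R:T, is the regression target throughout: as the
T amplitude approaches zero, T:R goes smoothly to zero whereas R:T
diverges, which would make a regression label unusable.

Patient recordings from the original study are not available; a synthetic
Holter generator with known per-segment ground truth stands in for them.
All group-level reproduction therefore happens at two levels: exact
arithmetic on the published per-patient count table (packaged as
`data/table3_counts.csv`), and property-based recovery on synthetic
cohorts.

## Synthetic Holter generator

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) with fixed latencies
and widths; the R bump's coefficient is the per-channel R amplitude
(defaults 1.0/0.8/1.2 mV for A/B/C) and the T bump's coefficient is driven
by a per-segment T:R process, so ground-truth amplitudes are template
coefficients, not measurements.  Per-beat RR intervals are truncated
normal (default 70 ± 3 bpm); the three channels share beat timing and
differ by amplitude scale, mirroring three simultaneous surrogate leads.
Additive disturbances: baseline wander (default 0.1 mV below 0.5 Hz),
50 Hz mains (0.02 mV), white noise (0.01 mV SD).

The slow T:R fluctuation emulates diuresis-timescale drift: a sinusoid of
period `drift_period_s` (default 6 h) plus an AR(1) component
(lag-1 correlation 0.95 at the 10-s segment scale).  The sinusoid carries
8% of the fluctuation variance and the AR term the rest; the realized
fluctuation is standardised per recording and rescaled so the segment-level
sample mean and SD equal (`tr_mean`, `tr_sd`) by construction — a
sinusoid-dominated process would make the realized SD depend on the drift
phase whenever the recording is shorter than one period.  Clipping at zero
is the only remaining distortion (≤ 0.005 on either moment for the presets
below).  Output is a pure function of the parameter set including its seed.

Group presets calibrate the process to the published group summaries:

| preset   | tr_mean | tr_sd | emulates                                |
|----------|---------|-------|-----------------------------------------|
| `hf`     | 0.18    | 0.09  | heart failure under IV diuresis          |
| `normal` | 0.10    | 0.07  | structurally normal hearts               |

For cohort simulations, per-patient mean T:R is additionally jittered with
a between-patient SD back-derived from the published group 95% CIs
(0.084/1.96 ≈ 0.043 for HF, 0.054/1.96 ≈ 0.028 for normal), separating
within-recording fluctuation (`tr_sd`) from between-patient spread.

What the generator does **not** emulate: arrhythmia, ectopy, bundle-branch
morphologies, posture changes, electrode artefacts and lead-off transients,
heteroscedastic noise.  Passing recovery tests on this data shows the
pipeline is self-consistent and recovers known amplitude ratios through
realistic stationary noise; it does not certify performance on pathological
real-world morphologies.

## Preprocessing

Per channel, in order: zero-phase 2nd-order Butterworth high-pass at 0.5 Hz
(baseline drift; forward-backward so T-wave morphology is not
phase-shifted), zero-phase IIR notch at the mains frequency (Q ≈ 30,
default 50 Hz), zero-phase 4th-order Butterworth low-pass at 40 Hz.  Filter
orders and cutoffs are this package's declared defaults, configurable via
`RunConfig`; edge handling is even-reflection padding.  A frequency-tracking
("adaptive") notch is deliberately out of scope.  Measured on realized
filters: ≥ 20 dB attenuation below 0.5 Hz with 10 Hz preserved within 5%;
≥ 30 dB at 50 Hz with 10 Hz within 2%; ≥ 20 dB at 120 Hz with 5 Hz within
2%.  On noise-free synthetic beats the whole chain changes per-segment
oracle T:R by less than 0.01.

Segmentation is anchored at t = 0, half-open non-overlapping 10-s windows,
trailing partial window discarded: 24 h → 8640 segments per channel.

## Delay-map images

Each segment is embedded as the 2-D point set {(x_t, x_{t+τ})} with
τ = 20 ms (10 samples at 500 Hz) by default, min-max rescaled per segment,
and binned into a 32×32 histogram normalised to unit mass
(count fractions).  Convention: bin index `floor(u·grid)` with u = 1
clamped into the last bin; rows hold the delayed coordinate, so time
reversal exactly transposes the image.  Min-max scaling makes images
invariant to overall amplitude, which is what makes a ratio learnable from
them; τ, the scaling and the intensity definition are declared defaults
(no published values exist).  Degenerate constant segments put all mass on
the centre pixel by convention.

## T:R estimators

**Explicit-wave oracle.**  R peaks: adaptive-threshold peak finding on the
absolute 5–25 Hz band-passed segment (threshold 0.4 × the 99.5th
percentile, 250 ms refractory period), refined to the raw-signal extremum
within ±40 ms.  Per beat, baseline is the median of the isoelectric PR
stretch 120–70 ms before the R peak; R amplitude is the baseline-corrected
peak excursion; T amplitude is the largest baseline-corrected excursion
150–450 ms after R, truncated at 60% of the running RR interval to avoid
the next QRS.  The segment value is the median over beats; segments with
fewer than three usable beats (or flat segments) return NaN rather than
raising.  On noise-free synthetic beats spanning true T:R 0.05–0.5 the
maximum absolute error is below 0.01.

**CNN regressor.**  A small convolutional network maps a 32×32 delay-map
image to scalar T:R without locating any waves: two valid-mode 3×3 conv
blocks (8 and 16 channels, ReLU, 2×2 max-pool), a 32-unit dense head and a
linear output, trained with Adam (lr 1e-3, batch 64, default 20 epochs) on
MSE.  The network is implemented directly on numpy (im2col convolutions,
exact max-pool gradients with ties split evenly); backpropagation is
verified against finite differences in the test suite.  Inputs are scaled
by the global pixel SD and the regression target is standardised during
training (predictions are mapped back); both constants are stored with the
weights.  Predictions are clipped below at zero; no upper clip.
Training labels come from generator ground truth when available, else from
the oracle; train/validation splits are by recording, never by segment, to
avoid temporal leakage.  Determinism: fixed config seed ⇒ identical
weights and predictions.

Desk-scale recovery (six 40-min mixed-preset recordings, ≈ 2900 training
images, stratified two-recording holdout, 15 epochs, a few minutes on one
CPU core): held-out MAE ≈ 0.005–0.01 and Pearson r ≈ 0.98–0.997, and mean
predictions increase monotonically across true T:R levels 0.05–0.45.

## Longitudinal characterisation

Per vector and 10-s segment series: mean and sample SD (n−1); count and
proportion of segments strictly above the threshold (default 1/3, the
manufacturer-derived cut-off); a trailing ("preceding half hour") rolling
mean with one point per segment, points before one full window flagged as
warm-up; an occupancy histogram (bin width 0.05 on [0, 1], half-open bins,
values ≥ 1 clamped into the last bin) of the fraction of the recording
spent in each T:R range.  Report formatting mirrors the published table:
count 0 → "0%", positive but below 1% → "<1%", otherwise rounded percent;
raw proportions are always carried alongside the formatted string.

Vector selection: eligibility over a long recording has no published
definition (conventional screening is a pass/fail snapshot), so the package
defines it as spending at most `eligibility_max_prop` (default 1%) of the
recording above the threshold — a documented extension, not a
reconstruction.  Among eligible vectors the recommendation minimises
(proportion above threshold, SD of T:R, lead order A < B < C)
lexicographically; with no eligible vector the report recommends none and
ranks all three by the same key.

## Group statistics

Welch two-sample t (Satterthwaite df, two-sided p) and Mann–Whitney U
(midranks; U = min(U₁, U₂)).  The Mann–Whitney p is exact by enumeration
over all label assignments — p = P(min(U₁,U₂) ≤ observed) under the
permutation null, which coincides with the classical two-tailed doubling
without double counting — when the pooled sample is tie-free with n ≤ 12;
otherwise the normal approximation with midrank tie correction and
continuity correction is used.  Both tests are two-sided (sidedness is not
stated in the source material).

The published count table's "±" is interpreted as the normal-approximation
95% CI half-width 1.96·s/√n: with that convention the packaged per-patient
counts reproduce every printed group mean and ± value after integer
rounding (377 ± 731 and 1146 ± 862 in the primary vector, etc.), which is
the evidence for the interpretation.  "<1%" display cells are reconstructed
from the printed counts, never parsed.  Mean percentages are computed on
exact proportions (count/8640) and formatted last, avoiding compounded
display rounding.  The published between-group p-values for unfavourable
time (.26/.29/.22) are not reproduction targets: the test that produced
them is unstated, and they sit uneasily beside the accompanying claim of
significance; the package computes its own two-sided tests instead.

## Problem sizes and numerical choices

Reproduction experiments default to desk scale: 40-min recordings for CNN
training (≈ 2900 images), 2-h recordings for the 21-patient cohort
contrast (720 segments per patient), chosen so the full suite runs in
minutes while every segment-level statistic keeps its 24-h structure (the
generator calibrates per recording, so shorter recordings realise the same
segment-level moments).  Histogram bin edges use a 1e-9 epsilon so values
sitting on an edge up to float error land in the upper (half-open) bin.
Flat or too-short segments yield NaN estimates and are excluded with a
logged count, never silently imputed.  All randomness flows from explicit
integer seeds; derived seeds stay below 2³¹.

## Known limitations

Synthetic morphology is idealised (no arrhythmia or artefacts); the
eligibility flag over 24 h is a package convention; the notch filter does
not track mains drift; the CNN is sized for CPU training on synthetic data
and its published-study counterpart's weights and accuracy are not
reproduction targets; real-data group means (0.181/0.104) serve only as
generator calibration targets, not as recomputable quantities.
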
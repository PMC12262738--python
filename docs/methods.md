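# Methods

## Signal model

All detectors operate on one sequence per patient: the count of segmented
aorta pixels on each axial CTA slice, index 0 at the most superior
analyzed slice, increasing toward the iliac bifurcation. The count is a
surrogate for luminal cross-sectional area; no slice-thickness or pixel
calibration is applied, so all volumes are unit-less pixel sums. Aneurysm
boundaries are inclusive slice intervals `[start, end]`.

## Rule-based detectors

Both rules compare each slice's count with a rolling mean of the counts
before it, so they are invariant to global scaling of the profile (the
thresholds are ratios).

**Failure screen** (normal/aneurysm classification). Slices are anomalous
when the count falls below `lower` (default 0.5) or exceeds `upper`
(default 1.4) times the rolling mean of the last `window` (default 4)
*normal* slices. Anomalous slices are excluded from the baseline buffer:
the baseline is meant to represent normal-caliber segmentation, and a
dropout stretch would otherwise drag it to zero within one window,
truncating the flagged extent after `window` slices. A scan is labeled
aneurysm when at least `persistence` (default 4) consecutive anomalous
slices occur; the first slice of the first qualifying run and the last
slice of the last qualifying run delimit the flagged extent. The first
`window` slices seed the baseline and are never flagged, which assumes
the analyzed range begins in normal aorta.

**Boundary detector.** Here the baseline is the mean of the `window`
slices immediately preceding each slice and is *never frozen*: it rolls
through the aneurysm, so the end rule measures the drop relative to
recent aneurysm-scale counts (a drop to 80 % of the *pre-aneurysm* level
would rarely occur for a dilation returning to normal caliber). A
candidate start is the first slice of a run of `window` consecutive
slices each above `upper`×baseline (default 1.2); a candidate end is the
last slice of a run of `window` consecutive slices each below
`lower`×baseline (default 0.8). Candidate regions pair a start with any
later end; the region of greatest slice extent is returned, ties toward
the earliest. No qualifying pair ⇒ no aneurysm.

A consequence of the never-frozen baseline worth knowing: a perfectly
abrupt step in the profile produces at most `window − 1` consecutive
threshold crossings (the rolling mean catches up within one window), so
idealized step profiles are *not* detected at the default thresholds.
The rule targets physiological profiles, where the caliber change is
spread over several slices; the detector's own tests cross-check every
output against an independent step-through simulation.

**Grid search** evaluates every (window, upper, lower) combination
exhaustively against mean interval Dice over the annotated cohort
(missed detections score 0); ties break toward the smaller window, then
the upper threshold closest to 1, then the lower closest to 1. The
default grid is windows 2–8, uppers 1.05–1.50 and lowers 0.50–0.95 in
steps of 0.05. When the pipeline runs grid search it does so on the full
provided cohort and marks the report `grid_in_sample`, making the
optimism explicit.

## LSTM slice labeler

Inputs are per-profile max-normalized counts, zero-padded (or truncated,
with a warning) to 200 timesteps; targets are per-slice indicators of the
annotated interval. The network is `recurrent_layers` (default 2) stacked
bidirectional LSTM layers with `hidden_units` (default 600) per
direction, followed by a fully connected ReLU stack (default widths 256,
64) applied *per timestep* to the concatenated forward/backward state,
ending in one sigmoid unit per timestep — i.e., 200 output probabilities.
The per-timestep head was chosen over a flatten-then-dense head because
it keeps the output length tied to the sequence and shares parameters
across positions; the decision threshold defaults to 0.5 and is
configurable since no canonical value exists.

Training uses Adam (learning rate 3·10⁻⁴, batch size 10) on

```
L = BCE(y, p) + w_J · (1 − Σ p·y / (Σ p + Σ y − Σ p·y))
```

with `w_J = 1` by default; the soft-Jaccard term directly rewards
interval overlap, which BCE alone under-weights for short intervals.
Early stopping monitors validation loss (patience 100 epochs, maximum
1000) and the best-validation parameters are restored. The engine is
pure NumPy with hand-derived backpropagation through time, verified
against finite differences in the test suite; float64 arithmetic and a
single seeded RNG (weight init, batch order, fold assignment) make runs
bit-reproducible.

Decoding takes the longest run of supra-threshold probabilities (ties →
earliest), mirroring the largest-abnormality-region principle of the
rule detector; padding positions are excluded.

**Cross-validation** partitions patients once (seeded) into k disjoint
test folds (default 5, i.e., 80/20 train/test); within each training
portion, 10 % of patients (at least one) are held out for early
stopping. A leakage guard asserts the folds partition the patient set,
and `train_detector` refuses overlapping train/validation cohorts. The
pooled report averages fold metrics and sums prediction counts.

## Evaluation metrics

* **Interval Dice** 2TP/(2TP+FP+FN) on slice-index sets; both-absent
  pairs score 1, one-absent pairs 0.
* **R²** is the printed formula 1 − RSS/TSS (not a fitted regression's
  R²), undefined for constant truth.
* **Surrogate volume** Σ counts over the inclusive boundary interval;
  **enlargement** sums the positive excess over a linear interpolation
  between the boundary-slice counts (dips clip to zero; a single-slice
  interval yields 0 by convention).
* **BCE** is implemented as the standard negative mean log-likelihood —
  a non-negative loss — with probabilities clipped at 10⁻⁷.
* Cohort reports average Dice over *all* annotated patients (missed
  detections contribute 0 and are counted in `n_missed`), while boundary
  R²/MAE/MSE and volume R² are computed over patients where prediction
  and truth both mark an aneurysm; metrics that are not computable are
  null, never silently 0.
* Classification metrics are reported as percentages at one decimal,
  null on zero denominators.

## Synthetic data

A profile is `baseline · (1 − taper·i/n) · (1 + A·rc(i))` with `rc` a
raised cosine of half-support `bump_halfwidth` centered at
`bump_center`, multiplied by `(1 + σ·Z)` Gaussian noise and rounded to
non-negative integers. Defaults: 200 slices, baseline 300 px, noise
σ = 3 % (multiplicative, since area noise scales with area), taper 10 %,
amplitude 1.0, half-width 25. The raised cosine was preferred over a
Gaussian because the set of slices whose noiseless multiplier exceeds the
annotation threshold (1.2, matching the start rule so synthetic truth and
the expert rule are commensurable) has a closed form used directly by the
tests. Dropout variants replace counts inside the annotated interval by
uniform draws in [0, 0.05·baseline], emulating segmentation failure.

`generate_cohort` randomizes the geometry per patient: half-width 7–11
slices, amplitude 1.2–1.8× baseline, uniformly placed centers. These
ranges describe abrupt-onset aneurysms whose cross-sectional area
roughly doubles to triples over one to two centimetres. The choice is
deliberate: a relative-threshold rule keyed to a 4-slice rolling mean is
sensitive to the *rate* of caliber change, and feasibility analysis of
the raised-cosine geometry shows bumps wider than ~12 slices at
amplitude ≤ 1.5 never move 20 % against their own 4-slice trailing mean.
The cohort generator therefore emulates the regime in which such a rule
is the appropriate detector; gradual, slowly tapering dilations are a
known limitation of the rule (not of the generator) and are the use case
for the learned labeler or for grid-searched, tighter thresholds.

What the synthetic conditions do **not** show: real SAM2 profiles carry
autocorrelated noise, partial-volume effects at branch vessels, tortuosity
artifacts, and annotation uncertainty; passing these tests demonstrates
algorithmic correctness under the stated signal model, not clinical
performance.

## Problem sizes and numerical choices

The test suite and the acceptance script use a compact labeler
configuration (2 bidirectional layers, 32 hidden units per direction,
one 64-unit dense layer, ≤ 60 epochs) on 200-patient synthetic cohorts;
at these sizes training converges in about a minute on one CPU and
reaches held-out mean interval Dice ≈ 0.97, comfortably demonstrating
parameter recovery without the full 600-unit architecture. Contrast
stretching rounds half away from zero and maps constant images to the
low output bound; rendered mask disks rank pixels by center distance
with lexicographic tie-breaks so counts are exact and round-trips are
identities. All randomness flows through `numpy.random.default_rng`
seeds recorded in configs and reports.

## Known limitations

* The boundary rule requires the analyzed range to start in normal aorta
  (the first window seeds the baseline) and assumes one dominant
  aneurysm; multiple lesions are reduced to the widest candidate region.
* The end boundary systematically lags the annotated end by ~2 slices on
  smooth bumps (the drop run ends where the falling flank flattens).
* Surrogate volumes are unit-less; no mm³ calibration is attempted.
* The LSTM sees at most 200 slices; longer profiles are truncated
  distally.
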
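# Methods

## Problem setting

Drowsiness — the intermediate state between wakefulness and sleep — impairs
reaction performance and expresses itself in eye-closure dynamics: blinks
become slower and longer, and episodes of prolonged closure (microsleeps)
appear. `vigileye` implements a *multi-timescale* characterization of
drowsiness from a 1-minute bilateral eyelid-distance time series sampled at
30 Hz. Four binary classifiers operate at timescales of 5, 15, 30 and 60
seconds: short timescales respond quickly but noisily, long timescales are
accurate but sluggish. Emitting all four levels at once sidesteps the
accuracy-responsiveness trade-off a single fixed window imposes.

## Ground truth from psychomotor vigilance tasks

The supervisory signal comes from reaction times (RTs) recorded during
10-minute psychomotor vigilance tasks (PVTs): visual stimuli at uniform
random 2–10 s intervals, each answered as fast as possible.

**Inter-subject normalization.** Within a subject, reaction *speed* (the
reciprocal RT, in 1/ms) is approximately normally distributed. Individual
skill differences are removed by shifting each subject's speed distribution
to the population mean:

    x' = 1 / (1/x − μ_k + μ̄),

where `μ_k` is the mean reciprocal RT of subject `k`'s alert reference
session and `μ̄` the grand mean of the `μ_k`. A consequence used as an
exact test: the mean reciprocal of a subject's *normalized* reference RTs
equals `μ̄` to machine precision. RTs whose shifted speed is nonpositive
are undefined; they are dropped and logged.

**Median RTs.** At an evaluation time `t`, four "median RTs" summarize
responsiveness at the four timescales. `m1` is a single RT — the event
closest to `t` within [t−1 s, t+1 s] (ties resolved to the earlier event),
or the linear interpolation *in RT value* between the surrounding events.
`m2`–`m4` are harmonic means (the median of a reciprocal-normal
distribution) of the RTs in the windows [t−15, t+5], [t−30, t+5] and
[t−60, t+5] seconds. The windows may be non-causal: they define training
targets, not an operational quantity. A window without events leaves the
median undefined; no edge correction is applied at session boundaries.

**Labels.** Each median RT maps to a ternary probability of drowsiness:
0 (alert) if `m ≤ 400` ms, 1 (drowsy) if `m ≥ 500` ms (the conventional
lapse threshold), 0.5 in between. Samples at 0.5 are kept for training (a
soft target) and discarded per-timescale at evaluation.

**Strata and validation weights.** Training samples fall into five strata
by how many of their four median RTs are at or above 470 ms; each training
epoch draws an equal quota per stratum (with replacement), which balances
the rarer drowsy windows. Validation loss terms are instead re-weighted by
`w = (1/f)/2`, where `f` is the occurrence frequency of the sample's
(timescale, side-of-470 ms) cell in the validation pool. On the published
alert-side frequencies (87.29 / 92.97 / 94.79 / 95.75 %) this reproduces
the weights 0.5728 / 0.5378 / 0.5275 / 0.5222 to four significant figures;
the drowsy-side weights recompute only to ~3 figures from the rounded
printed frequencies, so the tests assert the alert side.

## The temporal CNN

Input: an 1800×2 matrix (60 s × 30 Hz, left/right eyelid distance in
pixels), centered by the training-set mean distance. Architecture, at the
default width `W = 32` and head width 16:

* trunk: two temporal convolutions (depth `W`, field 15, stride 1, zero
  padding 7, ReLU then batch-norm), each densely connected (input
  concatenated to output → depths 34 and 66), separated by a max-pool
  (field 3, stride 3) that brings 1800 samples to 600 positions at an
  effective 10 Hz;
* four branches, one per timescale: a convolution (depth `W`, field 31,
  padding 15, ReLU then batch-norm, no skip), a global pooling, a dense
  16-unit head with ReLU;
* *temporal sigmoid-weighted pooling* for the 5/15/30 s branches: weights
  `w_n ∝ σ(slope · (n − 600 + 10·n0 − 0.5))` normalized to sum to one,
  monotone in position, concentrating the mass on the most recent `n0`
  seconds while decaying smoothly. The 60 s branch uses a plain global
  average. The half-sample offset is a cutoff tie-break: it places the
  transition *between* positions, so the infinite-slope limit is exactly
  the mean of the last `10·n0` positions (verified numerically at slope
  10³). At the default slope this offset is negligible.
* *multi-timescale context*: the four head embeddings are concatenated,
  passed through a shared 16-unit dense layer with ReLU, and concatenated
  back into every branch before its final 2-way softmax. The ablation
  switch removes this pathway and doubles the head width so the branch
  capacity stays comparable.

The slope of the pooling sigmoid is exposed as a configuration parameter
(default 1.5 per position). The weighting must fall off sharply *yet
smoothly* around the cutoff; very large slopes degenerate to a hard
window, very small ones to a global average, and the default was fixed
once as a mid-range value, not tuned.

**Loss.** The average of four binary relative entropies between the
predicted drowsy probability `p̂_i` and the ternary target `p_i`, with the
convention `0·ln(0/0) = 0` and `p̂` clamped to `[1e-7, 1−1e-7]`. This
equals cross-entropy minus the target entropy, so it is nonnegative and
zero exactly at `p̂ = p`. Validation adds the per-cell class weights above.

**Training.** Adam (β₁ = 0.9, β₂ = 0.999), learning rate 0.0016029, batch
size 32; dropout 0.35 after the second trunk concatenation, 0.7 after each
global pooling, 0.35 before each final dense layer; left/right channels
swapped with probability 0.5 at load time. Epochs are stratified (equal
per-stratum quotas); early stopping selects the parameters with minimal
weighted validation loss (patience and epoch cap are configuration).
Batch-norm statistics are frozen and dropout disabled at inference; binary
decisions threshold the drowsy probability at 0.5.

The network is implemented directly in numpy (im2col convolutions as
single large GEMMs, explicit backward passes); all backward passes are
verified against central-difference numeric gradients in double precision.

## Blink features and the linear baseline

The baseline represents the wider family of feature-based systems.
Per eye, a running maximum eyelid distance is tracked by adaptive
exponential smoothing, `M_t = max(d_t, (1−β)M_{t−1} + β d_t)` with
β = 0.002 per sample and `M_0` the 95th percentile of the first five
seconds; normalized openness is `r = d/M` (clipped to [0, 1.5]). The two
eyes' normalized series are averaged (eyelids blink together; averaging
suppresses uncorrelated noise).

Blinks are segmented by thresholding one-sided first derivatives of `r`:
a sample is *closing* when its backward difference is below
`−vel_threshold`, *re-opening* when its forward difference is above
`+vel_threshold`, and *closed* when `r < closed_threshold` and locally
flat on at least one side (or a sharp falling-to-rising turning point, the
one-sample-plateau case). One-sided differences are used deliberately:
central differences smear phase boundaries by a sample, and the boundary
sample of a plateau would inherit the ramp's slope. Closed runs separated
by sub-threshold noise gaps of at most two samples are merged, and a
single slow sample does not terminate a ramp. Defaults:
`closed_threshold = 0.3` openness (consistent with PERCLOS-70: at least
70 % closed ⇔ openness < 0.3) and `vel_threshold = 1.5 s⁻¹`. The velocity
threshold must sit below the slope of the *slowest* re-opening it should
still catch — a drowsy re-opening stretched to ~400 ms rises at only
≈ 2.5 s⁻¹ — while staying above the noise floor of the derivative; both
thresholds are configurable.

Six features are computed over each of the four most-recent windows
(5/15/30/60 s, blinks attributed by closing onset; empty windows yield
zeros): mean blink / closing / closed / re-opening durations, microsleep
count (blinks longer than 500 ms), and PERCLOS-70 as the per-sample
fraction of the window with openness below 0.3. The resulting
24-dimensional vectors feed four linear max-margin classifiers (one per
timescale; scikit-learn's liblinear-style `LinearSVC`), with features
min-max scaled to [0, 1] on the training set (no clamping at test time),
class weights equal to reciprocal training counts, and the regularization
strength C selected from a 13-point log grid over 10⁻³…10³ by inner
leave-one-subject-out balanced accuracy.

## Evaluation protocol

Subject-generic, leave-one-subject-out: with `n` subjects there are `n`
folds built by rotation — one test subject, `round(5n/29)` (at least 1)
validation subjects, the rest training — so every subject appears exactly
once as test and equally often in the other roles (the 23/5/1 design at
n = 29). Validation and test samples are stimulus-anchored: one 1-minute
sequence per PVT stimulus from 60 s onward (a stimulus at exactly 60 s is
included — its sequence exists in full). Per timescale, indeterminate
samples (target 0.5) are discarded; confusion counts are pooled across
folds *before* computing TNR, TPR and accuracy, so subjects contribute in
proportion to their data. The four binary decisions sum to a combined
level of drowsiness 0–4; the fraction of monotone joint patterns
(0000/1000/1100/1110/1111) is reported as a diagnostic of the learned
timescale hierarchy, not enforced.

## The synthetic cohort

The simulator exists so every stage is testable without human data. A
latent drowsiness process `D(t) ∈ [0, 1]` couples the two streams:

* *Sessions*: each subject performs one alert session (`D ≡ 0`, the
  normalization reference, mirroring a first-morning PVT) and two
  sleep-deprived sessions, 600 s at 30 Hz. Deprived sessions start at
  `D = 0.8` and follow a per-minute random walk (std 0.25, clipped to
  [0, 1]) — piecewise-constant blocks keep window labels nearly pure,
  which is what makes small-cohort learnability tests clean, while block
  transitions populate the intermediate strata.
* *Blinks*: trapezoidal — linear closing ramp, closed plateau at 2 % of
  the baseline aperture, linear re-opening — at 15 blinks/min with base
  phase durations (100, 50, 150) ms, ±20 % multiplicative jitter per
  phase, all durations scaled by `1 + (gain−1)·D` with gain 2.5, and a
  per-blink microsleep probability `0.25·D` that stretches the plateau to
  0.55–1.5 s. Left and right channels share the blink template and differ
  by independent Gaussian noise (σ = 2 % of baseline), exercising the
  two-channel input and the swap augmentation. Every rendered blink is
  logged (onset, per-phase sample counts), giving segmentation tests an
  oracle.
* *RTs*: stimulus gaps uniform in [2, 10] s; reaction speed is normal,
  `N(μ_subject − 0.0022·D, 0.0004)` 1/ms with `μ_subject` drawn once per
  subject around 1/280 (between-subject σ = 0.0003), floored at 1/3000 for
  numerical safety. At `D = 0` this gives ~280 ± 35 ms alert RTs; at
  `D = 1`, a mean around 600 ms with most RTs beyond the 500 ms lapse
  threshold.

These parameter values are chosen to be physiologically plausible
magnitudes, not estimates of any real population; the blink statistics of
the original study population are not published. What the synthetic
cohort deliberately lacks: head pose and gaze effects, illumination,
tracking dropouts, asymmetric or partial blinks, time-on-task drifts, and
the heavy class imbalance of real alert-dominated recordings (deprived
sessions here spend roughly half their time drowsy). Passing the
synthetic experiments therefore demonstrates that the implementation
learns and evaluates what it claims to — not that real-data accuracy
would match.

## Scaled-down experiment sizes

The packaged experiments run on a single CPU, so the default synthetic
study uses problem sizes chosen once for that setting: 8 subjects × 3
sessions, a training grid every 2 s, network width 8 with 8-unit heads,
per-stratum epoch quota 64, at most 6 epochs with patience 2, validation
subsampled to 160 sequences per fold. The architecture defaults remain the
full printed widths (32-deep convolutions, 16-unit heads, trunk depths
34/66), and the shape tests assert exactly those. Training the full-width
network on the full 29-subject design is the same code with different
configuration.

## Numerical choices and degenerate inputs

* Median-RT tie at equal distance from `t`: the earlier event wins.
* `m1` interpolation operates on RT values (not reciprocals); the choice
  is isolated in `median_rt_m1` and switchable in principle — at the
  500 ms scale the two differ by far less than the labeling thresholds.
* Stratum threshold uses `≥ 470 ms` exactly; label thresholds use
  `≤ 400` / `≥ 500`.
* Pooling-weight normalization is exact (weights sum to 1 within 1e-9);
  the 60 s branch bypasses the sigmoid entirely (global average).
* Loss clamp ε = 1e-7; degenerate validation pools (an empty
  side-of-470 ms cell) raise rather than silently reweight.
* Min-max scaling maps constant features to 0; test-set features may
  leave [0, 1] (linear map, no clamping).
* Traces shorter than 5 s fall back to the whole-trace percentile for the
  running-maximum initialization; traces must be positive and finite.
* Seeds: every stage draws from `numpy.random.default_rng` descendants of
  one master seed; identical configuration reproduces reports bit-for-bit
  on the same platform.

## Known limitations

* The generator's trapezoid blinks are easier to segment than real
  eyelid traces; segmentation accuracy on real data would depend on the
  threshold calibration the original feature literature calls empirical.
* The printed rendering of the pooling formula is ambiguous about the
  sigmoid slope; it is exposed as configuration rather than guessed
  silently, and results at short timescales depend on it.
* Small synthetic cohorts make subject-level variance large; the
  acceptance experiments therefore test directional and threshold claims
  over five seeds rather than point estimates.
* The real study's headline accuracies are not reproducible here: they
  require the unreleased face videos and GPU-scale training of 29
  full-width models.
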
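# vigileye

Multi-timescale characterization of drowsiness from eyelid-distance time
series, supervised by psychomotor-vigilance-task (PVT) reaction times.

Drowsiness monitors based on eye-closure dynamics face a trade-off: a
classifier averaging blink behaviour over a short window reacts quickly to
lapses and microsleeps but is noisy, while a long window is accurate but
slow. `vigileye` implements a system that sidesteps the trade-off by
emitting **four binary levels of drowsiness (LoD) at once**, at timescales
of 5, 15, 30 and 60 seconds, from a single 1-minute bilateral
eyelid-distance sequence (1800 × 2 samples at 30 Hz).

The package is aimed at sleep/vigilance researchers and at anyone who
wants a fully tested, CPU-only reference implementation of:

* **PVT-based multi-timescale ground truth.** Reaction speeds (1/RT) are
  normalized per subject, `x' = 1/(1/x − μ_k + μ̄)`, where `μ_k` is the
  subject's mean reciprocal RT in an alert reference session. Four
  "median RTs" `m₁..m₄` summarize responsiveness at each time `t` (a
  single/interpolated RT in [t−1, t+1] s, and harmonic means over
  [t−15, t+5], [t−30, t+5], [t−60, t+5] s), and each maps to a ternary
  probability of drowsiness: `p = 0` if `m ≤ 400` ms, `1` if `m ≥ 500` ms
  (the conventional lapse threshold), `0.5` in between.
* **A four-branch temporal CNN** (pure numpy, gradient-checked): a
  densely-connected convolutional trunk (depths 34 and 66, max-pooled
  1800 → 600), four timescale branches with *temporal sigmoid-weighted
  pooling* — normalized attention weights
  `w_n ∝ σ(slope·(n − 600 + 10 n₀))` that concentrate on the most recent
  `n₀` seconds — and a shared *multi-timescale context* embedding fed back
  into every branch. Trained with the average of four binary relative
  entropies against the ternary targets, stratified epoch sampling (470 ms
  strata), left/right swap augmentation and class-weighted validation.
* **A blink-feature baseline**: blink segmentation (closing / closed /
  re-opening) by derivative thresholds on max-normalized eyelid distance,
  six ocular features (mean blink/closing/closed/re-opening durations,
  microsleep count, PERCLOS-70) over four windows → 24 features → one
  linear max-margin classifier per timescale with inner
  leave-one-subject-out selection of C.
* **Leave-one-subject-out evaluation** with rotated train/validation/test
  subject sets (the 23/5/1 design at 29 subjects, scaled for smaller
  cohorts), stimulus-anchored sampling, pooled confusion counts, and the
  combined LoD (0–4) with its 16-outcome histogram and monotone-pattern
  diagnostic.
* **A synthetic PVT simulator** — a latent drowsiness process drives both
  trapezoidal blink dynamics (longer blinks and microsleeps when drowsy)
  and reciprocal-normal reaction times (slower when drowsy) — so the whole
  pipeline is testable without human data.

See `docs/methods.md` for the model details, parameter choices and
limitations.

## Worked example

Ground truth on a synthetic cohort:

```python
from vigileye import SyntheticConfig, simulate_cohort, fit_normalization, label_probability
from vigileye.ground_truth import normalize_events, median_rts, assign_stratum

cohort = simulate_cohort(SyntheticConfig(n_subjects=8, seed=3))
model = fit_normalization([s for s in cohort if s.tag == "alert"])
session = next(s for s in cohort if s.subject_id == "s00" and s.pvt_id == "pvt1")
events = normalize_events(session, model)

med = median_rts(180.0, events)            # evaluation time t = 180 s
print([round(m, 1) for m in med.m])        # [372.2, 473.4, 529.0, 531.0]
print([label_probability(m) for m in med.m])  # [0.0, 0.5, 1.0, 1.0]
print(assign_stratum(med))                 # 3
```

At `t = 180 s` this deprived session is coming out of a drowsy episode:
the 30 s and 60 s median RTs are still above the 500 ms lapse threshold
(drowsy, `p = 1`), the 15 s median sits in the indeterminate 400–500 ms
band, and the most recent RT is already back to alert (`p = 0`) — exactly
the responsiveness/accuracy gradient the four timescales are designed to
expose. Three of the four medians are ≥ 470 ms, so a training sequence
ending here belongs to stratum 3.

The full experiment — simulate, label, train the CNN and the baseline
under rotated leave-one-subject-out folds, pool the test metrics — runs
from the command line:

```bash
vigileye run-all --out report.json --seed 1
vigileye evaluate --report report.json
```

Individual stages are also exposed (`vigileye simulate / label / features /
train / proxy`), all seeded and reproducible: the same configuration and
seed yield an identical report.

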
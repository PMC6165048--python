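"""Multi-timescale ground truth of drowsiness from PVT reaction times.

Drowsiness impairs responsiveness, so reaction times (RTs) recorded during
a psychomotor vigilance task index the state the eyelid-trace models must
learn.  The machinery here:

1. *Inter-subject normalization.*  Within a subject, reaction speed (the
   reciprocal RT) is approximately normal; a subject's alert-session mean
   reciprocal ``mu_k`` is shifted to the population mean ``mu_pop``:
   ``x' = 1 / (1/x - mu_k + mu_pop)``.
2. *Median RTs* ``m1..m4`` at a time ``t``: ``m1`` is a single (or linearly
   interpolated) RT from the [-1 s, +1 s] window; ``m2..m4`` are harmonic
   means (the median of a reciprocal-normal distribution) of the RTs in the
   [-15, +5], [-30, +5] and [-60, +5] second windows.
3. *Label probabilities* ``p1..p4``: 0 (alert) if ``m <= 400`` ms, 1
   (drowsy) if ``m >= 500`` ms, else 0.5; 500 ms is the conventional lapse
   threshold.
4. *Training strata*: the count (0-4) of median RTs at or above 470 ms.
5. *Validation class weights* ``w = 1 / (2 f)`` from the occurrence
   frequency ``f`` of each (timescale, side-of-470-ms) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import PVTSession, RTEvent

__all__ = [
    "UndefinedRTError",
    "NormalizationModel",
    "MedianRTs",
    "GroundTruth",
    "fit_normalization",
    "normalize_rt",
    "normalize_events",
    "median_rt_m1",
    "median_rt_window",
    "median_rts",
    "label_probability",
    "assign_stratum",
    "validation_weights",
    "compute_validation_frequencies",
    "label_session",
]

logger = logging.getLogger(__name__)

ALERT_THRESHOLD_MS = 400.0
DROWSY_THRESHOLD_MS = 500.0
STRATUM_THRESHOLD_MS = 470.0
#: lookback seconds of the four median-RT windows (m1 uses [-1, +1] instead)
WINDOW_LOOKBACKS_S = (15.0, 30.0, 60.0)
WINDOW_LEAD_S = 5.0


class UndefinedRTError(ValueError):
    """Normalization produced a nonpositive reaction speed."""


@dataclass(frozen=True)
class NormalizationModel:
    """Per-subject mean reciprocal alert RTs and their grand mean (1/ms)."""

    mu_by_subject: dict[str, float]
    mu_pop: float

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self.mu_by_subject


@dataclass(frozen=True)
class MedianRTs:
    """The four median RTs (ms) at evaluation time ``t``; None = undefined."""

    t: float
    m: tuple[float | None, float | None, float | None, float | None]


@dataclass(frozen=True)
class GroundTruth:
    """Four label probabilities, each in {0, 0.5, 1} (None = undefined m)."""

    p: tuple[float | None, float | None, float | None, float | None]


def fit_normalization(reference_sessions: list[PVTSession]) -> NormalizationModel:
    """Fit ``mu_k`` per subject from alert reference sessions.

    ``mu_k`` is the mean of the reciprocals of all RTs in the subject's
    reference (first-morning, alert) session; ``mu_pop`` is the arithmetic
    mean of the fitted ``mu_k``.  Subjects without a usable reference
    session are excluded with a warning, mirroring the exclusion of
    subjects with missing first-session data.
    """
    by_subject: dict[str, list[float]] = {}
    for session in reference_sessions:
        by_subject.setdefault(session.subject_id, []).extend(e.rt for e in session.rt_events)
    mu = {}
    for subject_id, rts in sorted(by_subject.items()):
        if not rts:
            logger.warning("subject %s has no reference RTs; excluded from normalization", subject_id)
            continue
        mu[subject_id] = float(np.mean([1.0 / x for x in rts]))
    if not mu:
        raise ValueError("no subject has a usable reference session")
    return NormalizationModel(mu_by_subject=mu, mu_pop=float(np.mean(list(mu.values()))))


def normalize_rt(x: float, subject_id: str, model: NormalizationModel) -> float:
    """Shift one RT's reciprocal by ``mu_pop - mu_k``: ``1/(1/x - mu_k + mu_pop)``."""
    if subject_id not in model:
        raise KeyError(f"subject {subject_id!r} not in normalization model")
    speed = 1.0 / x - model.mu_by_subject[subject_id] + model.mu_pop
    if speed <= 0:
        raise UndefinedRTError(f"normalized speed nonpositive for rt={x} of {subject_id}")
    return 1.0 / speed


def normalize_events(session: PVTSession, model: NormalizationModel) -> list[RTEvent]:
    """Normalize a session's RT log, dropping (and logging) undefined RTs."""
    out = []
    for e in session.rt_events:
        try:
            out.append(RTEvent(e.stimulus_time, normalize_rt(e.rt, session.subject_id, model)))
        except UndefinedRTError:
            logger.warning("dropping rt=%.1f ms at t=%.1f s of %s", e.rt, e.stimulus_time, session.key)
    return out


def median_rt_m1(
    t: float, events: list[RTEvent], interpolate_reciprocal: bool = False
) -> float | None:
    """Single-RT median at the 5 s timescale.

    If at least one event falls in [t-1, t+1], return the RT of the event
    closest to ``t`` (earlier wins ties); otherwise linearly interpolate
    between the last event before and the first after ``t``.  Interpolation
    operates on RT values by default; ``interpolate_reciprocal`` switches it
    to reaction-speed (1/RT) space — at the 400-500 ms label thresholds the
    two differ by far less than the band width.  Undefined outside the
    event support.
    """
    if not events:
        return None
    in_window = [e for e in events if t - 1.0 <= e.stimulus_time <= t + 1.0]
    if in_window:
        best = min(in_window, key=lambda e: (abs(e.stimulus_time - t), e.stimulus_time))
        return best.rt
    before = [e for e in events if e.stimulus_time < t]
    after = [e for e in events if e.stimulus_time > t]
    if not before or not after:
        return None
    a, b = before[-1], after[0]
    frac = (t - a.stimulus_time) / (b.stimulus_time - a.stimulus_time)
    if interpolate_reciprocal:
        return 1.0 / (1.0 / a.rt + frac * (1.0 / b.rt - 1.0 / a.rt))
    return a.rt + frac * (b.rt - a.rt)


def median_rt_window(t: float, events: list[RTEvent], lookback: float) -> float | None:
    """Harmonic mean of the RTs with stimulus time in [t - lookback, t + 5]."""
    rts = [e.rt for e in events if t - lookback <= e.stimulus_time <= t + WINDOW_LEAD_S]
    if not rts:
        return None
    return float(len(rts) / np.sum([1.0 / x for x in rts]))


def median_rts(t: float, events: list[RTEvent]) -> MedianRTs:
    """All four median RTs at time ``t`` (events must be normalized)."""
    m1 = median_rt_m1(t, events)
    ms = tuple(median_rt_window(t, events, lb) for lb in WINDOW_LOOKBACKS_S)
    return MedianRTs(t=t, m=(m1, *ms))


def label_probability(m: float | None) -> float | None:
    """Ternary drowsiness probability from a median RT (ms)."""
    if m is None:
        return None
    if m <= ALERT_THRESHOLD_MS:
        return 0.0
    if m >= DROWSY_THRESHOLD_MS:
        return 1.0
    return 0.5


def assign_stratum(m: MedianRTs | tuple) -> int | None:
    """Training stratum 0-4: how many median RTs are >= 470 ms.

    Returns None (sample excluded from the training pool) if any median RT
    is undefined.
    """
    values = m.m if isinstance(m, MedianRTs) else tuple(m)
    if any(v is None for v in values):
        return None
    return int(sum(v >= STRATUM_THRESHOLD_MS for v in values))


def validation_weights(frequencies: np.ndarray) -> np.ndarray:
    """Class-balancing weights ``w = (1/f) / 2`` for the validation loss.

    ``frequencies`` holds the occurrence frequency (in (0, 1)) of each
    (timescale, side-of-470-ms) cell; any shape is accepted and preserved.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("occurrence frequencies must lie strictly inside (0, 1)")
    return 1.0 / (2.0 * f)


def compute_validation_frequencies(m_values: np.ndarray) -> np.ndarray:
    """Occurrence frequencies of m_i < 470 vs >= 470 per timescale.

    ``m_values`` is (n_samples, 4); returns a (4, 2) array with columns
    (below, at-or-above).  Raises if any cell is empty (degenerate pool).
    """
    m = np.asarray(m_values, dtype=float)
    ge = m >= STRATUM_THRESHOLD_MS
    f_ge = ge.mean(axis=0)
    freqs = np.stack([1.0 - f_ge, f_ge], axis=1)
    if np.any(freqs <= 0.0):
        raise ValueError("a (timescale, side) cell is empty; validation pool is degenerate")
    return freqs


def label_session(
    session: PVTSession,
    model: NormalizationModel,
    t_eval: np.ndarray,
) -> pd.DataFrame:
    """Label a session at the given evaluation times.

    Returns one row per time: subject/PVT ids, t, m1..m4 (NaN when
    undefined), p1..p4 and the training stratum (NaN when any m is
    undefined).
    """
    events = normalize_events(session, model)
    rows = []
    for t in np.asarray(t_eval, dtype=float):
        med = median_rts(t, events)
        probs = [label_probability(m) for m in med.m]
        stratum = assign_stratum(med)
        rows.append(
            {
                "subject_id": session.subject_id,
                "pvt_id": session.pvt_id,
                "t": t,
                **{f"m{i+1}": (np.nan if m is None else m) for i, m in enumerate(med.m)},
                **{f"p{i+1}": (np.nan if p is None else p) for i, p in enumerate(probs)},
                "stratum": np.nan if stratum is None else stratum,
            }
        )
    return pd.DataFrame(rows)
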
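"""Blink segmentation and multi-window ocular features.

The baseline intermediate representation: from a raw eyelid-distance
series, (1) track the maximum eyelid distance with adaptive exponential
smoothing, (2) normalize the series by that running maximum, (3) threshold
the first derivative of normalized openness to segment each blink into its
closing / closed / re-opening parts, and (4) summarize the blinks in the
four most-recent windows (5, 15, 30, 60 s) by six features each: mean
blink, closing, closed and re-opening durations, microsleep count (blinks
longer than 500 ms), and PERCLOS-70 (fraction of time the eye is at least
70 % closed, i.e. normalized openness < 0.3).  The result is a
24-dimensional feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlinkEvent",
    "track_max_distance",
    "normalize_trace",
    "segment_blinks",
    "window_features",
    "feature_vector",
    "FEATURE_WINDOWS_S",
    "FEATURE_NAMES",
]

#: most-recent window lengths, seconds (window-major order of the vector)
FEATURE_WINDOWS_S = (5.0, 15.0, 30.0, 60.0)
FEATURE_NAMES = (
    "mean_blink_ms",
    "mean_closing_ms",
    "mean_closed_ms",
    "mean_reopening_ms",
    "n_microsleeps",
    "perclos70",
)
MICROSLEEP_MS = 500.0
PERCLOS_OPENNESS = 0.3
DEFAULT_VEL_THRESHOLD = 1.5  # normalized openness per second
DEFAULT_CLOSED_THRESHOLD = 0.3
DEFAULT_SMOOTHING_BETA = 0.002  # per sample


@dataclass(frozen=True)
class BlinkEvent:
    """One segmented blink; half-open sample ranges at the trace's rate.

    ``[closing_start, closing_end)`` is the closing ramp,
    ``[closing_end, reopening_start)`` the closed plateau and
    ``[reopening_start, reopening_end)`` the re-opening ramp.
    """

    closing_start: int
    closing_end: int
    reopening_start: int
    reopening_end: int
    fps: float = 30.0

    def __post_init__(self) -> None:
        ok = self.closing_start < self.closing_end <= self.reopening_start < self.reopening_end
        if not ok:
            raise ValueError("blink phase indices must be ordered")

    @property
    def closing_ms(self) -> float:
        return (self.closing_end - self.closing_start) / self.fps * 1000.0

    @property
    def closed_ms(self) -> float:
        return (self.reopening_start - self.closing_end) / self.fps * 1000.0

    @property
    def reopening_ms(self) -> float:
        return (self.reopening_end - self.reopening_start) / self.fps * 1000.0

    @property
    def total_ms(self) -> float:
        return (self.reopening_end - self.closing_start) / self.fps * 1000.0


def track_max_distance(
    trace: np.ndarray, fps: float = 30.0, beta: float = DEFAULT_SMOOTHING_BETA
) -> np.ndarray:
    """Running maximum eyelid distance via adaptive exponential smoothing.

    ``M_t = max(d_t, (1 - beta) * M_{t-1} + beta * d_t)``: the estimate
    snaps up instantly when the eye opens wider than the current maximum
    and decays slowly (rate ``beta`` per sample) through blinks, tracking
    gradual changes of the wide-open aperture.  ``M_0`` is the 95th
    percentile of the first five seconds (the whole trace if shorter).
    """
    d = np.asarray(trace, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("trace must be a nonempty 1-D array")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("trace must be finite and nonnegative")
    head = d[: max(1, int(round(5.0 * fps)))] if d.size >= int(round(5.0 * fps)) else d
    m0 = float(np.percentile(head, 95.0))
    out = np.empty_like(d)
    m = m0
    for i, x in enumerate(d):
        m = max(x, (1.0 - beta) * m + beta * x)
        out[i] = m
    return out


def normalize_trace(trace: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Normalized openness ``r = d / M``, clipped to [0, 1.5] for robustness."""
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("running maximum must be positive everywhere")
    return np.clip(np.asarray(trace, dtype=float) / M, 0.0, 1.5)


def segment_blinks(
    r: np.ndarray,
    fps: float = 30.0,
    vel_threshold: float = DEFAULT_VEL_THRESHOLD,
    closed_threshold: float = DEFAULT_CLOSED_THRESHOLD,
) -> list[BlinkEvent]:
    """Segment blinks from a normalized-openness series.

    The first derivative is estimated one-sidedly so phase boundaries do
    not smear: a sample is *closing* when it has just fallen steeply
    (backward difference below ``-vel_threshold``), *re-opening* when it is
    about to rise steeply (forward difference above ``+vel_threshold``),
    and *closed* when ``r < closed_threshold`` and it is flat on at least
    one side (or is the sharp turning point of a one-sample plateau).
    Single-sample gaps inside a closed plateau (noise flips) are bridged.
    The closing ramp extends backwards from each closed plateau and the
    re-opening ramp forwards; blinks missing a ramp, or touching the trace
    boundary, are dropped; events are non-overlapping and chronological.
    """
    r = np.asarray(r, dtype=float)
    n = r.size
    if n < 3:
        return []
    bwd = np.zeros(n)
    bwd[1:] = (r[1:] - r[:-1]) * fps  # derivative on the past-facing side
    fwd = np.zeros(n)
    fwd[:-1] = (r[1:] - r[:-1]) * fps  # derivative on the future-facing side

    below = r < closed_threshold
    flat = np.minimum(np.abs(bwd), np.abs(fwd)) <= vel_threshold
    turning = (bwd < -vel_threshold) & (fwd > vel_threshold)
    closed_mask = below & (flat | turning)

    # maximal closed runs [start, stop), merged across short noise gaps
    padded = np.diff(np.concatenate([[0], closed_mask.view(np.int8), [0]]))
    starts, stops = np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)
    runs: list[list[int]] = []
    for a, b in zip(starts, stops):
        if runs and a - runs[-1][1] <= 2 and below[runs[-1][1] : a].all():
            runs[-1][1] = b
        else:
            runs.append([a, b])

    events: list[BlinkEvent] = []
    prev_end = 0
    for a, b in runs:
        # grow the ramps outwards; a single sub-threshold sample inside a
        # ramp (sensor noise) does not terminate it
        cs = a
        while cs - 1 >= prev_end and (
            bwd[cs - 1] < -vel_threshold
            or (cs - 2 >= prev_end and bwd[cs - 1] < 0 and bwd[cs - 2] < -vel_threshold)
        ):
            cs -= 1
        re = b
        while re < n and (
            fwd[re] > vel_threshold
            or (re + 1 < n and fwd[re] > 0 and fwd[re + 1] > vel_threshold)
        ):
            re += 1
        if cs < a and re > b and cs > 0 and re < n:
            events.append(
                BlinkEvent(
                    closing_start=cs, closing_end=a, reopening_start=b, reopening_end=re, fps=fps
                )
            )
            prev_end = re
    return events


def _perclos(r: np.ndarray, start: int, stop: int) -> float:
    window = r[max(0, start) : stop]
    if window.size == 0:
        return 0.0
    return float(np.mean(window < PERCLOS_OPENNESS))


def window_features(
    blinks: list[BlinkEvent],
    r: np.ndarray,
    fps: float,
    window_s: float,
    t_end: float,
) -> np.ndarray:
    """Six ocular features over the causal window [t_end - window_s, t_end].

    Blinks are attributed to the window by their closing onset.  Windows
    without blinks yield zeros for the four mean durations and the
    microsleep count; PERCLOS-70 is always the per-sample fraction of the
    window with normalized openness below 0.3.
    """
    i_end = int(round(t_end * fps))
    if not 0 <= i_end <= len(r):
        raise ValueError("t_end outside the trace")
    i_start = i_end - int(round(window_s * fps))
    t_start = t_end - window_s
    selected = [b for b in blinks if t_start <= b.closing_start / fps <= t_end]
    if selected:
        feats = [
            float(np.mean([b.total_ms for b in selected])),
            float(np.mean([b.closing_ms for b in selected])),
            float(np.mean([b.closed_ms for b in selected])),
            float(np.mean([b.reopening_ms for b in selected])),
            float(sum(b.total_ms > MICROSLEEP_MS for b in selected)),
        ]
    else:
        feats = [0.0, 0.0, 0.0, 0.0, 0.0]
    feats.append(_perclos(r, i_start, i_end))
    return np.array(feats)


def feature_vector(
    left: np.ndarray,
    right: np.ndarray,
    fps: float,
    t_end: float,
    vel_threshold: float = DEFAULT_VEL_THRESHOLD,
    closed_threshold: float = DEFAULT_CLOSED_THRESHOLD,
) -> np.ndarray:
    """The 24-dimensional ocular feature vector at ``t_end``.

    Both eyes are normalized independently and averaged into a single
    openness series (eyelids blink together; averaging suppresses
    uncorrelated per-eye noise), then the six features are computed over
    each of the four most-recent windows.  Window-major, feature-minor
    order.  ``t_end`` must be at least 60 s into the trace.
    """
    if t_end < FEATURE_WINDOWS_S[-1]:
        raise ValueError("t_end must be at least 60 s into the trace")
    r_left = normalize_trace(left, track_max_distance(left, fps))
    r_right = normalize_trace(right, track_max_distance(right, fps))
    r = (r_left + r_right) / 2.0
    blinks = segment_blinks(r, fps, vel_threshold, closed_threshold)
    parts = [window_features(blinks, r, fps, w, t_end) for w in FEATURE_WINDOWS_S]
    return np.concatenate(parts)
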
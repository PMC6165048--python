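"""Subject-wise cross-validation and pooled performance metrics.

Evaluation follows the subject-generic protocol: leave-one-subject-out
folds with disjoint train/validation/test subject sets, stimulus-anchored
sampling of 1-min sequences (every PVT stimulus from 60 s onward),
discarding of indeterminate samples (target probability 0.5) per
timescale, and confusion counts pooled across folds before computing TNR,
TPR and accuracy.  The four binary decisions can be summed into a combined
level of drowsiness 0-4; the fraction of monotone joint patterns
(0000/1000/1100/1110/1111) is a diagnostic of the learned timescale
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import PVTSession

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "make_folds",
    "sample_eval_points",
    "filter_definite",
    "aggregate_metrics",
    "combined_lod",
    "outcome_histogram",
    "monotone_outcome_fraction",
    "MONOTONE_PATTERNS",
]

TIMESCALES_S = (5, 15, 30, 60)
MONOTONE_PATTERNS = ("0000", "1000", "1100", "1110", "1111")


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold; the three subject sets are disjoint."""

    fold_id: int
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b, c = set(self.train), set(self.val), set(self.test)
        if a & b or a & c or b & c:
            raise ValueError("train/val/test subject sets must be disjoint")
        if len(self.test) != 1:
            raise ValueError("test set must hold exactly one subject")


def make_folds(subjects: list[str], seed: int = 0, val_size: int | None = None) -> list[FoldSplit]:
    """Leave-one-subject-out folds by rotation.

    With ``n`` subjects there are ``n`` folds; fold ``i`` tests subject
    ``i`` (of a seed-shuffled order), validates on the next ``v`` subjects
    cyclically, and trains on the rest.  Every subject therefore appears
    exactly once as test, ``v`` times in validation and ``n - 1 - v`` times
    in training.  The default ``v`` scales the 23/5/1 design:
    ``round(5 n / 29)``, at least 1.
    """
    subjects = list(subjects)
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects for train/val/test folds")
    v = val_size if val_size is not None else max(1, round(5 * n / 29))
    if n - 1 - v < 1:
        raise ValueError(f"validation size {v} leaves no training subjects for n={n}")
    order = list(np.random.default_rng(seed).permutation(subjects))
    folds = []
    for i in range(n):
        test = [order[i]]
        val = [order[(i + 1 + j) % n] for j in range(v)]
        train = [s for s in order if s not in set(test) | set(val)]
        folds.append(FoldSplit(fold_id=i, train=tuple(train), val=tuple(val), test=tuple(test)))
    return folds


def sample_eval_points(session: PVTSession, min_t: float = 60.0) -> list[float]:
    """Stimulus-anchored evaluation times: every stimulus from 60 s onward.

    Each returned time is the end of a 1-min sequence, so the 5 s label is
    exactly synchronized with a performed RT.  Stimuli inside the first
    minute are excluded (their sequence would be truncated); a stimulus at
    exactly 60 s is included.
    """
    return [e.stimulus_time for e in session.rt_events if e.stimulus_time >= min_t]


def filter_definite(p: np.ndarray, timescale_index: int) -> np.ndarray:
    """Boolean mask of samples whose target at this timescale is 0 or 1."""
    p = np.asarray(p, dtype=float)
    return np.isin(p[:, timescale_index], (0.0, 1.0))


@dataclass
class MetricsReport:
    """Pooled per-timescale confusion counts and derived rates."""

    per_timescale: dict[int, dict]

    def table(self) -> str:
        lines = ["timescale  n      TN    FP    FN    TP    TNR     TPR     accuracy"]
        for ts in TIMESCALES_S:
            m = self.per_timescale[ts]
            lines.append(
                f"{ts:>6} s  {m['n']:>5} {m['tn']:>5} {m['fp']:>5} {m['fn']:>5} {m['tp']:>5}"
                f"  {m['tnr']:.4f}  {m['tpr']:.4f}  {m['accuracy']:.4f}"
            )
        return "\n".join(lines)


def aggregate_metrics(fold_results: list[tuple[np.ndarray, np.ndarray]]) -> MetricsReport:
    """Pool per-fold (targets, decisions) pairs and compute the metrics.

    Each element is ``(p, decisions)`` with shapes (n, 4): ``p`` in
    {0, 0.5, 1} and ``decisions`` binary.  Indeterminate samples are
    discarded per timescale, the confusion counts are summed across folds
    *before* any rate is computed (subjects contribute proportionally to
    their sample counts), and TNR/TPR/accuracy follow.
    """
    per = {}
    for i, ts in enumerate(TIMESCALES_S):
        tn = fp = fn = tp = 0
        for p, dec in fold_results:
            p = np.atleast_2d(np.asarray(p, dtype=float))
            dec = np.atleast_2d(np.asarray(dec))
            mask = filter_definite(p, i)
            y, yhat = p[mask, i].astype(int), dec[mask, i].astype(int)
            tn += int(np.sum((y == 0) & (yhat == 0)))
            fp += int(np.sum((y == 0) & (yhat == 1)))
            fn += int(np.sum((y == 1) & (yhat == 0)))
            tp += int(np.sum((y == 1) & (yhat == 1)))
        total = tn + fp + fn + tp
        per[ts] = {
            "tn": tn,
            "fp": fp,
            "fn": fn,
            "tp": tp,
            "n": total,
            "tnr": tn / (tn + fp) if tn + fp else float("nan"),
            "tpr": tp / (tp + fn) if tp + fn else float("nan"),
            "accuracy": (tn + tp) / total if total else float("nan"),
        }
    return MetricsReport(per_timescale=per)


def combined_lod(decisions: np.ndarray) -> np.ndarray | int:
    """Sum the four binary decisions into a combined level of drowsiness 0-4."""
    d = np.asarray(decisions)
    if d.ndim == 1:
        return int(d.sum())
    return d.sum(axis=1).astype(int)


def _patterns(decisions: np.ndarray) -> list[str]:
    d = np.atleast_2d(np.asarray(decisions)).astype(int)
    return ["".join(str(int(v)) for v in row) for row in d]


def outcome_histogram(decisions: np.ndarray) -> dict[str, int]:
    """Counts of the 16 joint decision patterns (all keys always present)."""
    keys = [f"{i:04b}" for i in range(16)]
    hist = dict.fromkeys(keys, 0)
    for pattern in _patterns(decisions):
        hist[pattern] += 1
    return hist


def monotone_outcome_fraction(decisions: np.ndarray) -> float:
    """Fraction of samples whose joint pattern is timescale-monotone.

    Monotone patterns (0000, 1000, 1100, 1110, 1111) mean a drowsy decision
    at some timescale implies drowsy decisions at all shorter timescales.
    Reported as a diagnostic in [0, 1], not enforced.
    """
    patterns = _patterns(decisions)
    if not patterns:
        raise ValueError("no decisions given")
    return float(np.mean([p in MONOTONE_PATTERNS for p in patterns]))
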
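"""PVT session containers and plain-text session I/O.

A session couples one 10-min psychomotor vigilance task (PVT) with the
30 Hz bilateral eyelid-distance trace recorded while the subject performed
it.  Sessions are stored as a directory of reviewable text files:
``trace.csv`` (time_s, left_dist_px, right_dist_px), ``rt.csv``
(stimulus_time_s, rt_ms), ``meta.json`` and, for synthetic sessions,
``latent.csv`` holding the latent drowsiness series used by oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RTEvent", "PVTSession", "read_session", "write_session"]


@dataclass(frozen=True)
class RTEvent:
    """One PVT stimulus and the reaction time it elicited."""

    stimulus_time: float  # seconds from session start
    rt: float  # milliseconds, > 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.rt) or self.rt <= 0:
            raise ValueError(f"reaction time must be positive and finite, got {self.rt}")


@dataclass
class PVTSession:
    """One PVT: eyelid-distance trace plus the reaction-time log.

    ``latent_drowsiness`` is only populated for synthetic sessions; it is the
    simulator's hidden state and exists solely so tests can use it as an
    oracle.  ``blink_log`` likewise records the simulator's rendered blinks
    (onset sample and per-phase sample counts).
    """

    subject_id: str
    pvt_id: str
    trace_times: np.ndarray  # seconds, 30 Hz grid
    left_dist: np.ndarray  # pixels
    right_dist: np.ndarray  # pixels
    rt_events: list[RTEvent]
    fps: float = 30.0
    tag: str = ""
    seed: int | None = None
    latent_drowsiness: np.ndarray | None = None
    blink_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.trace_times)
        if len(self.left_dist) != n or len(self.right_dist) != n:
            raise ValueError("trace channels and times must have equal length")
        times = [e.stimulus_time for e in self.rt_events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("rt_events must be sorted by stimulus time")
        if times and (times[0] < 0 or times[-1] > self.duration_s):
            raise ValueError("stimulus times must lie within the session")

    @property
    def duration_s(self) -> float:
        return len(self.trace_times) / self.fps

    @property
    def key(self) -> str:
        return f"{self.subject_id}/{self.pvt_id}"


def write_session(session: PVTSession, out_dir: str | Path) -> Path:
    """Write a session to ``out_dir`` as trace.csv + rt.csv + meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": session.trace_times,
            "left_dist_px": session.left_dist,
            "right_dist_px": session.right_dist,
        }
    ).to_csv(out / "trace.csv", index=False, float_format="%.10f")
    pd.DataFrame(
        {
            "stimulus_time_s": [e.stimulus_time for e in session.rt_events],
            "rt_ms": [e.rt for e in session.rt_events],
        }
    ).to_csv(out / "rt.csv", index=False, float_format="%.10f")
    meta = {
        "subject_id": session.subject_id,
        "pvt_id": session.pvt_id,
        "tag": session.tag,
        "fps": session.fps,
        "seed": session.seed,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    if session.latent_drowsiness is not None:
        pd.DataFrame({"drowsiness": session.latent_drowsiness}).to_csv(
            out / "latent.csv", index=False, float_format="%.6f"
        )
    return out


def read_session(in_dir: str | Path) -> PVTSession:
    """Read a session directory written by :func:`write_session`.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` naming
    the offending row for malformed content.
    """
    in_dir = Path(in_dir)
    for name in ("trace.csv", "rt.csv", "meta.json"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"missing {name} in session directory {in_dir}")
    trace = pd.read_csv(in_dir / "trace.csv")
    for col in ("time_s", "left_dist_px", "right_dist_px"):
        if col not in trace.columns:
            raise ValueError(f"trace.csv misses column {col!r}")
        bad = np.flatnonzero(~np.isfinite(trace[col].to_numpy(float)))
        if bad.size:
            raise ValueError(f"trace.csv row {bad[0]}: non-finite {col}")
    t = trace["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"trace.csv row {row}: non-monotone time_s")
    rt = pd.read_csv(in_dir / "rt.csv")
    meta = json.loads((in_dir / "meta.json").read_text())
    events = []
    for i, row in rt.iterrows():
        try:
            events.append(RTEvent(float(row["stimulus_time_s"]), float(row["rt_ms"])))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"rt.csv row {i}: {exc}") from exc
    latent = None
    if (in_dir / "latent.csv").exists():
        latent = pd.read_csv(in_dir / "latent.csv")["drowsiness"].to_numpy(float)
    return PVTSession(
        subject_id=str(meta["subject_id"]),
        pvt_id=str(meta["pvt_id"]),
        trace_times=t,
        left_dist=trace["left_dist_px"].to_numpy(float),
        right_dist=trace["right_dist_px"].to_numpy(float),
        rt_events=events,
        fps=float(meta.get("fps", 30.0)),
        tag=str(meta.get("tag", "")),
        seed=meta.get("seed"),
        latent_drowsiness=latent,
    )
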
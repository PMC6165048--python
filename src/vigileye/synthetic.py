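"""Synthetic PVT-session simulator.

Generates cohorts of synthetic 10-min psychomotor vigilance task (PVT)
sessions — a 30 Hz bilateral eyelid-distance trace plus a stimulus/RT log —
coupled through a latent drowsiness process ``D(t)`` in [0, 1]:

* blinks get longer (and microsleeps more likely) as ``D`` rises, which is
  the physiological signature the eyelid-trace models exploit;
* reaction *speed* (the reciprocal RT, approximately normal within a
  subject) decreases linearly with ``D``, so reaction times lengthen.

Blink morphology is trapezoidal: a linear closing ramp, a closed plateau
near zero aperture, and a linear re-opening ramp, with multiplicative
per-blink jitter.  Every rendered blink is kept in a log (onset sample and
per-phase sample counts) so segmentation code can be tested against the
construction rather than against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import PVTSession, RTEvent

__all__ = [
    "DrowsinessProcess",
    "BlinkModel",
    "RTModel",
    "SyntheticConfig",
    "simulate_drowsiness",
    "simulate_trace",
    "simulate_rts",
    "simulate_cohort",
]

_SEED_MOD = 2**31 - 1


@dataclass
class DrowsinessProcess:
    """Latent drowsiness ``D(t)``: piecewise-constant per block, or smoothed.

    ``deprived_level`` is the level a sleep-deprived session starts at; the
    per-block random walk (std ``volatility``) then wanders within
    ``level_range``.  Alert sessions pin ``D`` at zero.
    """

    kind: str = "piecewise-constant"  # or "smoothed-random-walk"
    level_range: tuple[float, float] = (0.0, 1.0)
    volatility: float = 0.25
    block_s: float = 60.0
    deprived_level: float = 0.8

    def __post_init__(self) -> None:
        lo, hi = self.level_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("level_range must satisfy 0 <= lo <= hi <= 1")
        if self.kind not in ("piecewise-constant", "smoothed-random-walk"):
            raise ValueError(f"unknown drowsiness process kind {self.kind!r}")
        if self.block_s <= 0 or self.volatility < 0:
            raise ValueError("block_s must be positive and volatility nonnegative")


@dataclass
class BlinkModel:
    """Blink generator: rate, trapezoid phase durations, drowsiness coupling.

    ``drowsy_duration_gain`` multiplies all three phase durations at D = 1
    (interpolated linearly in D).  ``microsleep_prob_at_D1`` is the per-blink
    probability, at D = 1, that the closed plateau is stretched into a
    microsleep (closed phase drawn from ``microsleep_closed_ms``).
    """

    base_rate: float = 15.0  # blinks per minute at D = 0
    base_durations_ms: tuple[float, float, float] = (100.0, 50.0, 150.0)
    drowsy_duration_gain: float = 2.5
    microsleep_prob_at_D1: float = 0.25
    microsleep_closed_ms: tuple[float, float] = (550.0, 1500.0)
    baseline_px: float = 10.0
    closed_frac: float = 0.02  # plateau aperture as fraction of baseline
    jitter: float = 0.2  # multiplicative U(1-j, 1+j) per phase
    noise_frac: float = 0.02  # per-channel Gaussian noise, fraction of baseline
    min_gap_s: float = 0.3

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or any(d <= 0 for d in self.base_durations_ms):
            raise ValueError("blink rate and durations must be positive")
        if not 0.0 <= self.microsleep_prob_at_D1 <= 1.0:
            raise ValueError("microsleep_prob_at_D1 must be a probability")
        if self.drowsy_duration_gain < 1.0:
            raise ValueError("drowsy_duration_gain must be >= 1")
        if not 0.0 <= self.jitter < 1.0:
            raise ValueError("jitter must be in [0, 1)")


@dataclass
class RTModel:
    """Reaction-speed model: speed ~ N(alert_speed - loss * D, sd), RT = 1/speed.

    All speeds are in 1/ms.  ``subject_speed_sd`` is the between-subject
    spread of the alert speed (drawn once per subject); the speed is floored
    at ``speed_floor`` (default 1/3000 ms^-1) for numerical safety.
    """

    alert_speed_mean: float = 1.0 / 280.0
    speed_loss_at_D1: float = 0.0022
    speed_sd: float = 0.0004
    subject_speed_sd: float = 0.0003
    speed_floor: float = 1.0 / 3000.0

    def __post_init__(self) -> None:
        if self.alert_speed_mean <= 0 or self.speed_floor <= 0:
            raise ValueError("speeds must be positive")
        if self.speed_sd < 0 or self.subject_speed_sd < 0 or self.speed_loss_at_D1 < 0:
            raise ValueError("speed spreads and loss must be nonnegative")


@dataclass
class SyntheticConfig:
    """Full cohort configuration; see the component dataclasses for fields."""

    duration_s: float = 600.0
    fps: float = 30.0
    n_subjects: int = 8
    pvt_schedule: tuple[str, ...] = ("alert", "deprived", "deprived")
    drowsiness_process: DrowsinessProcess = field(default_factory=DrowsinessProcess)
    blink_model: BlinkModel = field(default_factory=BlinkModel)
    rt_model: RTModel = field(default_factory=RTModel)
    stimulus_interval_s: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_s * self.fps
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fps must be an integer number of samples")
        lo, hi = self.stimulus_interval_s
        if not 0 < lo <= hi:
            raise ValueError("stimulus interval range must be positive and ordered")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fps))


def simulate_drowsiness(config: SyntheticConfig, session_tag: str, seed: int) -> np.ndarray:
    """Latent drowsiness series on the trace grid for one session.

    ``"alert"`` sessions are pinned at D = 0; ``"deprived"`` sessions start
    at ``deprived_level`` and follow a per-block random walk clipped to
    ``level_range`` (piecewise-constant per block, or linearly smoothed for
    the ``smoothed-random-walk`` kind).
    """
    proc = config.drowsiness_process
    n = config.n_samples
    if session_tag == "alert":
        return np.zeros(n)
    if session_tag != "deprived":
        raise ValueError(f"unknown session tag {session_tag!r}")
    rng = np.random.default_rng(seed)
    n_blocks = max(1, int(np.ceil(config.duration_s / proc.block_s)))
    steps = rng.normal(0.0, proc.volatility, size=n_blocks)
    steps[0] = 0.0
    levels = np.clip(proc.deprived_level + np.cumsum(steps), *proc.level_range)
    block_len = int(round(proc.block_s * config.fps))
    if proc.kind == "piecewise-constant":
        d = np.repeat(levels, block_len)[:n]
        if d.size < n:  # duration not a multiple of block_s
            d = np.concatenate([d, np.full(n - d.size, levels[-1])])
    else:  # smoothed-random-walk: linear interpolation between block centres
        centres = (np.arange(n_blocks) + 0.5) * block_len
        d = np.interp(np.arange(n), centres, levels)
    return np.clip(d, 0.0, 1.0)


def simulate_trace(
    D: np.ndarray, config: SyntheticConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Render the bilateral eyelid-distance trace driven by ``D``.

    Returns ``(left, right, blink_log)``.  Each blink-log entry holds the
    onset sample, the per-phase sample counts ``(n_closing, n_closed,
    n_reopening)``, the jittered phase durations in ms, and whether the
    blink was stretched into a microsleep.  Left and right channels share
    the blink template and differ by independent Gaussian noise.
    """
    bm = config.blink_model
    fps = config.fps
    n = len(D)
    b = bm.baseline_px
    plateau = bm.closed_frac * b
    template = np.full(n, b)
    log: list[dict] = []
    rng = np.random.default_rng(seed)

    t = rng.uniform(0.0, 60.0 / bm.base_rate)
    while True:
        s = int(round(t * fps))
        if s >= n:
            break
        d0 = float(D[s])
        gain = 1.0 + (bm.drowsy_duration_gain - 1.0) * d0
        jit = rng.uniform(1.0 - bm.jitter, 1.0 + bm.jitter, size=3)
        closing_ms = bm.base_durations_ms[0] * gain * jit[0]
        closed_ms = bm.base_durations_ms[1] * gain * jit[1]
        reopening_ms = bm.base_durations_ms[2] * gain * jit[2]
        microsleep = rng.random() < bm.microsleep_prob_at_D1 * d0
        if microsleep:
            closed_ms = rng.uniform(*bm.microsleep_closed_ms)
        n_c = max(1, int(round(closing_ms / 1000.0 * fps)))
        n_z = max(1, int(round(closed_ms / 1000.0 * fps)))
        n_r = max(1, int(round(reopening_ms / 1000.0 * fps)))
        end = s + n_c + n_z + n_r
        if end >= n:  # partial blink at the boundary: drop it
            break
        template[s : s + n_c] = np.linspace(b, plateau, n_c + 2)[1:-1]
        template[s + n_c : s + n_c + n_z] = plateau
        template[s + n_c + n_z : end] = np.linspace(plateau, b, n_r + 2)[1:-1]
        log.append(
            {
                "onset": s,
                "n_closing": n_c,
                "n_closed": n_z,
                "n_reopening": n_r,
                "closing_ms": closing_ms,
                "closed_ms": closed_ms,
                "reopening_ms": reopening_ms,
                "microsleep": bool(microsleep),
            }
        )
        gap = max(bm.min_gap_s, rng.exponential(60.0 / bm.base_rate))
        t = end / fps + gap

    noise = rng.normal(0.0, bm.noise_frac * b, size=(2, n))
    left = np.clip(template + noise[0], 0.0, None)
    right = np.clip(template + noise[1], 0.0, None)
    return left, right, log


def simulate_rts(
    D: np.ndarray,
    config: SyntheticConfig,
    seed: int,
    subject_alert_speed: float | None = None,
) -> list[RTEvent]:
    """Draw stimulus times and reaction times for one session.

    Stimulus times are cumulative uniform draws from
    ``config.stimulus_interval_s``; each RT is the reciprocal of a normal
    reaction speed whose mean decreases linearly with ``D`` at the stimulus
    time, floored at ``speed_floor``.
    """
    rm = config.rt_model
    rng = np.random.default_rng(seed)
    mu0 = rm.alert_speed_mean if subject_alert_speed is None else subject_alert_speed
    events: list[RTEvent] = []
    lo, hi = config.stimulus_interval_s
    t = rng.uniform(lo, hi)
    n = len(D)
    while t <= config.duration_s:
        d0 = float(D[min(int(t * config.fps), n - 1)])
        speed = rng.normal(mu0 - rm.speed_loss_at_D1 * d0, rm.speed_sd)
        speed = max(speed, rm.speed_floor)
        events.append(RTEvent(stimulus_time=t, rt=1.0 / speed))
        t += rng.uniform(lo, hi)
    return events


def simulate_cohort(config: SyntheticConfig) -> list[PVTSession]:
    """Simulate one session per (subject, schedule tag), deterministically.

    Each subject's alert reaction speed is drawn once and shared across that
    subject's sessions, so inter-subject RT normalization has something real
    to remove.  Requires at least two subjects (leave-one-subject-out needs
    that many).
    """
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 for subject-wise cross-validation")
    master = np.random.default_rng(config.seed)
    times = np.arange(config.n_samples) / config.fps
    sessions: list[PVTSession] = []
    for i in range(config.n_subjects):
        subject_id = f"s{i:02d}"
        speed = config.rt_model.alert_speed_mean + config.rt_model.subject_speed_sd * master.normal()
        speed = max(speed, 2.0 * config.rt_model.speed_floor)
        for j, tag in enumerate(config.pvt_schedule):
            seeds = master.integers(0, _SEED_MOD, size=3)
            d = simulate_drowsiness(config, tag, int(seeds[0]))
            left, right, log = simulate_trace(d, config, int(seeds[1]))
            events = simulate_rts(d, config, int(seeds[2]), subject_alert_speed=speed)
            session = PVTSession(
                subject_id=subject_id,
                pvt_id=f"pvt{j}",
                trace_times=times.copy(),
                left_dist=left,
                right_dist=right,
                rt_events=events,
                fps=config.fps,
                tag=tag,
                seed=int(seeds[0]),
                latent_drowsiness=d,
            )
            session.blink_log = log
            sessions.append(session)
    return sessions
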
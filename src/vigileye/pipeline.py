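"""End-to-end experiment orchestration.

Runs the full study on a synthetic cohort: simulate sessions, fit the RT
normalization on the alert reference sessions, label 1-min sequences,
build subject-rotated cross-validation folds, train the temporal CNN and
the feature-based baseline per fold, and pool the test decisions into the
final metrics.  Every random draw descends from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .blink import FEATURE_WINDOWS_S, normalize_trace, segment_blinks, track_max_distance, window_features
from .evaluation import (
    aggregate_metrics,
    make_folds,
    monotone_outcome_fraction,
    outcome_histogram,
    sample_eval_points,
)
from .ground_truth import NormalizationModel, assign_stratum, fit_normalization, label_probability, median_rts, normalize_events
from .net import NetConfig, SequenceSample, TrainConfig, train_fold
from .proxy import DEFAULT_C_GRID, fit_proxy, predict_proxy
from .session import PVTSession
from .synthetic import SyntheticConfig, simulate_cohort

__all__ = [
    "ExperimentConfig",
    "build_samples",
    "session_features",
    "run_experiment",
    "scaled_net_config",
    "scaled_train_config",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31 - 1


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; sub-configs own their domains."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    grid_step_s: float = 2.0  # spacing of the frame-level training grid
    val_size: int | None = None  # subjects per validation set (None: scaled 5/29 rule)
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    reference_tag: str = "alert"
    include_net: bool = True
    include_proxy: bool = True
    shuffle_labels: bool = False  # negative control: permute training/validation labels
    seed: int = 0


def scaled_net_config() -> NetConfig:
    """CPU-scale architecture for synthetic experiments (width 8, heads 8)."""
    return NetConfig(width=8, head_width=8)


def scaled_train_config(seed: int = 0) -> TrainConfig:
    """CPU-scale training schedule for synthetic experiments."""
    return TrainConfig(stratum_quota=64, max_epochs=6, patience=2, seed=seed, val_subsample=160)


def _labeled_sample(session: PVTSession, events, t: float) -> SequenceSample:
    med = median_rts(t, events)
    p = np.array([np.nan if label_probability(m) is None else label_probability(m) for m in med.m])
    m = np.array([np.nan if v is None else v for v in med.m])
    return SequenceSample(session=session, t_end=t, p=p, m=m, stratum=assign_stratum(med))


def build_samples(
    sessions: list[PVTSession],
    model: NormalizationModel,
    grid_step_s: float = 2.0,
    seq_len_s: float = 60.0,
) -> dict[str, dict]:
    """Label each session's evaluation and training-grid sample sets.

    Evaluation samples are stimulus-anchored (one per PVT stimulus from
    60 s onward).  Training samples come from a regular time grid over
    [60 s, duration] with step ``grid_step_s`` — a tractable stand-in for
    "every frame" — and only keep points where all four median RTs are
    defined (so the stratum exists).
    """
    out: dict[str, dict] = {}
    for session in sessions:
        if session.subject_id not in model:
            logger.warning("skipping %s: subject not in normalization model", session.key)
            continue
        events = normalize_events(session, model)
        eval_samples = [_labeled_sample(session, events, t) for t in sample_eval_points(session)]
        grid = np.arange(seq_len_s, session.duration_s + 1e-9, grid_step_s)
        grid_samples = [
            s for s in (_labeled_sample(session, events, t) for t in grid) if s.stratum is not None
        ]
        out[session.key] = {"session": session, "eval": eval_samples, "grid": grid_samples}
    return out


def session_features(session: PVTSession, t_ends: list[float]) -> np.ndarray:
    """24-feature ocular vectors at each ``t_end`` (one segmentation pass)."""
    fps = session.fps
    r_left = normalize_trace(session.left_dist, track_max_distance(session.left_dist, fps))
    r_right = normalize_trace(session.right_dist, track_max_distance(session.right_dist, fps))
    r = (r_left + r_right) / 2.0
    blinks = segment_blinks(r, fps)
    rows = [
        np.concatenate([window_features(blinks, r, fps, w, t) for w in FEATURE_WINDOWS_S])
        for t in t_ends
    ]
    return np.stack(rows) if rows else np.empty((0, 24))


def _shuffle_sample_labels(samples: list[SequenceSample], rng: np.random.Generator) -> list[SequenceSample]:
    perm = rng.permutation(len(samples))
    return [
        SequenceSample(
            session=s.session, t_end=s.t_end,
            p=samples[j].p, m=samples[j].m, stratum=samples[j].stratum,
        )
        for s, j in zip(samples, perm)
    ]


def _collect(samples_by_key: dict, subjects: set[str], kind: str) -> list[SequenceSample]:
    return [
        s
        for entry in samples_by_key.values()
        if entry["session"].subject_id in subjects
        for s in entry[kind]
    ]


def run_experiment(config: ExperimentConfig) -> dict:
    """Simulate, label, train both systems fold-by-fold, pool the metrics.

    Returns a JSON-serializable report with per-timescale confusion counts
    and rates for the temporal CNN and the feature baseline, the combined
    level-of-drowsiness outcome histogram, the monotone-pattern fraction,
    and the per-fold training histories.
    """
    rng = np.random.default_rng(config.seed)
    synth = replace(config.synthetic, seed=int(rng.integers(0, _SEED_MOD)))
    sessions = simulate_cohort(synth)
    reference = [s for s in sessions if s.tag == config.reference_tag]
    model = fit_normalization(reference)
    samples_by_key = build_samples(sessions, model, grid_step_s=config.grid_step_s)
    subjects = sorted({e["session"].subject_id for e in samples_by_key.values()})
    folds = make_folds(subjects, seed=int(rng.integers(0, _SEED_MOD)), val_size=config.val_size)

    features_by_key = {
        key: session_features(entry["session"], [s.t_end for s in entry["eval"]])
        for key, entry in samples_by_key.items()
    } if config.include_proxy else {}

    report: dict = {"seed": config.seed, "n_subjects": len(subjects), "folds": len(folds)}
    net_results, proxy_results, histories = [], [], []
    shuffle_rng = np.random.default_rng(config.seed + 17)

    for fold in folds:
        train_subjects, val_subjects, test_subjects = set(fold.train), set(fold.val), set(fold.test)
        test_samples = _collect(samples_by_key, test_subjects, "eval")
        if not test_samples:
            continue
        p_test = np.stack([s.p for s in test_samples])

        if config.include_net:
            train_samples = _collect(samples_by_key, train_subjects, "grid")
            val_samples = _collect(samples_by_key, val_subjects, "eval")
            if config.shuffle_labels:
                train_samples = _shuffle_sample_labels(train_samples, shuffle_rng)
                val_samples = _shuffle_sample_labels(val_samples, shuffle_rng)
            fold_tc = replace(config.train, seed=int(rng.integers(0, _SEED_MOD)))
            net, history = train_fold(train_samples, val_samples, config.net, fold_tc)
            x_test = np.stack([s.matrix(config.net.seq_len) for s in test_samples]).astype(np.float32)
            dec = (net.predict_proba(x_test) >= 0.5).astype(int)
            net_results.append((p_test, dec))
            histories.append({"fold": fold.fold_id, "epochs": len(history), "history": history})

        if config.include_proxy:
            fit_subjects = train_subjects | val_subjects  # all but the test subject
            X_tr, p_tr, subj_tr = [], [], []
            for key, entry in samples_by_key.items():
                if entry["session"].subject_id in fit_subjects and len(entry["eval"]):
                    X_tr.append(features_by_key[key])
                    p_tr.append(np.stack([s.p for s in entry["eval"]]))
                    subj_tr.extend([entry["session"].subject_id] * len(entry["eval"]))
            proxy = fit_proxy(
                np.concatenate(X_tr), np.concatenate(p_tr), np.array(subj_tr), config.c_grid
            )
            X_te = np.concatenate(
                [
                    features_by_key[key]
                    for key, entry in samples_by_key.items()
                    if entry["session"].subject_id in test_subjects and len(entry["eval"])
                ]
            )
            proxy_results.append((p_test, predict_proxy(proxy, X_te)))

    if config.include_net and net_results:
        net_metrics = aggregate_metrics(net_results)
        all_dec = np.concatenate([dec for _, dec in net_results])
        report["net"] = {
            "metrics": net_metrics.per_timescale,
            "outcome_histogram": outcome_histogram(all_dec),
            "monotone_fraction": monotone_outcome_fraction(all_dec),
        }
        report["histories"] = histories
    if config.include_proxy and proxy_results:
        report["proxy"] = {"metrics": aggregate_metrics(proxy_results).per_timescale}
    return report
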
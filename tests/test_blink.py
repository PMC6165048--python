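"""Blink segmentation and ocular features against constructed fixtures."""

import numpy as np
import pytest

from vigileye import (
    BlinkModel,
    SyntheticConfig,
    feature_vector,
    normalize_trace,
    segment_blinks,
    simulate_trace,
    track_max_distance,
    window_features,
)
from vigileye.blink import BlinkEvent

FPS = 30.0


def _trapezoid(n_total, blinks, baseline=10.0, plateau=0.2):
    """Render trapezoid blinks like the generator does: (onset, nc, nz, nr)."""
    d = np.full(n_total, baseline)
    for s, nc, nz, nr in blinks:
        d[s : s + nc] = np.linspace(baseline, plateau, nc + 2)[1:-1]
        d[s + nc : s + nc + nz] = plateau
        d[s + nc + nz : s + nc + nz + nr] = np.linspace(plateau, baseline, nr + 2)[1:-1]
    return d


class TestRunningMax:
    def test_constant_trace_is_fixed_point(self):
        np.testing.assert_allclose(track_max_distance(np.full(400, 10.0)), 10.0)

    def test_decay_through_a_dip_is_bounded_geometric(self):
        beta = 0.002
        d = np.full(600, 10.0)
        d[300:330] = 0.0
        m = track_max_distance(d, FPS, beta=beta)
        assert np.all(m[300:330] <= 10.0 + 1e-12)
        assert np.all(m[300:330] >= 10.0 * (1 - beta) ** 30)

    def test_snaps_up_to_new_maximum(self):
        d = np.concatenate([np.full(200, 10.0), np.full(200, 12.0)])
        m = track_max_distance(d, FPS)
        assert m[200] == pytest.approx(12.0)

    def test_rejects_bad_traces(self):
        with pytest.raises(ValueError):
            track_max_distance(np.array([1.0, -2.0, 3.0]))


class TestNormalize:
    def test_basic_ratios(self):
        m = np.full(3, 10.0)
        np.testing.assert_allclose(normalize_trace(np.array([10.0, 0.0, 5.0]), m), [1.0, 0.0, 0.5])

    def test_nonpositive_maximum_rejected(self):
        with pytest.raises(ValueError):
            normalize_trace(np.ones(3), np.zeros(3))


class TestSegmentation:
    def test_flat_trace_has_no_blinks(self):
        assert segment_blinks(np.ones(500), FPS) == []

    def test_two_separated_trapezoids_in_order(self):
        d = _trapezoid(900, [(100, 3, 2, 5), (500, 3, 2, 5)])
        events = segment_blinks(d / 10.0, FPS)
        assert len(events) == 2
        assert events[0].closing_start < events[1].closing_start

    def test_recovered_phases_match_construction(self):
        nc, nz, nr = 3, 2, 5  # 100 / 67 / 167 ms at 30 Hz
        d = _trapezoid(600, [(200, nc, nz, nr)])
        (event,) = segment_blinks(d / 10.0, FPS)
        assert abs((event.closing_end - event.closing_start) - nc) <= 1
        assert abs((event.reopening_start - event.closing_end) - nz) <= 1
        assert abs((event.reopening_end - event.reopening_start) - nr) <= 1

    def test_translation_equivariance(self):
        blink = [(150, 3, 2, 5)]
        d1 = _trapezoid(900, blink)
        k = 57
        d2 = _trapezoid(900, [(150 + k, 3, 2, 5)])
        e1 = segment_blinks(d1 / 10.0, FPS)
        e2 = segment_blinks(d2 / 10.0, FPS)
        assert len(e1) == len(e2) == 1
        assert e2[0].closing_start - e1[0].closing_start == k
        assert e2[0].reopening_end - e1[0].reopening_end == k

    def test_generator_log_is_recovered_at_moderate_drowsiness(self):
        """Mean per-phase error below one sample period on >= 100 blinks."""
        cfg = SyntheticConfig(duration_s=600)
        left, right, log = simulate_trace(np.full(cfg.n_samples, 0.5), cfg, seed=11)
        r = (
            normalize_trace(left, track_max_distance(left, FPS))
            + normalize_trace(right, track_max_distance(right, FPS))
        ) / 2.0
        events = segment_blinks(r, FPS)
        assert len(log) >= 100
        assert len(events) == len(log)
        errs = []
        for entry, ev in zip(log, sorted(events, key=lambda e: e.closing_start)):
            assert abs(ev.closing_start - entry["onset"]) <= 2
            errs.append(
                [
                    (ev.closing_end - ev.closing_start) - entry["n_closing"],
                    (ev.reopening_start - ev.closing_end) - entry["n_closed"],
                    (ev.reopening_end - ev.reopening_start) - entry["n_reopening"],
                ]
            )
        errs = np.abs(np.array(errs, dtype=float))
        assert np.all(errs.mean(axis=0) <= 1.0)


class TestWindowFeatures:
    def test_empty_window_yields_zero_durations_and_raw_perclos(self):
        r = np.ones(3000)
        f = window_features([], r, FPS, 30.0, 100.0)
        np.testing.assert_allclose(f[:5], 0.0)
        assert f[5] == 0.0

    def test_long_blink_counts_as_microsleep(self):
        ev = BlinkEvent(1000, 1003, 1018, 1021, fps=FPS)  # total 700 ms
        f = window_features([ev], np.ones(3000), FPS, 30.0, 60.0)
        assert f[4] == 1.0
        assert f[0] == pytest.approx(700.0, abs=1.0)

    def test_perclos_counts_fraction_of_closed_samples(self):
        r = np.ones(3000)
        start = 1800 - 900  # 30 s window ending at t = 60 s
        r[start : start + 270] = 0.1  # 30 % of the window below 0.3
        f = window_features([], r, FPS, 30.0, 60.0)
        assert f[5] == pytest.approx(0.30)


class TestFeatureVector:
    def test_vector_has_24_entries_window_major(self):
        rng = np.random.default_rng(0)
        d = 10.0 + rng.normal(0, 0.1, 3600)
        v = feature_vector(d, d, FPS, 90.0)
        assert v.shape == (24,)

    def test_requires_one_minute_of_history(self):
        d = np.full(3600, 10.0)
        with pytest.raises(ValueError):
            feature_vector(d, d, FPS, 59.0)

    def test_open_eye_trace_is_all_zero_features(self):
        d = np.full(3600, 10.0)
        np.testing.assert_allclose(feature_vector(d, d, FPS, 90.0), 0.0)

    def test_identical_eyes_equal_single_eye_computation(self):
        cfg = SyntheticConfig(duration_s=120)
        left, _, _ = simulate_trace(np.zeros(cfg.n_samples), cfg, seed=3)
        v2 = feature_vector(left, left, FPS, 100.0)
        r = normalize_trace(left, track_max_distance(left, FPS))
        blinks = segment_blinks(r, FPS)
        from vigileye.blink import FEATURE_WINDOWS_S

        v1 = np.concatenate([window_features(blinks, r, FPS, w, 100.0) for w in FEATURE_WINDOWS_S])
        np.testing.assert_allclose(v2, v1)

    def test_invariant_to_positive_rescaling_of_distances(self):
        cfg = SyntheticConfig(duration_s=120)
        left, right, _ = simulate_trace(np.full(cfg.n_samples, 0.3), cfg, seed=5)
        v1 = feature_vector(left, right, FPS, 100.0)
        v2 = feature_vector(2.0 * left, 2.0 * right, FPS, 100.0)
        np.testing.assert_allclose(v1, v2, rtol=1e-9)
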
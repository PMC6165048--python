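"""RT normalization, median RTs, labels, strata and validation weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigileye import (
    PVTSession,
    RTEvent,
    SyntheticConfig,
    assign_stratum,
    fit_normalization,
    label_probability,
    median_rt_m1,
    median_rt_window,
    normalize_rt,
    simulate_cohort,
    validation_weights,
)
from vigileye.ground_truth import (
    NormalizationModel,
    UndefinedRTError,
    compute_validation_frequencies,
    normalize_events,
)


def _session(subject, rts, times=None):
    times = times if times is not None else list(np.arange(len(rts)) * 5.0 + 5.0)
    trace_t = np.arange(0, 600 * 30) / 30.0
    zeros = np.ones_like(trace_t)
    return PVTSession(
        subject_id=subject, pvt_id="pvt0", trace_times=trace_t, left_dist=zeros,
        right_dist=zeros, rt_events=[RTEvent(t, x) for t, x in zip(times, rts)], tag="alert",
    )


class TestNormalization:
    def test_mu_is_mean_reciprocal_of_reference_rts(self):
        model = fit_normalization([_session("a", [250.0, 500.0])])
        assert model.mu_by_subject["a"] == pytest.approx(0.003, abs=1e-15)

    def test_population_mean_over_subjects(self):
        model = fit_normalization([_session("a", [500.0]), _session("b", [250.0])])
        assert model.mu_pop == pytest.approx(0.003, abs=1e-15)

    def test_subject_without_reference_is_excluded(self):
        model = fit_normalization([_session("a", [400.0]), _session("b", [])])
        assert "b" not in model and "a" in model

    def test_identity_when_subject_at_population_mean(self):
        model = NormalizationModel({"a": 0.0025}, 0.0025)
        for x in (100.0, 400.0, 900.0):
            assert normalize_rt(x, "a", model) == pytest.approx(x)

    def test_shifts_reciprocal_by_population_offset(self):
        model = NormalizationModel({"a": 0.0025}, 0.002)
        assert normalize_rt(500.0, "a", model) == pytest.approx(1 / 0.0015)

    def test_nonpositive_shifted_speed_is_undefined(self):
        model = NormalizationModel({"a": 0.01}, 0.001)
        with pytest.raises(UndefinedRTError):
            normalize_rt(1000.0, "a", model)

    def test_normalized_reference_speeds_average_to_population_mean(self):
        """The fixed point of the normalization, exact to machine precision."""
        sessions = [s for s in simulate_cohort(SyntheticConfig(n_subjects=6, seed=2)) if s.tag == "alert"]
        model = fit_normalization(sessions)
        for s in sessions:
            normalized = normalize_events(s, model)
            mean_speed = np.mean([1.0 / e.rt for e in normalized])
            assert mean_speed == pytest.approx(model.mu_pop, abs=1e-12)


class TestMedianRTs:
    def test_single_rt_inside_two_second_window(self):
        assert median_rt_m1(10.5, [RTEvent(10.0, 320.0)]) == 320.0

    def test_linear_interpolation_between_neighbours(self):
        events = [RTEvent(10.0, 300.0), RTEvent(20.0, 500.0)]
        assert median_rt_m1(15.0, events) == pytest.approx(400.0)

    def test_undefined_outside_event_support(self):
        events = [RTEvent(10.0, 300.0), RTEvent(20.0, 500.0)]
        assert median_rt_m1(5.0, events) is None
        assert median_rt_m1(25.0, events) is None
        assert median_rt_m1(10.0, []) is None

    def test_reciprocal_space_interpolation_switch(self):
        events = [RTEvent(10.0, 300.0), RTEvent(20.0, 600.0)]
        assert median_rt_m1(15.0, events) == pytest.approx(450.0)
        assert median_rt_m1(15.0, events, interpolate_reciprocal=True) == pytest.approx(400.0)

    def test_tie_prefers_earlier_event(self):
        events = [RTEvent(9.5, 111.0), RTEvent(10.5, 222.0)]
        assert median_rt_m1(10.0, events) == 111.0

    def test_harmonic_mean_of_window(self):
        events = [RTEvent(9.0, 400.0), RTEvent(11.0, 600.0)]
        assert median_rt_window(10.0, events, 15.0) == pytest.approx(480.0)

    def test_single_and_constant_windows(self):
        assert median_rt_window(10.0, [RTEvent(9.0, 450.0)], 15.0) == pytest.approx(450.0)
        events = [RTEvent(t, 500.0) for t in (1.0, 5.0, 9.0)]
        assert median_rt_window(10.0, events, 30.0) == pytest.approx(500.0)
        assert median_rt_window(100.0, events, 15.0) is None

    @given(st.lists(st.tuples(st.floats(0, 600), st.floats(100, 2000)), min_size=1, max_size=40),
           st.floats(0, 600), st.sampled_from([15.0, 30.0, 60.0]))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_loop(self, pairs, t, lookback):
        events = [RTEvent(a, b) for a, b in sorted(pairs)]
        # independent oracle: explicit loop and reciprocal accumulation
        acc, count = 0.0, 0
        for e in events:
            if t - lookback <= e.stimulus_time <= t + 5.0:
                acc += 1.0 / e.rt
                count += 1
        expected = None if count == 0 else count / acc
        got = median_rt_window(t, events, lookback)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, rel=1e-12)

    def test_window_nesting(self):
        rng = np.random.default_rng(0)
        events = [RTEvent(float(t), float(r)) for t, r in
                  zip(np.sort(rng.uniform(0, 600, 80)), rng.uniform(200, 900, 80))]
        for t in (100.0, 300.0, 500.0):
            sets = [
                {e.stimulus_time for e in events if t - lb <= e.stimulus_time <= t + 5.0}
                for lb in (15.0, 30.0, 60.0)
            ]
            assert sets[0] <= sets[1] <= sets[2]

    def test_harmonic_never_exceeds_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rts = rng.uniform(150, 1500, size=rng.integers(1, 10))
            events = [RTEvent(float(i), float(r)) for i, r in enumerate(rts)]
            hm = median_rt_window(0.0, events, 60.0)
            assert hm <= np.mean(rts) + 1e-9


class TestLabelsAndStrata:
    @pytest.mark.parametrize("m,expected", [(400.0, 0.0), (450.0, 0.5), (500.0, 1.0),
                                            (399.9, 0.0), (500.1, 1.0), (None, None)])
    def test_threshold_labels(self, m, expected):
        assert label_probability(m) == expected

    def test_label_probability_is_nondecreasing(self):
        grid = np.linspace(200, 800, 601)
        labels = [label_probability(m) for m in grid]
        assert all(a <= b for a, b in zip(labels, labels[1:]))

    @pytest.mark.parametrize("ms,expected", [
        ((300.0, 300.0, 300.0, 300.0), 0),
        ((480.0, 460.0, 470.0, 500.0), 3),
        ((600.0, 600.0, 600.0, 600.0), 4),
    ])
    def test_stratum_counts_medians_at_or_above_470(self, ms, expected):
        assert assign_stratum(ms) == expected

    def test_undefined_median_excludes_sample(self):
        assert assign_stratum((480.0, None, 470.0, 500.0)) is None


class TestValidationWeights:
    def test_half_reciprocal_of_frequency(self):
        np.testing.assert_allclose(validation_weights(0.5), 1.0)

    def test_degenerate_frequencies_rejected(self):
        for f in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                validation_weights(f)

    def test_frequencies_from_median_pool(self):
        m = np.array([[480, 480, 480, 480], [300, 300, 300, 480], [300, 480, 300, 300]])
        freqs = compute_validation_frequencies(m)
        np.testing.assert_allclose(freqs[:, 1], [1 / 3, 2 / 3, 1 / 3, 2 / 3], atol=1e-12)
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0)
        with pytest.raises(ValueError):
            compute_validation_frequencies(np.full((3, 4), 480.0))
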
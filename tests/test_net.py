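"""Attention pooling, the relative-entropy loss, epoch sampling, training."""

import itertools

import numpy as np
import pytest

from vigileye import (
    DrowsinessNet,
    NetConfig,
    SyntheticConfig,
    TrainConfig,
    augment_swap,
    drowsiness_loss,
    fit_normalization,
    make_epoch,
    sigmoid_pool_weights,
    simulate_cohort,
    train_fold,
)
from vigileye.net import sigmoid_pool
from vigileye.pipeline import build_samples


class TestSigmoidPooling:
    @pytest.mark.parametrize("n0", [5.0, 15.0, 30.0])
    def test_weights_are_normalized_and_monotone(self, n0):
        w = sigmoid_pool_weights(n0, slope=1.5)
        assert abs(w.sum() - 1.0) < 1e-9
        assert np.all(np.diff(w) >= -1e-15)

    def test_constant_sequence_is_a_fixed_point(self):
        v = np.full((3, 600), 4.2)
        for n0 in (5.0, 15.0, 30.0):
            np.testing.assert_allclose(sigmoid_pool(v, n0, slope=1.5), 4.2, rtol=1e-9)

    @pytest.mark.parametrize("n0", [5.0, 15.0, 30.0])
    def test_hard_slope_limit_is_the_windowed_mean(self, n0):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4, 600))
        hard = sigmoid_pool(v, n0, slope=1e3)
        k = int(10 * n0)
        brute = v[:, -k:].sum(axis=1) / k  # plain mean of the most recent k positions
        assert np.abs(hard - brute).max() < 1e-6

    def test_short_cutoff_ignores_the_distant_past(self):
        w = sigmoid_pool_weights(5.0, slope=1.5)
        assert w[:540].sum() < 0.02

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            sigmoid_pool(np.zeros((2, 599)), 5.0, slope=1.5)


class TestLoss:
    def test_zero_at_the_target_for_all_ternary_labels(self):
        for combo in itertools.product((0.0, 0.5, 1.0), repeat=4):
            p = np.array(combo)
            assert abs(drowsiness_loss(p, p)) < 1e-6

    def test_uniform_prediction_against_certain_alert_is_ln2(self):
        loss = drowsiness_loss(np.full(4, 0.5), np.zeros(4))
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)

    def test_matches_brute_force_evaluation(self):
        def brute(p_hat, p, w):
            total = 0.0
            for i in range(4):
                ph = min(max(p_hat[i], 1e-7), 1 - 1e-7)
                term = 0.0
                if p[i] > 0:
                    term += p[i] * np.log(ph / p[i])
                if p[i] < 1:
                    term += (1 - p[i]) * np.log((1 - ph) / (1 - p[i]))
                total += w[i] * term
            return -total / 4.0

        rng = np.random.default_rng(1)
        for combo in itertools.product((0.0, 0.5, 1.0), repeat=4):
            p = np.array(combo)
            p_hat = rng.uniform(0.01, 0.99, size=4)
            w = rng.uniform(0.5, 3.0, size=4)
            assert drowsiness_loss(p_hat, p, weights=w) == pytest.approx(
                brute(p_hat, p, w), abs=1e-12
            )

    def test_nonnegative_and_positive_away_from_target(self):
        rng = np.random.default_rng(2)
        for combo in itertools.product((0.0, 0.5, 1.0), repeat=4):
            p = np.array(combo)
            off = np.clip(p + rng.uniform(0.05, 0.2, 4) * np.where(p < 1, 1, -1), 0.01, 0.99)
            assert drowsiness_loss(off, p) > 0.0


class TestEpochSampling:
    def test_stratified_epoch_size_and_composition(self):
        pool = {s: list(range(s * 1000, s * 1000 + 7)) for s in range(5)}
        epoch = make_epoch(pool, 256, np.random.default_rng(0))
        assert len(epoch) == 1280
        for s in range(5):
            assert np.sum((epoch >= s * 1000) & (epoch < s * 1000 + 1000)) == 256

    def test_empty_stratum_is_a_configuration_error(self):
        pool = {s: [1, 2] for s in range(4)}  # stratum 4 missing
        with pytest.raises(ValueError, match="stratum 4"):
            make_epoch(pool, 8, np.random.default_rng(0))

    def test_seeded_reproducibility(self):
        pool = {s: list(range(10)) for s in range(5)}
        a = make_epoch(pool, 16, np.random.default_rng(5))
        b = make_epoch(pool, 16, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


def test_swap_augmentation_is_an_involution():
    x = np.random.default_rng(0).normal(size=(1800, 2))
    np.testing.assert_array_equal(augment_swap(augment_swap(x)), x)
    symmetric = np.repeat(x[:, :1], 2, axis=1)
    np.testing.assert_array_equal(augment_swap(symmetric), symmetric)


class TestArchitecture:
    def test_untrained_inference_is_deterministic(self):
        net = DrowsinessNet(NetConfig(width=4, head_width=4), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 1800, 2)).astype(np.float32)
        p1 = net.forward(x, train=False)
        p2 = net.forward(x, train=False)
        np.testing.assert_array_equal(p1, p2)
        assert p1.shape == (2, 4)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_head_receives_own_and_context_embeddings(self):
        net = DrowsinessNet(NetConfig(), seed=0)
        # final dense layer of each branch sees 16 own + 16 context features
        assert all(fc.w.value.shape == (2, 32) for fc in net.branch_fc2)

    def test_ablation_removes_context_and_doubles_the_head(self):
        full = DrowsinessNet(NetConfig(), seed=0)
        bare = DrowsinessNet(NetConfig(with_context=False), seed=0)
        assert full.context_parameter_count() > 0
        assert bare.context_parameter_count() == 0
        assert bare.branch_fc1[0].w.value.shape[0] == 2 * full.branch_fc1[0].w.value.shape[0]


@pytest.fixture(scope="module")
def tiny_samples():
    cohort = simulate_cohort(SyntheticConfig(n_subjects=4, seed=6))
    model = fit_normalization([s for s in cohort if s.tag == "alert"])
    by_key = build_samples(cohort, model, grid_step_s=5.0)
    train = [s for e in by_key.values() for s in e["grid"] if e["session"].subject_id in ("s00", "s01")]
    val = [s for e in by_key.values() for s in e["eval"] if e["session"].subject_id == "s02"]
    return train, val


class TestTrainFold:
    def test_subject_overlap_is_rejected(self, tiny_samples):
        train, _ = tiny_samples
        with pytest.raises(ValueError, match="overlap"):
            train_fold(train, train[:5])

    def test_same_seed_reproduces_the_training_run(self, tiny_samples):
        train, val = tiny_samples
        nc = NetConfig(width=2, head_width=2)
        tc = TrainConfig(stratum_quota=8, max_epochs=2, patience=5, seed=9, val_subsample=40)
        _, h1 = train_fold(train, val, nc, tc)
        _, h2 = train_fold(train, val, nc, tc)
        assert h1 == h2
        assert all(np.isfinite(row["val_loss"]) for row in h1)
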
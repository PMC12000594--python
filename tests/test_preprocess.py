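import itertools

import numpy as np
import pytest

from mscformer import (
    AugmentConfig,
    TrialSet,
    apply_standardizer,
    fit_standardizer,
    segment_reconstruct,
)
from mscformer.preprocess import StandardizerStats, segment_boundaries


def single_trial_ts(values):
    values = np.asarray(values, dtype=float)
    return TrialSet(
        signals=values.reshape(1, 1, -1),
        labels=np.zeros(1, dtype=int),
        fs=250,
        channel_names=["C1"],
        class_names=["a"],
    )


class TestStandardizer:
    def test_global_mean_and_population_sd(self):
        ts = single_trial_ts([1, 2, 3, 4])
        stats = fit_standardizer(ts, scope="global")
        assert stats.mu == pytest.approx(2.5)
        assert stats.sigma == pytest.approx(np.std([1, 2, 3, 4]))

    def test_constant_signal_raises_without_epsilon(self):
        ts = single_trial_ts([5, 5, 5, 5])
        with pytest.raises(ValueError, match="epsilon"):
            fit_standardizer(ts)
        stats = fit_standardizer(ts, epsilon=1e-8)
        assert stats.sigma > 0

    def test_train_fit_train_apply_gives_zero_mean_unit_sd(self, worked_fixture):
        stats = fit_standardizer(worked_fixture)
        out = apply_standardizer(stats, worked_fixture)
        assert abs(out.signals.mean()) < 1e-6
        assert abs(out.signals.std() - 1) < 1e-6
        # re-fitting on standardized data: mu ~ 0, sigma ~ 1
        stats2 = fit_standardizer(out)
        assert abs(float(stats2.mu)) < 1e-6
        assert abs(float(stats2.sigma) - 1) < 1e-6

    def test_identity_stats_leave_input_unchanged(self, worked_fixture):
        stats = StandardizerStats(mu=np.array(0.0), sigma=np.array(1.0), scope="global")
        out = apply_standardizer(stats, worked_fixture)
        np.testing.assert_array_equal(out.signals, worked_fixture.signals)

    def test_direct_arithmetic(self):
        ts = single_trial_ts([2, 4])
        stats = StandardizerStats(mu=np.array(2.0), sigma=np.array(2.0), scope="global")
        np.testing.assert_allclose(
            apply_standardizer(stats, ts).signals.ravel(), [0, 1]
        )

    def test_per_channel_scope(self):
        sig = np.stack([[np.array([1.0, 3.0]), np.array([10.0, 30.0])]])  # (1, 2, 2)
        ts = TrialSet(sig, np.zeros(1, dtype=int), 250, ["C1", "C2"], ["a"])
        stats = fit_standardizer(ts, scope="per_channel")
        np.testing.assert_allclose(stats.mu, [2.0, 20.0])
        out = apply_standardizer(stats, ts)
        np.testing.assert_allclose(out.signals.mean(axis=(0, 2)), [0, 0], atol=1e-12)

    def test_channel_mismatch_rejected(self):
        stats = StandardizerStats(
            mu=np.zeros(3), sigma=np.ones(3), scope="per_channel"
        )
        with pytest.raises(ValueError, match="channels"):
            apply_standardizer(stats, single_trial_ts([1, 2]))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            StandardizerStats(mu=np.array(0.0), sigma=np.array(0.0), scope="global")


class TestSegmentBoundaries:
    def test_partition_covers_range_with_near_equal_sizes(self):
        bounds = segment_boundaries(16, 3)
        assert bounds[0][0] == 0 and bounds[-1][1] == 16
        sizes = [hi - lo for lo, hi in bounds]
        assert max(sizes) - min(sizes) <= 1
        # first (T mod Ns) segments carry the extra sample
        assert sizes == [6, 5, 5]

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            segment_boundaries(4, 5)


class TestSegmentReconstruct:
    def test_segments_trace_to_same_class_donors(self, worked_fixture):
        cfg = AugmentConfig(n_segments=3, n_augmented=40, seed=7)
        aug = segment_reconstruct(worked_fixture, cfg)
        assert aug.n_trials == 40
        bounds = segment_boundaries(worked_fixture.n_samples, 3)
        for i in range(aug.n_trials):
            donors_cls = set()
            for lo, hi in bounds:
                seg = aug.signals[i, :, lo:hi]
                matches = [
                    j
                    for j in range(worked_fixture.n_trials)
                    if np.array_equal(seg, worked_fixture.signals[j, :, lo:hi])
                ]
                assert matches, "augmented segment not found verbatim in any donor"
                donors_cls.update(worked_fixture.labels[j] for j in matches)
            assert donors_cls == {aug.labels[i]}

    def test_single_segment_copies_an_original(self, worked_fixture):
        aug = segment_reconstruct(
            worked_fixture, AugmentConfig(n_segments=1, n_augmented=10, seed=3)
        )
        for i in range(10):
            cls_idx = np.flatnonzero(worked_fixture.labels == aug.labels[i])
            assert any(
                np.array_equal(aug.signals[i], worked_fixture.signals[j])
                for j in cls_idx
            )

    def test_two_donor_enumeration_all_recombinations_appear(self):
        # 2 trials of one class, Ns=2: exactly 4 possible artificial trials
        sig = np.zeros((2, 1, 4))
        sig[0] = [[0, 1, 2, 3]]
        sig[1] = [[10, 11, 12, 13]]
        ts = TrialSet(sig, np.zeros(2, dtype=int), 250, ["C1"], ["a"])
        expected = {
            (0.0, 1.0, 2.0, 3.0),
            (0.0, 1.0, 12.0, 13.0),
            (10.0, 11.0, 2.0, 3.0),
            (10.0, 11.0, 12.0, 13.0),
        }
        aug = segment_reconstruct(
            ts, AugmentConfig(n_segments=2, n_augmented=200, seed=0)
        )
        seen = {tuple(aug.signals[i, 0]) for i in range(aug.n_trials)}
        assert seen <= expected
        assert seen == expected  # all four appear given enough draws

    def test_missing_class_named_in_error(self):
        sig = np.zeros((2, 1, 4))
        ts = TrialSet(sig, np.zeros(2, dtype=int), 250, ["C1"], ["a", "b"])
        with pytest.raises(ValueError, match="class 1"):
            segment_reconstruct(ts, AugmentConfig(n_segments=2, n_augmented=4))

    def test_seed_determinism(self, worked_fixture):
        cfg = AugmentConfig(n_segments=4, n_augmented=16, seed=5)
        a = segment_reconstruct(worked_fixture, cfg)
        b = segment_reconstruct(worked_fixture, cfg)
        np.testing.assert_array_equal(a.signals, b.signals)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = segment_reconstruct(
            worked_fixture, AugmentConfig(n_segments=4, n_augmented=16, seed=6)
        )
        assert not np.array_equal(a.signals, c.signals)

    def test_commutes_with_fixed_standardization(self, worked_fixture):
        stats = StandardizerStats(mu=np.array(3.0), sigma=np.array(2.0), scope="global")
        cfg = AugmentConfig(n_segments=4, n_augmented=12, seed=9)
        a = apply_standardizer(stats, segment_reconstruct(worked_fixture, cfg))
        b = segment_reconstruct(apply_standardizer(stats, worked_fixture), cfg)
        np.testing.assert_allclose(a.signals, b.signals)

    def test_default_n_augmented_doubles_the_data(self, worked_fixture):
        aug = segment_reconstruct(worked_fixture, AugmentConfig(seed=1))
        assert aug.n_trials == worked_fixture.n_trials
        assert all(tag == "augmented" for tag in aug.provenance)
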
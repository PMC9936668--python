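"""Pulse-train construction and the factorial design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vnsim.patterns import (
    Condition,
    PulseTrain,
    TrialProtocol,
    enumerate_design,
    make_burst_train,
    make_constant_train,
    make_duty50_train,
    make_random_train,
    pattern_stats,
)


class TestConstantTrain:
    @pytest.mark.parametrize(
        "freq, window, n_expected",
        [(20.0, 30.0, 600), (2.0, 30.0, 60), (100.0, 30.0, 3000)],
    )
    def test_count(self, freq, window, n_expected):
        train = make_constant_train(freq, window)
        assert train.n_pulses == n_expected

    def test_uniform_spacing(self):
        train = make_constant_train(20.0, 30.0)
        assert np.allclose(np.diff(train.onsets), 0.05)

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError):
            make_constant_train(2000.0, 30.0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            make_constant_train(0.0, 30.0)


class TestBurstTrain:
    def test_epoch_structure(self):
        train = make_burst_train(40.0, 10, 30.0)
        assert train.n_pulses == 300
        first_epoch = train.onsets[train.onsets < 1.0]
        assert np.allclose(first_epoch, np.arange(10) * 0.025)

    def test_degenerate_burst_equals_constant(self):
        burst = make_burst_train(20.0, 20, 30.0)
        const = make_constant_train(20.0, 30.0)
        assert np.array_equal(burst.onsets, const.onsets)

    def test_100hz_50mpr(self):
        train = make_burst_train(100.0, 50, 30.0)
        assert train.n_pulses == 1500
        epoch = train.onsets[train.onsets < 1.0]
        assert epoch[-1] == pytest.approx(0.49)

    def test_mpr_above_frequency_rejected(self):
        with pytest.raises(ValueError):
            make_burst_train(10.0, 20, 30.0)


class TestRandomTrain:
    def test_tiling(self):
        train = make_random_train(10, seed=5, window=2.0)
        epoch1 = train.onsets[:10]
        epoch2 = train.onsets[10:]
        assert np.allclose(epoch2, epoch1 + 1.0)

    def test_count(self):
        assert make_random_train(20, seed=1, window=30.0).n_pulses == 600

    def test_seed_reproducibility(self):
        a = make_random_train(10, seed=3)
        b = make_random_train(10, seed=3)
        c = make_random_train(10, seed=4)
        assert np.array_equal(a.onsets, b.onsets)
        assert not np.array_equal(a.onsets, c.onsets)

    def test_min_ipi_enforced(self):
        for seed in range(30):
            train = make_random_train(20, seed=seed, window=2.0)
            assert np.diff(train.onsets).min() >= 1e-3 - 1e-12

    def test_mean_ipf_at_least_mpr(self):
        # arithmetic mean of 1/IPI >= harmonic mean = pulse rate
        for seed in range(50):
            train = make_random_train(10, seed=seed, window=30.0)
            assert pattern_stats(train)["mean_ipf"] >= 10.0 - 1e-9


class TestDuty50:
    def test_compressed_first_half(self):
        train = make_duty50_train(20, 30.0)
        epoch = train.onsets[train.onsets < 1.0]
        assert epoch.size == 20
        assert epoch.max() < 0.5
        assert np.allclose(np.diff(epoch), 0.025)


class TestDesign:
    def test_pattern_and_condition_counts(self):
        conditions = enumerate_design()
        assert len(conditions) == 108
        patterns = {
            (c.intra_burst_frequency, c.mean_pulse_rate) for c in conditions
        }
        assert len(patterns) == 36
        constant = [c for c in conditions if c.pattern_kind == "constant"]
        assert len(constant) == 24  # 8 frequencies x 3 amplitudes

    def test_small_grid_enumeration(self):
        conditions = enumerate_design(rate_grid=(10.0, 20.0), amplitudes=(1.0,))
        labels = {
            (c.intra_burst_frequency, c.mean_pulse_rate, c.pattern_kind)
            for c in conditions
        }
        assert labels == {
            (10.0, 10.0, "constant"),
            (20.0, 20.0, "constant"),
            (20.0, 10.0, "burst"),
        }

    def test_duplicate_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_design(rate_grid=(10.0, 10.0, 20.0))

    @pytest.mark.parametrize("n_rates", [2, 4, 8])
    def test_size_formula(self, n_rates):
        rates = tuple(2.0 * (k + 1) for k in range(n_rates))
        conditions = enumerate_design(rate_grid=rates, amplitudes=(0.8, 1.0))
        assert len(conditions) == 2 * (n_rates + n_rates * (n_rates - 1) // 2)

    def test_every_epoch_has_mpr_pulses(self, full_design):
        from vnsim.patterns import train_for_condition

        seen = set()
        for cond in full_design:
            key = (cond.intra_burst_frequency, cond.mean_pulse_rate)
            if key in seen:
                continue
            seen.add(key)
            train = train_for_condition(cond, 30.0)
            for epoch in range(30):
                n = np.count_nonzero(
                    (train.onsets >= epoch) & (train.onsets < epoch + 1)
                )
                assert n == cond.mean_pulse_rate


class TestPatternStats:
    def test_constant_train(self):
        stats = pattern_stats(make_constant_train(20.0, 30.0))
        assert stats["mean_ipf"] == pytest.approx(20.0)
        assert stats["geom_mean_ipf"] == pytest.approx(20.0)

    def test_hand_computed_ipis(self):
        train = PulseTrain(np.array([0.0, 0.025, 0.125]))
        stats = pattern_stats(train)
        assert stats["mean_ipf"] == pytest.approx(25.0)  # (40 + 10) / 2
        assert stats["geom_mean_ipf"] == pytest.approx(20.0)  # sqrt(40 * 10)

    def test_single_pulse_rejected(self):
        with pytest.raises(ValueError):
            pattern_stats(PulseTrain(np.array([0.0])))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_am_gm_inequality(self, seed):
        train = make_random_train(10, seed=seed, window=5.0)
        stats = pattern_stats(train)
        assert stats["geom_mean_ipf"] <= stats["mean_ipf"] + 1e-9


class TestInvariantsAndProtocol:
    def test_protocol_windows(self):
        proto = TrialProtocol()
        assert proto.total_s == 70.0
        assert proto.stim_window == (10.0, 40.0)
        assert proto.hr_analysis_window == (15.0, 40.0)

    def test_pulse_train_rejects_decreasing_onsets(self):
        with pytest.raises(ValueError):
            PulseTrain(np.array([0.0, 0.2, 0.1]))

    def test_condition_validation(self):
        with pytest.raises(ValueError):
            Condition(
                amplitude=1.0,
                intra_burst_frequency=10.0,
                mean_pulse_rate=20.0,
            )
        with pytest.raises(ValueError):
            Condition(
                amplitude=1.0,
                intra_burst_frequency=20.0,
                mean_pulse_rate=10.0,
                pattern_kind="constant",
            )
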
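"""Vagus-to-ICNS synaptic gate and ACh release kinetics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from vnsim.hr.ach import AChParams, ach_impulse_response, simulate_ach
from vnsim.hr.ganglion import (
    mean_success_fraction,
    simulate_icns,
    success_probability,
    transmission_fraction,
)
from vnsim.patterns import make_constant_train


class TestSuccessProbability:
    def test_printed_formula_on_dense_grid(self):
        dt = np.linspace(0.5, 1000.0, 4001)
        oracle = np.minimum(
            1.0, np.maximum(0.0, 1.028 - 2.183 * dt ** (-0.7146))
        )
        assert np.array_equal(success_probability(dt), oracle)

    def test_point_values(self):
        assert success_probability(10.0) == pytest.approx(0.607, abs=5e-4)
        assert success_probability(2.0) == 0.0
        assert success_probability(500.0) == 1.0

    def test_clamp_boundaries_by_root_finding(self):
        raw = lambda dt: 1.028 - 2.183 * dt ** (-0.7146)
        lower = brentq(raw, 1.0, 10.0)
        upper = brentq(lambda dt: raw(dt) - 1.0, 100.0, 1000.0)
        assert lower == pytest.approx(2.87, abs=0.01)
        assert upper == pytest.approx(444.0, abs=1.0)
        assert success_probability(lower * 0.99) == 0.0
        assert success_probability(upper * 1.01) == 1.0
        assert 0 < success_probability((lower + upper) / 2) < 1

    def test_non_decreasing(self):
        dt = np.linspace(0.5, 600.0, 2000)
        assert np.all(np.diff(success_probability(dt)) >= 0)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            success_probability(0.0)


class TestTransmissionFraction:
    def test_slow_trains_fully_transmitted(self):
        # at 2 Hz the recovery interval is 500 ms where p clamps to 1
        assert transmission_fraction(500.0) == pytest.approx(1.0)

    def test_matches_monte_carlo(self):
        # independent oracle: brute-force Markov simulation of the gate
        rng = np.random.default_rng(0)
        for ipi in (10.0, 25.0, 50.0):
            t0 = -1e9
            transmitted = 0
            n = 200_000
            for k in range(n):
                t = k * ipi
                if rng.random() < success_probability(t - t0):
                    transmitted += 1
                    t0 = t
            assert transmission_fraction(ipi) == pytest.approx(
                transmitted / n, rel=0.02
            )

    def test_decreasing_in_rate(self):
        ipis = [5.0, 10.0, 20.0, 50.0, 100.0, 500.0]
        fracs = [transmission_fraction(ipi) for ipi in ipis]
        assert np.all(np.diff(fracs) > 0)  # longer IPI, higher fidelity


class TestSimulateICNS:
    def test_transmitted_rate_bounded_by_pulse_rate(self, make_constant_condition):
        train = make_constant_train(50.0, 10.0)
        events = simulate_icns(train, 10.0, seed=1, intrinsic=False)
        assert events.transmitted_fraction() <= 1.0
        assert events.transmitted_fraction() == pytest.approx(
            transmission_fraction(20.0), abs=0.05
        )

    def test_2hz_fully_transmitted(self):
        train = make_constant_train(2.0, 10.0)
        events = simulate_icns(train, 10.0, seed=2, intrinsic=False)
        assert events.transmitted_fraction() == pytest.approx(1.0)

    def test_filtering_knockout_transmits_everything(self):
        train = make_constant_train(100.0, 5.0)
        events = simulate_icns(train, 5.0, seed=3, filtering=False)
        assert all(len(e) == train.n_pulses for e in events.evoked)

    def test_seed_reproducibility_and_structure(self):
        train = make_constant_train(20.0, 5.0)
        a = simulate_icns(train, 5.0, seed=7)
        b = simulate_icns(train, 5.0, seed=7)
        assert a.intrinsic_cells.tolist() == b.intrinsic_cells.tolist()
        assert len(a.intrinsic_cells) == 50
        assert a.n_cells == 100
        for ea, eb in zip(a.evoked, b.evoked):
            assert np.array_equal(ea, eb)

    def test_intrinsic_rate_in_range(self):
        events = simulate_icns(None, 30.0, seed=4)
        counts = [len(events.intrinsic[c]) for c in events.intrinsic_cells]
        mean_rate = np.mean(counts) / 30.0
        # half-sine profile peaking at 0.6/50 ms bin -> mean (2/pi)*12 Hz
        assert 0.5 * 7.64 < mean_rate < 1.5 * 7.64
        non_intrinsic = set(range(100)) - set(events.intrinsic_cells)
        assert all(len(events.intrinsic[c]) == 0 for c in non_intrinsic)


class TestACh:
    def test_no_events_zero_trace(self):
        trace = simulate_ach([np.empty(0)], AChParams(), 1.0)
        assert not np.any(trace)

    def test_single_event_matches_closed_form(self):
        params = AChParams()
        trace = simulate_ach([np.array([0.0])], params, 2.0, dt_s=1e-3)
        t = np.arange(2000) * 1e-3
        expected = ach_impulse_response(t, params)
        assert np.allclose(trace[:, 0], expected, atol=1e-6 * expected.max())

    def test_exchange_off_single_exponential(self):
        # with no release low-pass and no exchange the junction decays
        # as a single exponential exp(-k_H t)
        params = AChParams(
            k_release=1e6, k_junction_to_extra=0.0, k_extra_to_junction=0.0,
            k_hydrolysis=14.0,
        )
        t = np.linspace(0.01, 0.3, 50)
        resp = ach_impulse_response(t, params)
        expected = params.release_mm * np.exp(-14.0 * t)
        assert np.allclose(resp, expected, rtol=1e-4)

    def test_higher_rate_more_ach(self):
        params = AChParams()
        fast = simulate_ach([np.arange(0, 10, 0.1)], params, 12.0)
        slow = simulate_ach([np.arange(0, 10, 0.5)], params, 12.0)
        assert fast[2000:10000].mean() > slow[2000:10000].mean()

    def test_superposition(self):
        params = AChParams()
        a = simulate_ach([np.array([0.5])], params, 4.0)
        b = simulate_ach([np.array([1.5])], params, 4.0)
        both = simulate_ach([np.array([0.5, 1.5])], params, 4.0)
        assert np.allclose(both, a + b, atol=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            AChParams(k_hydrolysis=-1.0)
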
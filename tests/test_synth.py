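"""Synthetic trial generator: ground truth, determinism, fatigue, vagotomy."""

import numpy as np
import pytest

from vnsim.patterns import Condition, TrialProtocol
from vnsim.synth import (
    EMGConfig,
    ResponseSurface,
    generate_cohort,
    generate_random_session,
    generate_trial,
)


def _const(freq, amplitude=1.0):
    return Condition(
        amplitude=amplitude,
        intra_burst_frequency=float(freq),
        mean_pulse_rate=float(freq),
    )


class TestResponseSurface:
    def test_monotone_in_mpr_and_amplitude(self):
        surface = ResponseSurface()
        from vnsim.patterns import train_for_condition

        targets = {}
        for amp in (0.8, 1.0, 1.2):
            for mpr in (5.0, 20.0, 50.0):
                cond = _const(mpr, amp)
                train = train_for_condition(cond, 30.0)
                targets[(amp, mpr)] = surface.hr_norm_target(cond, train)
        for amp in (0.8, 1.0, 1.2):
            col = [targets[(amp, m)] for m in (5.0, 20.0, 50.0)]
            assert np.all(np.diff(col) < 0)
        for mpr in (5.0, 20.0, 50.0):
            row = [targets[(a, mpr)] for a in (0.8, 1.0, 1.2)]
            assert np.all(np.diff(row) < 0)

    def test_higher_intra_burst_frequency_weakens_response(self):
        from vnsim.patterns import train_for_condition

        surface = ResponseSurface()
        vals = []
        for freq in (20.0, 50.0, 100.0):
            cond = Condition(
                amplitude=1.0, intra_burst_frequency=freq,
                mean_pulse_rate=20.0,
                pattern_kind="constant" if freq == 20.0 else "burst",
            )
            train = train_for_condition(cond, 30.0)
            vals.append(surface.hr_norm_target(cond, train))
        assert np.all(np.diff(vals) > 0)  # HR_norm rises toward 1

    def test_invalid_surface_rejected(self):
        with pytest.raises(ValueError):
            ResponseSurface(amp_gains=((0.8, 0.4), (1.0, 0.2), (1.2, 0.1)))


class TestGenerateTrial:
    def test_zero_amplitude_no_effect(self):
        cond = Condition(
            amplitude=0.0, intra_burst_frequency=20.0, mean_pulse_rate=20.0
        )
        rec, truth = generate_trial(cond, noise_sd=0.0, seed=0)
        assert truth.target_hr_norm == 1.0
        assert np.all(truth.per_pulse_emg_amplitude == 0)

    def test_vagotomy_abolishes_responses(self):
        rec, truth = generate_trial(
            _const(20.0), noise_sd=0.0, seed=1, vagotomized=True
        )
        assert truth.target_hr_norm == 1.0
        assert np.all(truth.per_pulse_emg_amplitude == 0)
        # EMG contains only the artifact: nothing in the evoked window
        i0 = int(round((rec.trigger_times[0] + 1.2e-3) * rec.fs))
        i1 = int(round((rec.trigger_times[0] + 6e-3) * rec.fs))
        assert np.max(np.abs(rec.emg[i0:i1])) < 1e-9

    def test_deterministic_beats_without_rsa(self):
        surface = ResponseSurface(rsa_depth=0.0, baseline_bpm=450.0)
        cond = Condition(
            amplitude=0.0, intra_burst_frequency=20.0, mean_pulse_rate=20.0
        )
        rec, truth = generate_trial(cond, surface, noise_sd=0.0, seed=2)
        from vnsim.quant import detect_beats

        beats = detect_beats(rec.ecg, rec.fs)
        rr = np.diff(beats)
        # beat placement is quantised to the generator's 1 ms rate grid
        assert np.allclose(rr, 60.0 / 450.0, atol=1.1e-3)
        assert abs(rr.mean() - 60.0 / 450.0) < 1e-5

    def test_seed_reproducibility(self):
        a = generate_trial(_const(20.0), noise_sd=0.05, seed=3)[0]
        b = generate_trial(_const(20.0), noise_sd=0.05, seed=3)[0]
        assert np.array_equal(a.ecg, b.ecg)
        assert np.array_equal(a.emg, b.emg)

    def test_channel_lengths_and_triggers(self):
        rec, _ = generate_trial(_const(20.0), noise_sd=0.0, seed=4)
        assert rec.ecg.size == 70 * 5000
        assert rec.emg.size == 70 * 5000
        assert rec.trigger_times.size == 600
        assert rec.trigger_times[0] == pytest.approx(10.0)

    def test_fatigue_decline_at_100hz(self):
        _, truth = generate_trial(_const(100.0), noise_sd=0.0, seed=5)
        amp = truth.per_pulse_emg_amplitude
        # amplitudes decline toward a depletion equilibrium: strictly at
        # first, then saturating at the fatigued floor
        assert np.all(np.diff(amp[:200]) < 0)
        assert np.all(np.diff(amp) < 1e-9)
        assert amp[-1] < 0.75 * amp[0]


class TestCohort:
    def test_counts_and_order_permutation(self, short_protocol):
        design = [_const(f) for f in (5.0, 20.0)]
        cohort = generate_cohort(
            3, design, seed=1, noise_sd=0.0, protocol=short_protocol
        )
        assert len(cohort) == 6
        orders = cohort.manifest.groupby("animal")["mean_pulse_rate"].apply(list)
        assert len(orders) == 3

    def test_same_seed_identical(self, short_protocol):
        design = [_const(20.0)]
        a = generate_cohort(2, design, seed=9, protocol=short_protocol)
        b = generate_cohort(2, design, seed=9, protocol=short_protocol)
        ra, rb = a.trial(0)[0], b.trial(0)[0]
        assert np.array_equal(ra.ecg, rb.ecg)

    def test_zero_animal_sigma_identical_truth(self, short_protocol):
        design = [_const(20.0)]
        cohort = generate_cohort(
            3, design, seed=2, protocol=short_protocol,
            animal_gain_sigma=0.0, animal_emg_sigma=0.0,
        )
        truths = [t.target_hr_norm for _, t in cohort.trials()]
        assert len(set(truths)) == 1

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, [], seed=0)


class TestRandomSession:
    def test_structure(self, short_protocol):
        session = generate_random_session(10, seed=1, protocol=short_protocol)
        kinds = [rec.condition.pattern_kind for rec, _ in session]
        assert kinds == ["constant", "random", "constant"]
        for rec, _ in session:
            assert rec.condition.amplitude == 1.0
            epoch = rec.trigger_times[
                rec.trigger_times < short_protocol.baseline_s + 1.0
            ]
            assert epoch.size == 10

    def test_invalid_mpr_rejected(self):
        with pytest.raises(ValueError):
            generate_random_session(15, seed=0)
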
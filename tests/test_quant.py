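"""Signal quantification: beat detection, HR metrics, artifact removal,
EMG quantification, effect score."""

import numpy as np
import pytest

from vnsim.patterns import Condition, TrialProtocol
from vnsim.quant import (
    InvalidTrialError,
    detect_beats,
    effect_score,
    emg_quantify,
    hr_metrics,
    normalize_emg,
    quantify_trial,
    subtract_artifact,
)
from vnsim.synth import generate_trial


def _const(freq, amplitude=1.0):
    return Condition(
        amplitude=amplitude,
        intra_burst_frequency=float(freq),
        mean_pulse_rate=float(freq),
    )


class TestDetectBeats:
    def test_round_trip_on_noiseless_ecg(self):
        rec, truth = generate_trial(_const(20.0), noise_sd=0.0, seed=1)
        beats = detect_beats(rec.ecg, rec.fs)
        # compare against the generator's beat count and spacing
        expected_n = int(np.round(truth.hr_trajectory.mean() / 60 * 70))
        assert abs(beats.size - expected_n) <= 2

    def test_flat_signal_no_beats(self):
        assert detect_beats(np.zeros(5000)).size == 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            detect_beats(np.array([0.0, np.nan, 1.0]))

    def test_noise_robustness(self):
        # SNR ~ 10: all true beats recovered, no false positives
        missed = false_pos = 0
        for seed in range(10):
            rec, _ = generate_trial(_const(20.0), noise_sd=0.1, seed=seed)
            clean, _ = generate_trial(_const(20.0), noise_sd=0.0, seed=seed)
            true_beats = detect_beats(clean.ecg, clean.fs)
            beats = detect_beats(rec.ecg, rec.fs)
            d = np.abs(true_beats[:, None] - beats[None, :])
            matched = (d.min(axis=1) < 5e-3).sum()
            missed += true_beats.size - matched
            false_pos += beats.size - matched
        assert missed <= 0.01 * 10 * 500
        assert false_pos == 0


class TestHRMetrics:
    def test_constant_rr(self):
        beats = np.arange(0.0, 70.0, 0.15)
        hr_b, hr_s, hr_n, series = hr_metrics(beats)
        assert hr_b == pytest.approx(400.0)
        assert hr_s == pytest.approx(400.0)
        assert hr_n == pytest.approx(1.0)

    def test_stim_slowing_hand_computed(self):
        # 150 ms RR at baseline, 187.5 ms during stimulation: 400 -> 320
        proto = TrialProtocol()
        beats = list(np.arange(0.0, 10.05, 0.15))
        t = beats[-1] + 0.1875
        while t < 40.0:
            beats.append(t)
            t += 0.1875
        while t < 70.0:
            beats.append(t)
            t += 0.15
        hr_b, hr_s, hr_n, _ = hr_metrics(np.array(beats), proto)
        # windows spanning the transitions blur the estimate slightly
        assert hr_b == pytest.approx(400.0, rel=5e-3)
        assert hr_s == pytest.approx(320.0, rel=5e-3)
        assert hr_n == pytest.approx(0.8, rel=5e-3)

    def test_too_few_beats_flagged(self):
        with pytest.raises(InvalidTrialError):
            hr_metrics(np.array([1.0]))


class TestArtifactSubtraction:
    def test_identical_artifacts_removed_exactly(self):
        fs = 5000.0
        emg = np.zeros(5000)
        artifact = np.array([1.0, -0.5, 0.2, 0.1, 0.0])
        triggers = np.array([0.1, 0.3, 0.5])
        for t in triggers:
            i = int(t * fs)
            emg[i : i + 5] += artifact
        cleaned = subtract_artifact(emg, triggers, fs)
        assert np.allclose(cleaned, 0.0, atol=1e-12)

    def test_evoked_wave_untouched(self):
        fs = 5000.0
        emg = np.zeros(5000)
        triggers = np.array([0.1, 0.3])
        for t in triggers:
            i = int((t + 2e-3) * fs)  # outside the [-1, +1] ms template
            emg[i : i + 10] += 0.7
        cleaned = subtract_artifact(emg, triggers, fs)
        assert np.allclose(cleaned, emg)

    def test_jittered_artifact_reduced(self):
        rng = np.random.default_rng(0)
        fs = 5000.0
        emg = np.zeros(50000)
        artifact = np.array([2.0, -1.0, 0.5, 0.0, 0.0])
        triggers = np.arange(0.1, 9.0, 0.05)
        for t in triggers:
            i = int(round(t * fs))
            emg[i : i + 5] += artifact * rng.uniform(0.5, 1.5)
        cleaned = subtract_artifact(emg, triggers, fs)
        assert np.sqrt(np.mean(cleaned**2)) <= 0.5 * np.sqrt(np.mean(emg**2))

    def test_idempotent_on_own_output(self):
        rec, _ = generate_trial(_const(20.0), noise_sd=0.0, seed=2)
        once = subtract_artifact(rec.emg, rec.trigger_times, rec.fs)
        twice = subtract_artifact(once, rec.trigger_times, rec.fs)
        assert np.allclose(once, twice, atol=1e-12)

    def test_no_triggers_rejected(self):
        with pytest.raises(ValueError):
            subtract_artifact(np.zeros(100), np.array([]))


class TestEMGQuantify:
    def test_rectangular_wave_arv(self):
        fs = 5000.0
        emg = np.zeros(1000)
        trigger = 0.02
        i0 = int((trigger + 1e-3) * fs)
        i1 = int((trigger + 6e-3) * fs)
        emg[i0:i1] = -0.8  # rectified
        arv, total = emg_quantify(emg, np.array([trigger]), fs)
        assert arv[0] == pytest.approx(0.8)
        assert total == pytest.approx(0.8)

    def test_zero_signal(self):
        arv, total = emg_quantify(np.zeros(1000), np.array([0.05]), 5000.0)
        assert total == 0.0

    def test_sum_linearity(self):
        fs = 5000.0
        n_pulses = 40
        emg = np.zeros(int(fs * 3))
        triggers = (250 + np.arange(n_pulses) * 250) / fs  # sample-aligned
        for t in triggers:
            i0 = int(round((t + 1e-3) * fs))
            emg[i0 : i0 + 25] = 0.3
        arv, total = emg_quantify(emg, triggers, fs)
        assert total == pytest.approx(n_pulses * arv[0])

    def test_window_bounds_validated(self):
        with pytest.raises(ValueError):
            emg_quantify(np.zeros(100), np.array([0.0]), 5000.0, window_ms=(1.0, 9.0))


class TestScores:
    def test_normalize_reference_is_one(self):
        assert normalize_emg(3.2, 3.2) == 1.0
        assert normalize_emg(0.0, 3.2) == 0.0
        assert normalize_emg(6.4, 3.2) == 2.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_emg(1.0, 0.0)

    def test_reference_condition_scores_zero(self):
        assert effect_score(0.84, 0.84, 1.0) == 0.0

    def test_no_effect_scores_zero(self):
        assert effect_score(1.0, 0.84, 0.0) == 0.0

    def test_hand_computed(self):
        assert effect_score(0.68, 0.84, 1.0) == pytest.approx(1.0)

    def test_reference_without_bradycardia_rejected(self):
        with pytest.raises(ValueError):
            effect_score(0.9, 1.0, 1.0)

    def test_monotone_in_arguments(self):
        base = effect_score(0.8, 0.84, 1.0)
        assert effect_score(0.7, 0.84, 1.0) > base  # deeper bradycardia
        assert effect_score(0.8, 0.84, 1.5) < base  # more muscle response


class TestTrialRoundTrip:
    @pytest.mark.parametrize("freq, amp", [(20.0, 1.0), (50.0, 1.2), (5.0, 0.8)])
    def test_noiseless_recovery(self, freq, amp):
        rec, truth = generate_trial(_const(freq, amp), noise_sd=0.0, seed=11)
        q = quantify_trial(rec)
        assert q.hr_norm == pytest.approx(truth.target_hr_norm, rel=0.01)
        assert q.emg_sum == pytest.approx(truth.target_emg_sum, rel=0.02)
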
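"""Synthetic trial recordings with known ground truth.

Generates the two-channel 5 kHz recordings (ECG + laryngeal EMG) the
analysis pipeline consumes, for 70 s trials (10 s baseline, 30 s VNS,
30 s recovery).  The heart-rate response to a stimulation condition is
drawn from a configurable ground-truth response surface

    HR_norm(amp, mpr, f) = 1 - A(amp) * S(mpr_eff),   S(x) = x / (x + m50)

where ``mpr_eff`` is the mean pulse rate attenuated by the ganglionic
transmission fraction at the intra-burst inter-pulse interval -- so the
surface reproduces the qualitative in vivo trends: deeper bradycardia
with higher amplitude and MPR, shallower with higher intra-burst
frequency at fixed MPR.  Baseline heart rate sits in the anesthetised-
mouse range (450 BPM default) with respiration-linked variability
(~60 breaths/min).

Evoked EMG waves follow each pulse (1.5-6 ms post-trigger) on top of a
0-1 ms stimulus artifact, with amplitude set by a logistic recruitment
curve in units of bradycardia threshold and a high-rate fatigue decline.
A vagotomy switch abolishes both the HR response and the evoked EMG,
leaving only artifact and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .hr.ganglion import mean_success_fraction, transmission_fraction
from .patterns import (
    Condition,
    PulseTrain,
    TrialProtocol,
    make_constant_train,
    make_random_train,
    train_for_condition,
)

__all__ = [
    "ResponseSurface",
    "EMGConfig",
    "GroundTruth",
    "TrialRecording",
    "Cohort",
    "generate_trial",
    "generate_cohort",
    "generate_random_session",
]

FS_HZ = 5000.0


@dataclass(frozen=True)
class ResponseSurface:
    """Ground-truth heart-rate response surface of the generator.

    ``amp_gains`` maps amplitude (xBCT) to the saturating bradycardia
    gain A; gains at other amplitudes are linearly interpolated through
    (0, 0).  ``m50`` is the half-saturation mean pulse rate.
    """

    amp_gains: tuple = ((0.8, 0.10), (1.0, 0.25), (1.2, 0.45))
    m50: float = 20.0
    baseline_bpm: float = 450.0
    rsa_depth: float = 0.03
    rsa_rate_bpm: float = 60.0
    transient_tau_s: float = 1.0

    def __post_init__(self):
        amps = [a for a, _ in self.amp_gains]
        gains = [g for _, g in self.amp_gains]
        if sorted(amps) != list(amps):
            raise ValueError("amp_gains must be sorted by amplitude")
        if any(g < 0 or g > 1 for g in gains):
            raise ValueError("gains must lie in [0, 1]")
        if np.any(np.diff([0.0] + gains) < 0):
            raise ValueError(
                "gains must be non-decreasing in amplitude "
                "(monotone response surface)"
            )
        if self.m50 <= 0 or self.baseline_bpm <= 0:
            raise ValueError("m50 and baseline must be positive")

    def gain(self, amplitude: float) -> float:
        """Bradycardia gain A at an amplitude, linear through (0, 0)."""
        amps = np.array([0.0] + [a for a, _ in self.amp_gains])
        gains = np.array([0.0] + [g for _, g in self.amp_gains])
        return float(np.interp(amplitude, amps, gains))

    def scaled(self, gain_factor: float) -> "ResponseSurface":
        new = tuple(
            (a, min(g * gain_factor, 1.0)) for a, g in self.amp_gains
        )
        return replace(self, amp_gains=new)

    def hr_norm_target(self, condition: Condition, train: PulseTrain) -> float:
        """Ground-truth HR_norm for a condition.

        The effective drive is MPR times the ganglionic transmission
        fraction: at the intra-burst IPI for regular patterns, or the
        Monte-Carlo mean over the realised train for random patterns.
        """
        if condition.amplitude == 0:
            return 1.0
        if condition.pattern_kind == "random":
            frac = mean_success_fraction(
                train.onsets - train.onsets[0], seed=condition.seed or 0
            )
        else:
            frac = transmission_fraction(1e3 / condition.intra_burst_frequency)
        mpr_eff = condition.mean_pulse_rate * frac
        return 1.0 - self.gain(condition.amplitude) * mpr_eff / (
            mpr_eff + self.m50
        )


@dataclass(frozen=True)
class EMGConfig:
    """Evoked-EMG and artifact conventions of the generator.

    The analysis windows constrain the shapes: the artifact occupies
    0-1 ms post-trigger (inside the subtraction template), the evoked
    wave 1.5-6 ms (inside the quantification window).  Recruitment is
    logistic in units of bradycardia threshold with onset near 0.4xBCT
    and near-saturation by 0.8xBCT.  Fatigue scales successive evoked
    amplitudes down under sustained high-rate stimulation and recovers
    between bursts.
    """

    artifact_mv: float = 2.0
    evoked_mv: float = 1.0
    evoked_start_ms: float = 1.5
    evoked_end_ms: float = 6.0
    recruit_center: float = 0.6
    recruit_scale: float = 0.07
    fatigue_floor: float = 0.3
    fatigue_scale: float = 30.0
    fatigue_recovery_s: float = 0.3

    def recruitment(self, amplitude: float) -> float:
        if amplitude <= 0:
            return 0.0
        z = (amplitude - self.recruit_center) / self.recruit_scale
        return float(1.0 / (1.0 + np.exp(-z)))

    def fatigue_factors(self, onsets: np.ndarray) -> np.ndarray:
        """Per-pulse amplitude factor from a depletion state that grows by
        one per pulse and decays exponentially between pulses."""
        factors = np.empty(onsets.size)
        d = 0.0
        last = None
        for i, t in enumerate(onsets):
            if last is not None:
                d *= np.exp(-(t - last) / self.fatigue_recovery_s)
            factors[i] = self.fatigue_floor + (1 - self.fatigue_floor) * np.exp(
                -d / self.fatigue_scale
            )
            d += 1.0
            last = t
        return factors


@dataclass
class GroundTruth:
    """What the generator actually put into a trial."""

    hr_trajectory: np.ndarray  # BPM on a 1 ms grid
    per_pulse_emg_amplitude: np.ndarray  # mV
    artifact_template: np.ndarray
    target_hr_norm: float
    target_emg_sum: float  # expected summed EMG_arv, mV
    vagotomized: bool


@dataclass
class TrialRecording:
    """Synthetic 5 kHz two-channel trial recording."""

    ecg: np.ndarray
    emg: np.ndarray
    trigger_times: np.ndarray
    condition: Condition
    protocol: TrialProtocol
    animal_id: str = "SIM0"
    fs: float = FS_HZ


def _qrs_template(fs: float) -> np.ndarray:
    """8 ms biphasic QRS-like wavelet, unit positive peak at its centre."""
    n = int(round(8e-3 * fs))
    t = (np.arange(n) - n // 2) / fs * 1e3  # ms around the peak
    wave = np.exp(-((t / 1.0) ** 2) / 2) - 0.45 * np.exp(
        -(((t - 2.2) / 1.2) ** 2) / 2
    )
    return wave / wave.max()


def _artifact_template(fs: float, amplitude_mv: float) -> np.ndarray:
    """Biphasic stimulus artifact, 0-1 ms post-trigger."""
    n = int(round(1e-3 * fs))
    t = np.arange(n) / fs * 1e3
    wave = np.where(t < 0.3, 1.0, np.where(t < 0.6, -1.0, 0.0)) * np.exp(
        -t / 0.6
    )
    return amplitude_mv * wave


def _evoked_template(fs: float, cfg: EMGConfig) -> np.ndarray:
    """Unit-amplitude biphasic evoked EMG wave on the post-trigger grid
    (zero before ``evoked_start_ms``)."""
    n = int(round(cfg.evoked_end_ms * 1e-3 * fs))
    t = np.arange(n) / fs * 1e3
    dur = cfg.evoked_end_ms - cfg.evoked_start_ms
    phase = (t - cfg.evoked_start_ms) / dur
    active = (phase >= 0) & (phase < 1)
    wave = np.zeros(n)
    wave[active] = np.sin(2 * np.pi * phase[active]) * np.sin(
        np.pi * phase[active]
    )
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def _bandlimited_noise(rng, n, fs, sd):
    if sd <= 0:
        return np.zeros(n)
    white = rng.normal(0.0, sd, size=n)
    b, a = butter(4, [10.0, 1000.0], btype="bandpass", fs=fs)
    return filtfilt(b, a, white)


def generate_trial(
    condition: Condition,
    surface: ResponseSurface | None = None,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    protocol: TrialProtocol | None = None,
    emg_config: EMGConfig | None = None,
    vagotomized: bool = False,
    emg_scale: float = 1.0,
    animal_id: str = "SIM0",
    fs: float = FS_HZ,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic trial and its ground truth.

    The ECG places a QRS wavelet at beat times from an
    integrate-to-threshold process driven by the heart-rate trajectory
    (baseline x respiratory modulation x response, with an exponential
    transient at stimulation on/offset).  The EMG superimposes, per
    pulse, the stimulus artifact and an evoked wave whose amplitude is
    recruitment(amplitude) x fatigue.  Fully reproducible from ``seed``.
    """
    surface = surface or ResponseSurface()
    protocol = protocol or TrialProtocol()
    cfg = emg_config or EMGConfig()
    rng = np.random.default_rng(seed)
    n = int(round(protocol.total_s * fs))

    train = train_for_condition(condition, protocol.stim_s, start=protocol.baseline_s)
    target = (
        1.0 if vagotomized else surface.hr_norm_target(condition, train)
    )

    # --- heart-rate trajectory on a 1 ms grid ---
    grid = np.arange(0.0, protocol.total_s, 1e-3)
    t_on, t_off = protocol.stim_window
    tau = surface.transient_tau_s
    response = np.ones_like(grid)
    during = (grid >= t_on) & (grid < t_off)
    response[during] = target + (1 - target) * np.exp(
        -(grid[during] - t_on) / tau
    )
    after = grid >= t_off
    level_off = target + (1 - target) * np.exp(-(t_off - t_on) / tau)
    response[after] = 1.0 + (level_off - 1.0) * np.exp(
        -(grid[after] - t_off) / tau
    )
    rsa = 1.0 + surface.rsa_depth * np.sin(
        2 * np.pi * (surface.rsa_rate_bpm / 60.0) * grid
    )
    hr_bpm = surface.baseline_bpm * rsa * response

    # --- integrate-to-threshold beat times ---
    phase = np.cumsum(hr_bpm / 60.0) * 1e-3
    beat_count = np.floor(phase)
    beat_idx = np.nonzero(np.diff(beat_count) > 0)[0] + 1
    beat_times = grid[beat_idx]

    ecg = np.zeros(n)
    qrs = _qrs_template(fs)
    half = len(qrs) // 2
    for bt in beat_times:
        i = int(round(bt * fs)) - half
        j0, j1 = max(i, 0), min(i + len(qrs), n)
        ecg[j0:j1] += qrs[j0 - i : j1 - i]

    # --- EMG: artifact + evoked waves per pulse ---
    emg = np.zeros(n)
    artifact = _artifact_template(fs, cfg.artifact_mv * condition.amplitude)
    evoked_shape = _evoked_template(fs, cfg)
    onsets = train.onsets
    if vagotomized:
        per_pulse = np.zeros(onsets.size)
    else:
        per_pulse = (
            cfg.evoked_mv
            * emg_scale
            * cfg.recruitment(condition.amplitude)
            * cfg.fatigue_factors(onsets)
        )
    for amp_i, t0 in zip(per_pulse, onsets):
        i = int(round(t0 * fs))
        j1 = min(i + len(artifact), n)
        emg[i:j1] += artifact[: j1 - i]
        j1 = min(i + len(evoked_shape), n)
        emg[i:j1] += amp_i * evoked_shape[: j1 - i]

    ecg += _bandlimited_noise(rng, n, fs, noise_sd)
    emg += _bandlimited_noise(rng, n, fs, noise_sd)

    # expected summed EMG_arv over the standard [1, 6] ms window
    w0, w1 = int(round(1e-3 * fs)), int(round(6e-3 * fs))
    shape_arv = float(np.mean(np.abs(evoked_shape[w0:w1])))
    truth = GroundTruth(
        hr_trajectory=hr_bpm,
        per_pulse_emg_amplitude=per_pulse,
        artifact_template=artifact,
        target_hr_norm=target,
        target_emg_sum=float(np.sum(per_pulse) * shape_arv),
        vagotomized=vagotomized,
    )
    rec = TrialRecording(
        ecg=ecg,
        emg=emg,
        trigger_times=onsets,
        condition=condition,
        protocol=protocol,
        animal_id=animal_id,
        fs=fs,
    )
    return rec, truth


@dataclass
class Cohort:
    """Lazily generated multi-animal synthetic dataset.

    Trials are synthesised on demand from per-trial seeds, so a full
    cohort (e.g. 10 animals x 108 conditions of 70 s two-channel data)
    never needs to be held in memory at once.  ``manifest`` lists every
    trial; ``trials()`` yields (recording, ground truth) pairs in
    manifest order.
    """

    manifest: pd.DataFrame
    surface: ResponseSurface
    noise_sd: float
    protocol: TrialProtocol
    emg_config: EMGConfig
    animal_surfaces: dict
    animal_emg_scales: dict
    vagotomized: bool = False

    def __len__(self):
        return len(self.manifest)

    def trial(self, index: int):
        row = self.manifest.iloc[index]
        condition = Condition(
            amplitude=row["amplitude"],
            intra_burst_frequency=row["intra_burst_frequency"],
            mean_pulse_rate=row["mean_pulse_rate"],
            pattern_kind=row["pattern_kind"],
            seed=None if pd.isna(row["pattern_seed"]) else int(row["pattern_seed"]),
        )
        return generate_trial(
            condition,
            self.animal_surfaces[row["animal"]],
            noise_sd=self.noise_sd,
            seed=int(row["trial_seed"]),
            protocol=self.protocol,
            emg_config=self.emg_config,
            emg_scale=self.animal_emg_scales[row["animal"]],
            vagotomized=self.vagotomized,
            animal_id=row["animal"],
        )

    def trials(self):
        for i in range(len(self)):
            yield self.trial(i)

    def to_hdf5(self, path):
        """Write the cohort to HDF5, one group per trial."""
        import h5py

        with h5py.File(path, "w") as f:
            for i, (rec, truth) in enumerate(self.trials()):
                g = f.create_group(f"trial_{i:04d}")
                g.create_dataset("ecg", data=rec.ecg, compression="gzip")
                g.create_dataset("emg", data=rec.emg, compression="gzip")
                g.create_dataset("triggers", data=rec.trigger_times)
                g.attrs.update(
                    {
                        "animal": rec.animal_id,
                        "amplitude": rec.condition.amplitude,
                        "intra_burst_frequency": rec.condition.intra_burst_frequency,
                        "mean_pulse_rate": rec.condition.mean_pulse_rate,
                        "pattern_kind": rec.condition.pattern_kind,
                        "target_hr_norm": truth.target_hr_norm,
                        "target_emg_sum": truth.target_emg_sum,
                        "vagotomized": truth.vagotomized,
                    }
                )


def generate_cohort(
    n_animals: int,
    design: list[Condition],
    seed: int = 0,
    *,
    surface: ResponseSurface | None = None,
    noise_sd: float = 0.02,
    protocol: TrialProtocol | None = None,
    emg_config: EMGConfig | None = None,
    animal_gain_sigma: float = 0.10,
    animal_emg_sigma: float = 0.20,
    vagotomized: bool = False,
) -> Cohort:
    """Build a randomised-block cohort over a condition design.

    Each animal receives every condition once, in a per-animal random
    order, with log-normal per-animal jitter of the surface gains and
    EMG scale creating an "animal" factor (sigma 0 makes all animals
    identical).  Same seed, same dataset.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if not design:
        raise ValueError("design must contain at least one condition")
    surface = surface or ResponseSurface()
    protocol = protocol or TrialProtocol()
    emg_config = emg_config or EMGConfig()

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    animal_surfaces = {}
    animal_emg_scales = {}
    trial_seed = iter(ss.spawn(n_animals * len(design)))
    for a in range(n_animals):
        animal = f"SIM{a:02d}"
        gain_factor = float(np.exp(rng.normal(0.0, animal_gain_sigma)))
        animal_surfaces[animal] = surface.scaled(gain_factor)
        animal_emg_scales[animal] = float(
            np.exp(rng.normal(0.0, animal_emg_sigma))
        )
        order = rng.permutation(len(design))
        for block_pos, k in enumerate(order):
            cond = design[k]
            rows.append(
                {
                    "animal": animal,
                    "block_position": block_pos,
                    "amplitude": cond.amplitude,
                    "intra_burst_frequency": cond.intra_burst_frequency,
                    "mean_pulse_rate": cond.mean_pulse_rate,
                    "pattern_kind": cond.pattern_kind,
                    "pattern_seed": cond.seed,
                    "trial_seed": next(trial_seed).generate_state(1)[0] % (2**31),
                }
            )
    manifest = pd.DataFrame(rows)
    return Cohort(
        manifest=manifest,
        surface=surface,
        noise_sd=noise_sd,
        protocol=protocol,
        emg_config=emg_config,
        animal_surfaces=animal_surfaces,
        animal_emg_scales=animal_emg_scales,
        vagotomized=vagotomized,
    )


def generate_random_session(
    mpr: int,
    seed: int = 0,
    *,
    surface: ResponseSurface | None = None,
    noise_sd: float = 0.0,
    protocol: TrialProtocol | None = None,
    emg_config: EMGConfig | None = None,
):
    """One random-pattern session: constant (C1), random (R), constant (C2).

    All three trials run at 1.0xBCT with the given mean pulse rate; the
    random trial tiles one randomised 1 s epoch.  Returns three
    (recording, ground truth) pairs.
    """
    if mpr not in (10, 20):
        raise ValueError("sessions use MPR of 10 or 20 pulses/s")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    const = Condition(
        amplitude=1.0,
        intra_burst_frequency=float(mpr),
        mean_pulse_rate=float(mpr),
        pattern_kind="constant",
    )
    rand = Condition(
        amplitude=1.0,
        intra_burst_frequency=float(mpr),
        mean_pulse_rate=float(mpr),
        pattern_kind="random",
        seed=seeds[3],
    )
    out = []
    for cond, s in zip((const, rand, const), seeds[:3]):
        out.append(
            generate_trial(
                cond,
                surface,
                noise_sd=noise_sd,
                seed=s,
                protocol=protocol,
                emg_config=emg_config,
            )
        )
    return out
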
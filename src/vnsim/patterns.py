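"""Stimulation pulse-train construction and the factorial parameter design.

Pulse trains are symmetric biphasic charge-balanced pulses (300 us per
phase) described only by their onset times and amplitude; waveform shape
is handled by the consumers (synthetic EMG generation, fiber models).
Temporal patterns repeat in concatenated 1 s epochs: a constant-frequency
train delivers pulses at uniform spacing, a burst train compresses the
epoch's pulses to the intra-burst interval at the start of each epoch, and
a random train places them uniformly at random within one epoch and tiles
that epoch for the stimulation window.  The mean pulse rate (MPR) is the
number of pulses per 1 s epoch; it equals the frequency for constant
stimulation and the pulses-per-burst for burst patterns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PulseTrain",
    "Condition",
    "TrialProtocol",
    "EPOCH_S",
    "DEFAULT_RATE_GRID",
    "DEFAULT_AMPLITUDES",
    "BCT_MEDIAN_MA",
    "make_constant_train",
    "make_burst_train",
    "make_random_train",
    "make_duty50_train",
    "train_for_condition",
    "enumerate_design",
    "pattern_stats",
]

#: Duration of one repeating pattern epoch, seconds.
EPOCH_S = 1.0

#: Default rate grid (Hz) spanning the tested constant frequencies.
DEFAULT_RATE_GRID = (2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0)

#: Default stimulation amplitudes in multiples of bradycardia threshold.
DEFAULT_AMPLITUDES = (0.8, 1.0, 1.2)

#: Median bradycardia threshold current (mA); recorded metadata only.
BCT_MEDIAN_MA = 0.12


@dataclass(frozen=True)
class PulseTrain:
    """Timed biphasic stimulation pulses.

    Parameters
    ----------
    onsets : ndarray
        Pulse onset times in seconds from trial start, strictly increasing.
    phase_width : float
        Duration of each phase of the biphasic pulse, seconds.
    amplitude : float
        Stimulation amplitude as a multiple of bradycardia threshold (BCT).
    amplitude_ma : float or None
        Optional absolute amplitude in mA (metadata).
    polarity : str
        ``"cathode-leading"`` or ``"anode-leading"``.
    """

    onsets: np.ndarray
    phase_width: float = 300e-6
    amplitude: float = 1.0
    amplitude_ma: float | None = None
    polarity: str = "cathode-leading"

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.polarity not in ("cathode-leading", "anode-leading"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.phase_width <= 0:
            raise ValueError("phase_width must be positive")
        if onsets.ndim != 1:
            raise ValueError("onsets must be one-dimensional")
        if onsets.size >= 2:
            ipi = np.diff(onsets)
            if np.any(ipi <= 0):
                raise ValueError("pulse onsets must be strictly increasing")
            if np.any(ipi < 2 * self.phase_width):
                raise ValueError(
                    "inter-pulse interval shorter than the biphasic pulse "
                    f"(min IPI {ipi.min() * 1e3:.3f} ms < "
                    f"{2 * self.phase_width * 1e3:.3f} ms)"
                )

    @property
    def n_pulses(self) -> int:
        return int(self.onsets.size)

    def shifted(self, offset_s: float) -> "PulseTrain":
        """Return a copy with all onsets shifted by ``offset_s`` seconds."""
        return replace(self, onsets=self.onsets + offset_s)


@dataclass(frozen=True)
class Condition:
    """One cell of the stimulation parameter design.

    ``mean_pulse_rate`` (MPR) is pulses per 1 s epoch.  For constant
    patterns MPR equals ``intra_burst_frequency``.
    """

    amplitude: float
    intra_burst_frequency: float
    mean_pulse_rate: float
    pattern_kind: str = "constant"
    seed: int | None = None

    def __post_init__(self):
        if self.pattern_kind not in ("constant", "burst", "random", "duty50"):
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")
        if self.mean_pulse_rate > self.intra_burst_frequency:
            raise ValueError("MPR cannot exceed the intra-burst frequency")
        if self.pattern_kind == "constant" and (
            self.mean_pulse_rate != self.intra_burst_frequency
        ):
            raise ValueError("constant patterns require MPR == frequency")
        if self.pattern_kind == "random" and self.seed is None:
            raise ValueError("random patterns require a seed")

    @property
    def label(self) -> str:
        return (
            f"{self.amplitude:g}xBCT/"
            f"{self.intra_burst_frequency:g}Hz/"
            f"{self.mean_pulse_rate:g}pps/{self.pattern_kind}"
        )


@dataclass(frozen=True)
class TrialProtocol:
    """Trial timing: baseline, stimulation, recovery windows.

    The default 70 s trial has stimulation over [10, 40) s; heart rate
    during stimulation is analysed from ``analysis_start_offset_s`` after
    stimulation onset to exclude the transient.
    """

    baseline_s: float = 10.0
    stim_s: float = 30.0
    recovery_s: float = 30.0
    analysis_start_offset_s: float = 5.0

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stim_s + self.recovery_s

    @property
    def stim_window(self) -> tuple[float, float]:
        return (self.baseline_s, self.baseline_s + self.stim_s)

    @property
    def hr_analysis_window(self) -> tuple[float, float]:
        return (
            self.baseline_s + self.analysis_start_offset_s,
            self.baseline_s + self.stim_s,
        )


def _check_frequency(frequency: float, phase_width: float) -> None:
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if 1.0 / frequency < 2 * phase_width:
        raise ValueError(
            f"{frequency:g} Hz: inter-pulse interval shorter than the "
            "biphasic pulse duration"
        )


def make_constant_train(
    frequency: float,
    window: float = 30.0,
    *,
    start: float = 0.0,
    amplitude: float = 1.0,
    phase_width: float = 300e-6,
) -> PulseTrain:
    """Uniformly spaced pulses at ``frequency`` Hz over ``window`` seconds.

    The first pulse falls at the window onset; the count is
    ``floor(frequency * window)``.
    """
    _check_frequency(frequency, phase_width)
    n = int(np.floor(frequency * window))
    onsets = start + np.arange(n) / frequency
    return PulseTrain(onsets, phase_width=phase_width, amplitude=amplitude)


def make_burst_train(
    intra_burst_frequency: float,
    mpr: float,
    window: float = 30.0,
    *,
    start: float = 0.0,
    amplitude: float = 1.0,
    phase_width: float = 300e-6,
) -> PulseTrain:
    """Burst pattern: ``mpr`` pulses at the intra-burst interval at the
    start of each 1 s epoch, then silence to the epoch end.

    Degenerates to :func:`make_constant_train` when ``mpr`` equals the
    intra-burst frequency.
    """
    _check_frequency(intra_burst_frequency, phase_width)
    n_per_epoch = int(round(mpr))
    if n_per_epoch != mpr or n_per_epoch < 1:
        raise ValueError("mpr must be a positive integer pulse count")
    if mpr > intra_burst_frequency:
        raise ValueError("mpr > intra_burst_frequency is not a valid burst")
    burst = np.arange(n_per_epoch) / intra_burst_frequency
    if burst[-1] >= EPOCH_S:
        raise ValueError("burst does not fit within the 1 s epoch")
    n_epochs = int(np.floor(window / EPOCH_S))
    onsets = (burst[None, :] + EPOCH_S * np.arange(n_epochs)[:, None]).ravel()
    return PulseTrain(onsets + start, phase_width=phase_width, amplitude=amplitude)


def make_random_train(
    mpr: int,
    seed: int,
    window: float = 30.0,
    *,
    start: float = 0.0,
    amplitude: float = 1.0,
    phase_width: float = 300e-6,
    min_ipi: float = 1e-3,
) -> PulseTrain:
    """Random pattern: one 1 s epoch with ``mpr`` uniformly random onsets
    (minimum inter-pulse interval ``min_ipi``), tiled for the window.

    The same epoch content repeats in every epoch, so the realised pattern
    is reproducible from the seed and periodic with period 1 s.  A minimum
    IPI of 1 ms (> the 0.6 ms pulse) is enforced by rejection sampling,
    including across the epoch boundary.
    """
    mpr = int(mpr)
    if mpr < 1:
        raise ValueError("mpr must be >= 1")
    if mpr * min_ipi >= EPOCH_S:
        raise ValueError("mpr too high for the minimum inter-pulse interval")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        epoch = np.sort(rng.uniform(0.0, EPOCH_S, size=mpr))
        gaps = np.diff(epoch)
        wrap_gap = (EPOCH_S - epoch[-1]) + epoch[0] if mpr > 1 else EPOCH_S
        if mpr == 1 or (np.all(gaps >= min_ipi) and wrap_gap >= min_ipi):
            break
    else:  # pragma: no cover - astronomically unlikely at design MPRs
        raise RuntimeError("rejection sampling failed to satisfy min IPI")
    n_epochs = int(np.floor(window / EPOCH_S))
    onsets = (epoch[None, :] + EPOCH_S * np.arange(n_epochs)[:, None]).ravel()
    return PulseTrain(onsets + start, phase_width=phase_width, amplitude=amplitude)


def make_duty50_train(
    mpr: float,
    window: float = 30.0,
    *,
    start: float = 0.0,
    amplitude: float = 1.0,
    phase_width: float = 300e-6,
) -> PulseTrain:
    """50% duty-cycle pattern: the epoch's ``mpr`` pulses compressed into
    the first 0.5 s (spacing ``0.5/mpr`` s), then a 0.5 s pause."""
    n_per_epoch = int(round(mpr))
    if n_per_epoch < 1:
        raise ValueError("mpr must be >= 1")
    burst = np.arange(n_per_epoch) * (0.5 / n_per_epoch)
    n_epochs = int(np.floor(window / EPOCH_S))
    onsets = (burst[None, :] + EPOCH_S * np.arange(n_epochs)[:, None]).ravel()
    return PulseTrain(onsets + start, phase_width=phase_width, amplitude=amplitude)


def train_for_condition(
    condition: Condition,
    window: float = 30.0,
    *,
    start: float = 0.0,
    phase_width: float = 300e-6,
) -> PulseTrain:
    """Build the pulse train described by a :class:`Condition`."""
    kind = condition.pattern_kind
    if kind == "constant":
        return make_constant_train(
            condition.intra_burst_frequency, window, start=start,
            amplitude=condition.amplitude, phase_width=phase_width,
        )
    if kind == "burst":
        return make_burst_train(
            condition.intra_burst_frequency, condition.mean_pulse_rate,
            window, start=start, amplitude=condition.amplitude,
            phase_width=phase_width,
        )
    if kind == "random":
        return make_random_train(
            int(condition.mean_pulse_rate), condition.seed, window,
            start=start, amplitude=condition.amplitude,
            phase_width=phase_width,
        )
    return make_duty50_train(
        condition.mean_pulse_rate, window, start=start,
        amplitude=condition.amplitude, phase_width=phase_width,
    )


def enumerate_design(
    rate_grid=DEFAULT_RATE_GRID,
    amplitudes=DEFAULT_AMPLITUDES,
) -> list[Condition]:
    """Enumerate the factorial design: every (intra-burst frequency, MPR)
    pair with MPR <= frequency, crossed with the amplitudes.

    With the default 8-value grid this yields 8 constant + 28 burst = 36
    temporal patterns, 108 conditions across 3 amplitudes.
    """
    rates = [float(r) for r in rate_grid]
    amps = [float(a) for a in amplitudes]
    if len(set(rates)) != len(rates):
        raise ValueError("duplicate values in rate_grid")
    if len(set(amps)) != len(amps):
        raise ValueError("duplicate values in amplitudes")
    conditions = []
    for amp, freq, mpr in itertools.product(amps, sorted(rates), sorted(rates)):
        if mpr > freq:
            continue
        kind = "constant" if mpr == freq else "burst"
        conditions.append(
            Condition(
                amplitude=amp,
                intra_burst_frequency=freq,
                mean_pulse_rate=mpr,
                pattern_kind=kind,
            )
        )
    return conditions


def pattern_stats(train: PulseTrain) -> dict[str, float]:
    """Arithmetic and geometric mean inter-pulse frequency of a train.

    Both statistics are means of the reciprocals of successive
    inter-pulse intervals; the geometric mean never exceeds the arithmetic
    mean (AM-GM), with equality only for uniform spacing.
    """
    if train.n_pulses < 2:
        raise ValueError("pattern statistics require at least 2 pulses")
    ipf = 1.0 / np.diff(train.onsets)
    return {
        "mean_ipf": float(np.mean(ipf)),
        "geom_mean_ipf": float(np.exp(np.mean(np.log(ipf)))),
    }
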
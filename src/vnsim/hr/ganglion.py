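"""Frequency-dependent synaptic filtering at the vagus-to-ICNS synapse.

Each pre-ganglionic vagal efferent synapses onto one post-ganglionic cell
of the intrinsic cardiac nervous system (ICNS).  Transmission is
unreliable at short intervals: the probability that a vagal action
potential triggers post-ganglionic ACh release recovers with the time
since the last post-ganglionic event ``dt`` (ms) as::

    p(dt) = clamp(1.028 - 2.183 * dt**(-0.7146), 0, 1)

so pulses arriving < ~2.87 ms after an event always fail and pulses
arriving > ~444 ms later always succeed.  Half of the 100 ICNS cells also
fire intrinsically, phase-locked to respiration, at 0 to 0.6 events per
50 ms bin; intrinsic events release ACh and reset the same recovery clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..patterns import PulseTrain

__all__ = [
    "success_probability",
    "transmission_fraction",
    "mean_success_fraction",
    "intrinsic_rate_profile",
    "ICNSEvents",
    "simulate_icns",
]

_A = 1.028
_B = 2.183
_C = 0.7146

#: Width of the intrinsic-firing probability bin, ms.
INTRINSIC_BIN_MS = 50.0

#: Peak intrinsic rate, events per 50 ms bin.
INTRINSIC_PEAK = 0.6

#: Respiratory cycle period for the phasic intrinsic profile, seconds.
RESPIRATORY_PERIOD_S = 1.0


def success_probability(dt_ms):
    """Transmission probability as a function of the recovery interval.

    Parameters
    ----------
    dt_ms : float or ndarray
        Time since the last post-ganglionic event, milliseconds (> 0).

    Returns
    -------
    float or ndarray
        ``1.028 - 2.183 * dt**(-0.7146)`` clamped to [0, 1].
    """
    dt = np.asarray(dt_ms, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("recovery interval must be positive")
    p = np.clip(_A - _B * dt ** (-_C), 0.0, 1.0)
    return float(p) if np.isscalar(dt_ms) else p


def transmission_fraction(ipi_ms: float, tol: float = 1e-12) -> float:
    """Steady-state fraction of pulses transmitted for a constant-interval
    train.

    For uniform pulses every ``ipi_ms`` the recovery interval at a pulse
    is always an integer multiple of the IPI, so the gate is a renewal
    chain.  The expected number of pulses per transmitted event is
    ``M = sum_k k q_k prod_{j<k}(1 - q_j)`` with ``q_k = p(k * ipi)``; the
    transmitted fraction is ``1 / M``.
    """
    if ipi_ms <= 0:
        raise ValueError("inter-pulse interval must be positive")
    mean_pulses = 0.0
    survival = 1.0
    k = 0
    while survival > tol:
        k += 1
        q = success_probability(k * ipi_ms)
        mean_pulses += k * q * survival
        survival *= 1.0 - q
        if k > 10_000_000:  # pragma: no cover
            break
    if mean_pulses == 0.0:
        return 0.0
    return 1.0 / mean_pulses


def mean_success_fraction(
    onsets_s: np.ndarray, n_cells: int = 200, seed: int = 0
) -> float:
    """Monte-Carlo mean transmitted fraction for an arbitrary pulse train.

    Runs ``n_cells`` independent synaptic gates over the train and returns
    the mean fraction of pulses transmitted.  Used to evaluate the
    effective drive of irregular (random-pattern) trains.
    """
    onsets_ms = np.asarray(onsets_s, dtype=float) * 1e3
    if onsets_ms.size == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    t0 = np.full(n_cells, -1e9)
    transmitted = 0
    for t in onsets_ms:
        p = success_probability(np.maximum(t - t0, 1e-9))
        succ = rng.random(n_cells) < p
        transmitted += int(succ.sum())
        t0[succ] = t
    return transmitted / (onsets_ms.size * n_cells)


def intrinsic_rate_profile(t_s):
    """Phasic intrinsic ICNS rate, events per 50 ms bin, at time ``t_s``.

    A half-sine over each respiratory cycle peaking at 0.6 events/bin.
    """
    phase = np.mod(np.asarray(t_s, dtype=float), RESPIRATORY_PERIOD_S)
    return INTRINSIC_PEAK * np.sin(np.pi * phase / RESPIRATORY_PERIOD_S)


@dataclass
class ICNSEvents:
    """Per-cell post-ganglionic ACh release event times (seconds).

    ``evoked[i]`` are the VNS-evoked release times of cell ``i``;
    ``intrinsic[i]`` its intrinsic release times (empty for
    non-intrinsic cells).  ``intrinsic_cells`` lists the 50 cells with
    intrinsic firing.
    """

    evoked: list
    intrinsic: list
    intrinsic_cells: np.ndarray
    n_pulses: int

    @property
    def n_cells(self) -> int:
        return len(self.evoked)

    def transmitted_fraction(self) -> float:
        """Mean fraction of stimulus pulses that evoked ACh release."""
        if self.n_pulses == 0:
            return float("nan")
        counts = [len(e) for e in self.evoked]
        return float(np.mean(counts) / self.n_pulses)


def simulate_icns(
    train: PulseTrain | None,
    duration_s: float,
    *,
    filtering: bool = True,
    intrinsic: bool = True,
    seed: int = 0,
    n_cells: int = 100,
    n_intrinsic: int = 50,
) -> ICNSEvents:
    """Simulate post-ganglionic ACh release events for all ICNS cells.

    Every cell receives the shared pre-synaptic pulse train.  At each
    pulse, cell ``i`` releases ACh with probability
    ``success_probability(t - t0_i)`` where ``t0_i`` is the cell's last
    post-ganglionic event (stimulus-evoked or intrinsic).  With
    ``filtering=False`` every pulse releases ACh in every cell (the
    ganglionic-filtering knockout).  Intrinsic cells additionally fire a
    Bernoulli event per 50 ms bin at the respiration-phased rate.

    Three independent random streams (transmission draws, intrinsic
    firing, intrinsic-cell assignment) are derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rng_txn, rng_intr, rng_assign = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    intrinsic_cells = np.sort(
        rng_assign.choice(n_cells, size=n_intrinsic, replace=False)
    )

    pulse_ms = (
        np.asarray(train.onsets, dtype=float) * 1e3
        if train is not None
        else np.empty(0)
    )
    duration_ms = duration_s * 1e3

    # Pre-draw intrinsic events (cell, time) from the phasic bin rates.
    intr_times: list[np.ndarray] = [np.empty(0)] * n_cells
    if intrinsic and n_intrinsic > 0:
        n_bins = int(np.floor(duration_ms / INTRINSIC_BIN_MS))
        bin_starts = np.arange(n_bins) * INTRINSIC_BIN_MS
        rates = intrinsic_rate_profile(bin_starts / 1e3)
        for cell in intrinsic_cells:
            fired = rng_intr.random(n_bins) < rates
            times = bin_starts[fired] + rng_intr.uniform(
                0, INTRINSIC_BIN_MS, size=int(fired.sum())
            )
            intr_times[cell] = np.sort(times)

    # Merge pulses (applied to all cells at once) and per-cell intrinsic
    # events into one chronological stream; both reset the recovery clock.
    events = [(t, -1) for t in pulse_ms]
    for cell in range(n_cells):
        events.extend((t, cell) for t in intr_times[cell])
    events.sort()

    t_last = np.full(n_cells, -1e9)
    evoked: list[list[float]] = [[] for _ in range(n_cells)]
    for t, cell in events:
        if cell >= 0:  # intrinsic event: unconditional, resets the clock
            t_last[cell] = t
            continue
        if filtering:
            p = success_probability(np.maximum(t - t_last, 1e-9))
            succ = rng_txn.random(n_cells) < p
        else:
            rng_txn.random(n_cells)  # keep stream alignment across modes
            succ = np.ones(n_cells, dtype=bool)
        t_last[succ] = t
        for cell_idx in np.nonzero(succ)[0]:
            evoked[cell_idx].append(t)

    return ICNSEvents(
        evoked=[np.asarray(e) / 1e3 for e in evoked],
        intrinsic=[t / 1e3 for t in intr_times],
        intrinsic_cells=intrinsic_cells,
        n_pulses=int(pulse_ms.size),
    )
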
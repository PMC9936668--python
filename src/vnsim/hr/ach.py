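"""Three-compartment acetylcholine release kinetics.

Each post-ganglionic event commits a fixed fraction of the pre-synaptic
main store's available ACh to a releasing pool, which transfers to the
neuroeffector junction at a first-order rate; junctional and
extra-junctional ACh exchange by first-order kinetics and both are
hydrolysed at rate ``k_H``.  The finite release rate low-pass filters
the discrete release events so the junctional concentration rises and
decays smoothly over tens of milliseconds.

The system is linear, so the junctional trace is the superposition of
the impulse responses of all events; it is evaluated on a uniform grid
with exact per-mode exponential recursions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = ["AChParams", "simulate_ach", "ach_impulse_response"]


@dataclass(frozen=True)
class AChParams:
    """Kinetic parameters of the ACh release model.

    ``available_mm`` is the pre-synaptic ACh available per event (mM);
    the value of 0.075 mM (raised from the source model's 0.04 mM)
    produces the small (~0.2%) baseline fluctuations of the SAN network
    rate under intrinsic ICNS firing.  ``k_hydrolysis`` acts on both the
    junctional and extra-junctional compartments; 14, 5 and 30 s^-1 are
    the documented alternatives.
    """

    available_mm: float = 0.075
    release_fraction: float = 0.05
    k_release: float = 4.0  # store -> junction, 1/s
    k_junction_to_extra: float = 10.0  # 1/s
    k_extra_to_junction: float = 10.0  # 1/s
    k_hydrolysis: float = 14.0  # 1/s

    def __post_init__(self):
        for name in (
            "available_mm",
            "release_fraction",
            "k_release",
            "k_junction_to_extra",
            "k_extra_to_junction",
            "k_hydrolysis",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def release_mm(self) -> float:
        """ACh committed to the releasing pool per event, mM."""
        return self.release_fraction * self.available_mm

    def system_matrix(self) -> np.ndarray:
        """Kinetic matrix of (releasing pool, junction, extra-junctional)."""
        kr = self.k_release
        kje = self.k_junction_to_extra
        kej = self.k_extra_to_junction
        kh = self.k_hydrolysis
        return np.array(
            [
                [-kr, 0.0, 0.0],
                [kr, -(kh + kje), kej],
                [0.0, kje, -(kh + kej)],
            ]
        )


def _junction_modes(params: AChParams):
    """Eigen-decomposition of the junctional impulse response.

    Returns (rates, weights) such that a unit event (injection into the
    releasing pool) produces ``J(t) = sum_m w_m exp(rate_m t)``.
    """
    m = params.system_matrix()
    lam, vecs = np.linalg.eig(m)
    coeffs = np.linalg.solve(vecs, np.array([1.0, 0.0, 0.0]))
    weights = vecs[1, :] * coeffs
    return lam.real, weights.real


def ach_impulse_response(t_s, params: AChParams) -> np.ndarray:
    """Junctional concentration after a single event at t = 0 (closed form)."""
    lam, w = _junction_modes(params)
    t = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t)
    for rate, weight in zip(lam, w):
        out += weight * np.exp(rate * np.clip(t, 0, None))
    out[t < 0] = 0.0
    return params.release_mm * out


def simulate_ach(
    event_times: list[np.ndarray] | np.ndarray,
    params: AChParams,
    duration_s: float,
    dt_s: float = 1e-3,
) -> np.ndarray:
    """Junctional ACh traces for one or many cells on a uniform grid.

    Parameters
    ----------
    event_times : ndarray or list of ndarray
        Release event times in seconds, one array per cell (or a single
        array for one cell).
    duration_s, dt_s : float
        Trace length and sample interval; ACh time constants are tens of
        milliseconds, so the default 1 ms grid resolves the kinetics.

    Returns
    -------
    ndarray, shape (n_samples, n_cells)
        Junctional ACh concentration (mM).  Identically zero for cells
        with no events.
    """
    single = isinstance(event_times, np.ndarray)
    cells = [event_times] if single else list(event_times)
    n_samples = int(round(duration_s / dt_s))
    inj = np.zeros((n_samples, len(cells)))
    for j, times in enumerate(cells):
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            continue
        if np.any(times < 0) or np.any(times >= duration_s):
            raise ValueError("event times must lie within the duration")
        idx = np.floor(times / dt_s).astype(int)
        np.add.at(inj[:, j], idx, params.release_mm)

    lam, w = _junction_modes(params)
    trace = np.zeros_like(inj)
    for rate, weight in zip(lam, w):
        decay = np.exp(rate * dt_s)
        trace += weight * lfilter([1.0], [1.0, -decay], inj, axis=0)
    return np.clip(trace, 0.0, None)
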
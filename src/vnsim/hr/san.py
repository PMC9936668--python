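"""Coupled sinoatrial-node pacemaker network.

A 10x10 grid of spontaneously firing pacemaker cells, edge-neighbours
coupled by 6 nS gap junctions.  Each cell is a reduced three-variable
conductance-based relaxation oscillator (fast inward current with
instantaneous activation, delayed-rectifier potassium current, and a slow
hyperpolarisation-activated depolarising current standing in for the
funny-current/calcium-clock diastolic mechanisms).  Cholinergic slowing
enters through an ACh-gated potassium current

    I_KACh = g_KACh * s(ACh) * (V - E_K),

with ``g_KACh`` scaled from the source model's 0.00864 uS at 32 pF to
0.00675 uS at the 25 pF mouse cell capacitance, and ``s`` a Hill function
of junctional ACh.  Default parameters are calibrated so the unperturbed
network fires at 389 BPM and slows monotonically to quiescence with ACh.

The mean firing rate of the 36 cells on the network periphery is
interpreted as heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "PacemakerParams",
    "SANResult",
    "capacitance_scaled_conductance",
    "simulate_san",
    "single_cell_rate",
    "peripheral_indices",
]

#: SAN network grid shape.
GRID_SHAPE = (10, 10)

#: Spike detection threshold (mV, rising edge).
SPIKE_THRESHOLD_MV = -20.0


def capacitance_scaled_conductance(
    g_us: float = 0.00864, c_orig_pf: float = 32.0, c_new_pf: float = 25.0
) -> float:
    """Scale a maximal conductance by the ratio of cell capacitances.

    The ACh-gated potassium conductance published for a 32 pF rabbit SAN
    cell (0.00864 uS) maps to 0.00864 * 25 / 32 = 0.00675 uS for the
    25 pF mouse cell.
    """
    if c_orig_pf <= 0 or c_new_pf <= 0:
        raise ValueError("capacitances must be positive")
    return g_us * c_new_pf / c_orig_pf


@dataclass(frozen=True)
class PacemakerParams:
    """Reduced pacemaker cell and network parameters.

    Conductances in nS, capacitance in pF, potentials in mV, time
    constants in ms.  The defaults are calibrated (see ``docs/methods``)
    so the isolated cell -- and therefore the synchronised unperturbed
    network -- fires at 389 BPM at the default 0.05 ms time step, and the
    Hill ACh sensitivity reproduces ~0.2% baseline rate fluctuation under
    intrinsic ICNS drive.
    """

    c_pf: float = 25.0
    # fast inward current (instantaneous tanh activation)
    g_fast: float = 6.0
    e_fast: float = 60.0
    vm_half: float = -30.0
    vm_slope: float = 5.0
    # delayed-rectifier potassium current
    g_k: float = 16.0
    e_k: float = -85.0
    vn_half: float = -25.0
    vn_slope: float = 5.0
    tau_n: float = 25.0
    # slow diastolic depolarisation current: activates slowly at diastolic
    # potentials (ramp that sets the pacemaker period), deactivates
    # quickly during the spike
    g_f: float = 2.63285649
    e_f: float = 0.0
    vy_half: float = -35.0
    vy_slope: float = 6.0
    tau_y_slow: float = 350.0
    tau_y_fast: float = 5.0
    vy_switch: float = -30.0
    vy_switch_slope: float = 5.0
    # background leak
    g_leak: float = 1.0
    e_leak: float = -70.0
    # ACh-gated potassium current
    g_kach: float = 6.75  # nS == 0.00675 uS at 25 pF
    ach_k05_mm: float = 4.6e-3
    ach_hill: float = 11.0
    # gap junctions
    g_gap: float = 6.0
    # initial state (post-spike diastole)
    v_init: float = -65.0
    n_init: float = 0.3
    y_init: float = 0.0

    def time_scaled(self, factor: float) -> "PacemakerParams":
        """Return parameters with cell dynamics slowed by ``factor``.

        Scaling every intrinsic conductance by ``1/factor`` and every
        gating time constant by ``factor`` (capacitance fixed) rescales
        the solution in time exactly.
        """
        return replace(
            self,
            g_fast=self.g_fast / factor,
            g_k=self.g_k / factor,
            g_f=self.g_f / factor,
            g_leak=self.g_leak / factor,
            tau_n=self.tau_n * factor,
            tau_y_slow=self.tau_y_slow * factor,
            tau_y_fast=self.tau_y_fast * factor,
        )

    def ach_activation(self, ach_mm):
        """Hill activation of the ACh-gated potassium conductance."""
        a = np.clip(np.asarray(ach_mm, dtype=float), 0.0, None)
        h = self.ach_hill
        return a**h / (a**h + self.ach_k05_mm**h)


def peripheral_indices(shape=GRID_SHAPE) -> np.ndarray:
    """Indices of the cells on the border of the grid (36 for 10x10)."""
    rows, cols = np.divmod(np.arange(shape[0] * shape[1]), shape[1])
    border = (
        (rows == 0) | (rows == shape[0] - 1) | (cols == 0) | (cols == shape[1] - 1)
    )
    return np.nonzero(border)[0]


@njit(cache=True)
def _integrate_network(
    v, n, y, s_ach, ach_step_ratio, n_steps, dt,
    c_pf, g_fast, e_fast, vm_half, vm_slope,
    g_k, e_k, vn_half, vn_slope, tau_n,
    g_f, e_f, vy_half, vy_slope,
    tau_y_slow, tau_y_fast, vy_switch, vy_switch_slope,
    g_leak, e_leak, g_kach, g_gap,
    nrow, ncol, spike_times, spike_counts, v_thresh,
):  # pragma: no cover - exercised through simulate_san
    n_cells = v.shape[0]
    max_spikes = spike_times.shape[1]
    n_ach = s_ach.shape[0]
    v_next = np.empty(n_cells)
    for step in range(n_steps):
        t_ms = step * dt
        ach_idx = step // ach_step_ratio
        if ach_idx >= n_ach:
            ach_idx = n_ach - 1
        for i in range(n_cells):
            vi = v[i]
            m_inf = 0.5 * (1.0 + np.tanh((vi - vm_half) / vm_slope))
            n_inf = 0.5 * (1.0 + np.tanh((vi - vn_half) / vn_slope))
            y_inf = 0.5 * (1.0 - np.tanh((vi - vy_half) / vy_slope))
            tau_y = tau_y_fast + (tau_y_slow - tau_y_fast) * 0.5 * (
                1.0 - np.tanh((vi - vy_switch) / vy_switch_slope)
            )

            i_ion = (
                g_fast * m_inf * (vi - e_fast)
                + g_k * n[i] * (vi - e_k)
                + g_f * y[i] * (vi - e_f)
                + g_leak * (vi - e_leak)
                + g_kach * s_ach[ach_idx, i] * (vi - e_k)
            )
            # 4-neighbour gap-junction current
            r = i // ncol
            c = i - r * ncol
            i_gap = 0.0
            if r > 0:
                i_gap += g_gap * (vi - v[i - ncol])
            if r < nrow - 1:
                i_gap += g_gap * (vi - v[i + ncol])
            if c > 0:
                i_gap += g_gap * (vi - v[i - 1])
            if c < ncol - 1:
                i_gap += g_gap * (vi - v[i + 1])

            v_new = vi - dt * (i_ion + i_gap) / c_pf
            n[i] += dt * (n_inf - n[i]) / tau_n
            y[i] += dt * (y_inf - y[i]) / tau_y
            if vi < v_thresh <= v_new and spike_counts[i] < max_spikes:
                spike_times[i, spike_counts[i]] = t_ms
                spike_counts[i] += 1
            v_next[i] = v_new
        for i in range(n_cells):
            v[i] = v_next[i]
    return v, n, y


@dataclass
class SANResult:
    """Spike output of a SAN network simulation."""

    spike_times: list  # per-cell spike times, seconds
    duration_s: float
    peripheral: np.ndarray  # indices of peripheral cells
    density_mask: np.ndarray  # cells receiving VNS-evoked ACh

    def peripheral_rate_bpm(self, window: tuple[float, float] | None = None) -> float:
        """Mean peripheral firing rate (BPM) over ``window`` seconds.

        Per cell the rate is (spikes - 1) / (last - first) within the
        window, which is free of the edge-count quantisation of a plain
        count; cells with fewer than two spikes contribute their count
        rate (0 for silent cells).
        """
        t0, t1 = window if window is not None else (0.0, self.duration_s)
        if t1 <= t0:
            raise ValueError("empty analysis window")
        rates = []
        for i in self.peripheral:
            st = self.spike_times[i]
            st = st[(st >= t0) & (st < t1)]
            if st.size >= 2 and st[-1] > st[0]:
                rates.append((st.size - 1) / (st[-1] - st[0]) * 60.0)
            else:
                rates.append(st.size / (t1 - t0) * 60.0)
        return float(np.mean(rates))

    def network_rate_series(
        self, dt_s: float = 0.01, window_s: float = 0.5
    ) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed instantaneous network rate (BPM) on a uniform grid.

        At each time the per-cell instantaneous rate is 60/ISI of the
        inter-spike interval spanning that time, averaged over peripheral
        cells, then smoothed with a ``window_s`` moving mean.
        """
        grid = np.arange(0.0, self.duration_s, dt_s)
        rates = np.full((len(self.peripheral), grid.size), np.nan)
        for j, i in enumerate(self.peripheral):
            st = self.spike_times[i]
            if st.size < 2:
                continue
            idx = np.searchsorted(st, grid)
            valid = (idx >= 1) & (idx < st.size)
            isi = st[idx[valid]] - st[idx[valid] - 1]
            rates[j, valid] = 60.0 / isi
        have = np.sum(~np.isnan(rates), axis=0)
        with np.errstate(invalid="ignore"):
            network = np.where(
                have > 0, np.nansum(np.nan_to_num(rates), axis=0) / np.maximum(have, 1), np.nan
            )
        k = max(1, int(round(window_s / dt_s)))
        kernel = np.ones(k) / k
        valid = ~np.isnan(network)
        if valid.sum() >= k:
            smoothed = np.convolve(network[valid], kernel, mode="valid")
            t_valid = grid[valid][k - 1 :] - (window_s - dt_s) / 2.0
            return t_valid, smoothed
        return grid[valid], network[valid]

    def rate_fluctuation_percent(
        self, window: tuple[float, float] | None = None
    ) -> float:
        """Peak-to-trough relative variation of the network rate, percent."""
        t, r = self.network_rate_series()
        if window is not None:
            sel = (t >= window[0]) & (t < window[1])
            t, r = t[sel], r[sel]
        if r.size == 0 or np.mean(r) == 0:
            return float("nan")
        return float((r.max() - r.min()) / r.mean() * 100.0)


def simulate_san(
    duration_s: float,
    *,
    evoked_ach: np.ndarray | None = None,
    intrinsic_ach: np.ndarray | None = None,
    density: int = 0,
    seed: int = 0,
    intrinsic_cells: np.ndarray | None = None,
    ach_dt_s: float = 1e-3,
    dt_ms: float = 0.05,
    params: PacemakerParams | None = None,
) -> SANResult:
    """Integrate the coupled SAN network.

    Parameters
    ----------
    evoked_ach, intrinsic_ach : ndarray or None
        Junctional ACh traces, shape (n_ach_samples, 100), sampled every
        ``ach_dt_s``.  VNS-evoked ACh reaches only the ``density`` cells
        of a uniformly random mask (drawn from ``seed``); intrinsic ACh
        reaches the cells listed in ``intrinsic_cells`` regardless.
    density : int
        Number of cells receiving VNS-evoked ACh (the model's proxy for
        stimulation amplitude), 0 to 100.
    dt_ms : float
        Fixed integration step, milliseconds.

    Returns
    -------
    SANResult
    """
    params = params or PacemakerParams()
    nrow, ncol = GRID_SHAPE
    n_cells = nrow * ncol
    if not 0 <= density <= n_cells:
        raise ValueError("density must lie in [0, 100]")
    rng_mask = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    mask_cells = np.sort(rng_mask.choice(n_cells, size=density, replace=False))

    n_steps = int(round(duration_s * 1e3 / dt_ms))
    ach_step_ratio = max(1, int(round(ach_dt_s * 1e3 / dt_ms)))
    n_ach = max(1, int(round(duration_s / ach_dt_s)))
    total = np.zeros((n_ach, n_cells))
    if evoked_ach is not None and density > 0:
        total[:, mask_cells] += evoked_ach[:n_ach, mask_cells]
    if intrinsic_ach is not None and intrinsic_cells is not None:
        total[:, intrinsic_cells] += intrinsic_ach[:n_ach, intrinsic_cells]
    s_ach = np.ascontiguousarray(params.ach_activation(total))

    v = np.full(n_cells, params.v_init)
    n = np.full(n_cells, params.n_init)
    y = np.full(n_cells, params.y_init)
    max_spikes = int(duration_s * 20) + 16
    spike_times = np.zeros((n_cells, max_spikes))
    spike_counts = np.zeros(n_cells, dtype=np.int64)

    _integrate_network(
        v, n, y, s_ach, ach_step_ratio, n_steps, dt_ms,
        params.c_pf, params.g_fast, params.e_fast, params.vm_half,
        params.vm_slope, params.g_k, params.e_k, params.vn_half,
        params.vn_slope, params.tau_n, params.g_f, params.e_f,
        params.vy_half, params.vy_slope, params.tau_y_slow,
        params.tau_y_fast, params.vy_switch, params.vy_switch_slope,
        params.g_leak, params.e_leak, params.g_kach, params.g_gap,
        nrow, ncol, spike_times, spike_counts, SPIKE_THRESHOLD_MV,
    )
    spikes = [
        spike_times[i, : spike_counts[i]] / 1e3 for i in range(n_cells)
    ]
    return SANResult(
        spike_times=spikes,
        duration_s=duration_s,
        peripheral=peripheral_indices(),
        density_mask=mask_cells,
    )


def single_cell_rate(
    params: PacemakerParams | None = None,
    *,
    ach_mm: float = 0.0,
    duration_s: float = 10.0,
    dt_ms: float = 0.05,
    discard_s: float = 2.0,
) -> float:
    """Firing rate (BPM) of one isolated cell at constant junctional ACh.

    Runs a 1x1 network (no gap-junction partners).  Returns 0 for a
    quiescent cell.
    """
    params = params or PacemakerParams()
    n_steps = int(round(duration_s * 1e3 / dt_ms))
    s = np.full((1, 1), params.ach_activation(ach_mm))
    v = np.array([params.v_init])
    n = np.array([params.n_init])
    y = np.array([params.y_init])
    max_spikes = int(duration_s * 20) + 16
    spike_times = np.zeros((1, max_spikes))
    spike_counts = np.zeros(1, dtype=np.int64)
    _integrate_network(
        v, n, y, s, n_steps, n_steps, dt_ms,
        params.c_pf, params.g_fast, params.e_fast, params.vm_half,
        params.vm_slope, params.g_k, params.e_k, params.vn_half,
        params.vn_slope, params.tau_n, params.g_f, params.e_f,
        params.vy_half, params.vy_slope, params.tau_y_slow,
        params.tau_y_fast, params.vy_switch, params.vy_switch_slope,
        params.g_leak, params.e_leak, params.g_kach, 0.0, 1, 1,
        spike_times, spike_counts, SPIKE_THRESHOLD_MV,
    )
    st = spike_times[0, : spike_counts[0]] / 1e3
    st = st[st >= discard_s]
    if st.size < 2:
        return 0.0
    return float((st.size - 1) / (st[-1] - st[0]) * 60.0)
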
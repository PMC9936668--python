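"""Neighbourhood particle swarm optimisation of the muscle model.

The swarm has 100 particles in 20 fixed neighbourhoods of 5.  Each
particle is an 8-vector of force-fatigue parameters within the published
bounds, scaled to [0, 1] per dimension internally so the shared random
coefficient acts uniformly across the heterogeneous scales.  Per
iteration, each particle's velocity is

    V_i = rand() * (P_best1 - P_i) - rand() * (P_best2 - P_i)

with rand() uniform on [0, 1.496) drawn per dimension, where (P_best1,
P_best2) follow the three-case neighbourhood ranking rule: the
neighbourhood best is pulled by the global best and the neighbourhood
second best; the second best by the neighbourhood best and third best;
everyone else by the neighbourhood best and second best.  The global
best particle is not moved (elitism).  Note the second term's minus sign
is repulsive, which departs from conventional PSO; ``velocity_sign``
toggles between the rule as printed above ("printed") and the
conventional attractive form ("conventional").

Cost is the RMSE between the model's Force_norm and the target
normalised EMG over the training patterns; runs use a 50-50
training/testing split of the 36 temporal patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .muscle import (
    DingParams,
    PARAM_BOUNDS,
    PARAM_NAMES,
    force_time_integral,
)
from .patterns import Condition, make_constant_train, train_for_condition

__all__ = [
    "Swarm",
    "PSORun",
    "cost",
    "select_bests",
    "step_swarm",
    "run_pso",
    "MuscleActivationModel",
    "MuscleFitResults",
]

N_PARTICLES = 100
N_NEIGHBORHOODS = 20
NEIGHBORHOOD_SIZE = 5
N_ITERATIONS = 50
RAND_UPPER = 1.496

_LOWER = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
_UPPER = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])


def _to_unit(positions):
    return (positions - _LOWER) / (_UPPER - _LOWER)


def _from_unit(unit):
    return _LOWER + unit * (_UPPER - _LOWER)


class _ForceNormEvaluator:
    """Force_norm for a set of patterns at given parameters.

    Pulse trains (including the 20 Hz reference) are built once; each
    cost evaluation simulates every training pattern plus the reference.
    ``window_s`` and ``dt_ms`` set the simulated pattern duration and
    integration step, allowing scaled-down fitting runs.
    """

    def __init__(self, patterns, window_s=30.0, dt_ms=0.1):
        self.labels = [c.label for c in patterns]
        self.trains = [
            train_for_condition(c, window_s) for c in patterns
        ]
        self.reference = make_constant_train(20.0, window_s)
        self.dt_ms = dt_ms
        self.duration_s = window_s + 0.5

    def force_norms(self, params: DingParams) -> np.ndarray:
        ref = force_time_integral(
            self.reference, params, dt_ms=self.dt_ms, duration_s=self.duration_s
        )
        if not np.isfinite(ref) or ref <= 0:
            return np.full(len(self.trains), np.inf)
        return np.array(
            [
                force_time_integral(
                    tr, params, dt_ms=self.dt_ms, duration_s=self.duration_s
                )
                / ref
                for tr in self.trains
            ]
        )


def cost(
    params: DingParams,
    patterns: list[Condition],
    targets: np.ndarray,
    *,
    window_s: float = 30.0,
    dt_ms: float = 0.1,
    evaluator: _ForceNormEvaluator | None = None,
) -> float:
    """RMSE between modelled Force_norm and the target normalised EMG."""
    if len(patterns) == 0:
        raise ValueError("empty pattern set")
    ev = evaluator or _ForceNormEvaluator(patterns, window_s, dt_ms)
    resid = ev.force_norms(params) - np.asarray(targets, dtype=float)
    return float(np.sqrt(np.mean(resid**2)))


def select_bests(
    i: int, neighborhood: np.ndarray, costs: np.ndarray, global_best: int
) -> tuple[int, int]:
    """Particle indices (P_best1, P_best2) steering particle ``i``.

    ``neighborhood`` lists the particle indices of i's neighbourhood;
    ranking ties break by stable particle index.
    """
    order = neighborhood[np.lexsort((neighborhood, costs[neighborhood]))]
    if i == order[0]:
        return int(global_best), int(order[1])
    if i == order[1]:
        return int(order[0]), int(order[2])
    return int(order[0]), int(order[1])


@dataclass
class Swarm:
    """Particle positions (unit-scaled), costs, and fixed neighbourhoods."""

    unit_positions: np.ndarray  # (n_particles, 8) in [0, 1]
    costs: np.ndarray
    neighborhoods: np.ndarray  # (n_neighborhoods, neighborhood_size)

    @classmethod
    def initialise(cls, rng, n_particles=N_PARTICLES):
        if n_particles % NEIGHBORHOOD_SIZE:
            raise ValueError("particle count must fill whole neighbourhoods")
        unit = rng.uniform(0.0, 1.0, size=(n_particles, len(PARAM_NAMES)))
        hoods = np.arange(n_particles).reshape(-1, NEIGHBORHOOD_SIZE)
        return cls(
            unit_positions=unit,
            costs=np.full(n_particles, np.inf),
            neighborhoods=hoods,
        )

    def positions(self) -> np.ndarray:
        return _from_unit(self.unit_positions)

    def params(self, i: int) -> DingParams:
        return DingParams.from_free_vector(self.positions()[i])

    @property
    def global_best(self) -> int:
        return int(np.lexsort((np.arange(self.costs.size), self.costs))[0])


def step_swarm(
    swarm: Swarm, rng, *, velocity_sign: str = "printed"
) -> None:
    """Advance every particle except the global best by one velocity step.

    Positions are clipped to the bounds after the update (several
    identified parameter values sit exactly at bounds, consistent with
    clipping).
    """
    if velocity_sign not in ("printed", "conventional"):
        raise ValueError("velocity_sign must be 'printed' or 'conventional'")
    sign = -1.0 if velocity_sign == "printed" else 1.0
    gbest = swarm.global_best
    pos = swarm.unit_positions
    new_pos = pos.copy()
    ndim = pos.shape[1]
    for hood in swarm.neighborhoods:
        for i in hood:
            # draws consumed for every particle to keep the stream stable
            r1 = rng.uniform(0.0, RAND_UPPER, size=ndim)
            r2 = rng.uniform(0.0, RAND_UPPER, size=ndim)
            if i == gbest:
                continue
            b1, b2 = select_bests(i, hood, swarm.costs, gbest)
            velocity = r1 * (pos[b1] - pos[i]) + sign * r2 * (pos[b2] - pos[i])
            new_pos[i] = np.clip(pos[i] + velocity, 0.0, 1.0)
    swarm.unit_positions = new_pos


@dataclass
class PSORun:
    """Diagnostics of a single swarm run."""

    best_params: DingParams
    best_history: np.ndarray  # lowest swarm cost per iteration
    train_patterns: list
    test_patterns: list
    train_rmse: float
    test_rmse: float
    total_rmse: float
    seed: int


def _evaluate_swarm(swarm, evaluator, targets, rng):
    for i in range(swarm.unit_positions.shape[0]):
        params = swarm.params(i)
        resid = evaluator.force_norms(params) - targets
        c = float(np.sqrt(np.mean(resid**2)))
        if not np.isfinite(c):
            warnings.warn(
                "non-finite cost; particle re-initialised", stacklevel=2
            )
            swarm.unit_positions[i] = rng.uniform(0.0, 1.0, size=len(PARAM_NAMES))
            params = swarm.params(i)
            resid = evaluator.force_norms(params) - targets
            c = float(np.sqrt(np.mean(resid**2)))
        swarm.costs[i] = c


def run_pso(
    targets: dict | pd.Series,
    *,
    split_seed: int = 0,
    init_seed: int = 0,
    runs: int = 5,
    n_iterations: int = N_ITERATIONS,
    n_particles: int = N_PARTICLES,
    window_s: float = 30.0,
    dt_ms: float = 0.1,
    velocity_sign: str = "printed",
    fixed_params: dict | None = None,
) -> tuple[DingParams, list[PSORun]]:
    """Fit the muscle model to per-pattern normalised-EMG targets.

    ``targets`` maps :class:`Condition` (amplitude 1.0 temporal patterns)
    to the mean normalised EMG.  Each run draws a fresh uniform-in-bounds
    swarm and a fresh 50-50 training/testing split, iterates the swarm on
    the training patterns, and reports training/testing/total RMSE; the
    returned parameter set is the best particle of the run with the
    lowest *total* RMSE.  ``fixed_params`` pins named parameters to given
    values throughout (used in recovery experiments).
    """
    conditions = list(targets.keys()) if isinstance(targets, dict) else list(targets.index)
    values = np.array(
        [targets[c] for c in conditions], dtype=float
    )
    n = len(conditions)
    if n < 2:
        raise ValueError("at least two target patterns are required")
    fixed_idx = {}
    if fixed_params:
        for name, val in fixed_params.items():
            k = PARAM_NAMES.index(name)
            lo, hi = _LOWER[k], _UPPER[k]
            fixed_idx[k] = (val - lo) / (hi - lo)

    ss = np.random.SeedSequence([init_seed, split_seed])
    run_seeds = ss.spawn(runs)
    results = []
    for r, seq in enumerate(run_seeds):
        rng = np.random.default_rng(seq)
        perm = rng.permutation(n)
        n_train = n // 2
        train_ids = sorted(perm[:n_train])
        test_ids = sorted(perm[n_train:])
        train_conditions = [conditions[i] for i in train_ids]
        test_conditions = [conditions[i] for i in test_ids]
        ev_train = _ForceNormEvaluator(train_conditions, window_s, dt_ms)
        ev_all = _ForceNormEvaluator(conditions, window_s, dt_ms)

        swarm = Swarm.initialise(rng, n_particles)

        def _pin(sw):
            for k, unit_val in fixed_idx.items():
                sw.unit_positions[:, k] = unit_val

        _pin(swarm)
        history = np.empty(n_iterations)
        for it in range(n_iterations):
            _evaluate_swarm(swarm, ev_train, values[train_ids], rng)
            history[it] = swarm.costs.min()
            if it < n_iterations - 1:
                step_swarm(swarm, rng, velocity_sign=velocity_sign)
                _pin(swarm)
        best = swarm.global_best
        best_params = swarm.params(best)
        fn_all = ev_all.force_norms(best_params)
        train_rmse = float(
            np.sqrt(np.mean((fn_all[train_ids] - values[train_ids]) ** 2))
        )
        test_rmse = float(
            np.sqrt(np.mean((fn_all[test_ids] - values[test_ids]) ** 2))
        )
        total_rmse = float(np.sqrt(np.mean((fn_all - values) ** 2)))
        results.append(
            PSORun(
                best_params=best_params,
                best_history=history,
                train_patterns=train_conditions,
                test_patterns=test_conditions,
                train_rmse=train_rmse,
                test_rmse=test_rmse,
                total_rmse=total_rmse,
                seed=r,
            )
        )
    winner = min(results, key=lambda run: run.total_rmse)
    return winner.best_params, results


@dataclass
class MuscleFitResults:
    """Results of fitting the muscle model to normalised-EMG targets."""

    params: DingParams
    runs: list
    model: "MuscleActivationModel"

    @property
    def total_rmse(self) -> float:
        return min(r.total_rmse for r in self.runs)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "run": r.seed,
                "train_rmse": r.train_rmse,
                "test_rmse": r.test_rmse,
                "total_rmse": r.total_rmse,
                "converged_by_20": bool(
                    r.best_history[min(20, len(r.best_history) - 1) :].min()
                    >= r.best_history[-1] - 1e-9
                ),
            }
            for r in self.runs
        ]
        return pd.DataFrame(rows)

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": PARAM_NAMES,
                "value": self.params.free_vector(),
                "lower": _LOWER,
                "upper": _UPPER,
            }
        )


class MuscleActivationModel:
    """Force-fatigue muscle model fitted to normalised EMG targets.

    Parameters
    ----------
    targets : DataFrame
        One row per temporal pattern with columns
        ``intra_burst_frequency``, ``mean_pulse_rate``, ``pattern_kind``
        and ``emg_norm`` (mean normalised EMG across animals at 1.0xBCT).
    """

    def __init__(self, targets: pd.DataFrame, *, window_s=30.0, dt_ms=0.1):
        required = {
            "intra_burst_frequency",
            "mean_pulse_rate",
            "pattern_kind",
            "emg_norm",
        }
        if not required.issubset(targets.columns):
            raise ValueError(f"targets must have columns {sorted(required)}")
        self.targets = targets.copy()
        self.window_s = window_s
        self.dt_ms = dt_ms

    @classmethod
    def from_quantified(cls, quantified: pd.DataFrame, **kwargs):
        """Mean EMG_norm per temporal pattern at 1.0xBCT from a tidy
        quantified-trials table."""
        sel = quantified[quantified["amplitude"] == 1.0]
        grouped = (
            sel.groupby(
                ["intra_burst_frequency", "mean_pulse_rate", "pattern_kind"]
            )["emg_norm"]
            .mean()
            .reset_index()
        )
        return cls(grouped, **kwargs)

    def _target_map(self) -> dict:
        out = {}
        for _, row in self.targets.iterrows():
            cond = Condition(
                amplitude=1.0,
                intra_burst_frequency=float(row["intra_burst_frequency"]),
                mean_pulse_rate=float(row["mean_pulse_rate"]),
                pattern_kind=row["pattern_kind"],
            )
            out[cond] = float(row["emg_norm"])
        return out

    def fit(
        self,
        *,
        runs: int = 5,
        split_seed: int = 0,
        init_seed: int = 0,
        n_iterations: int = N_ITERATIONS,
        n_particles: int = N_PARTICLES,
        velocity_sign: str = "printed",
        fixed_params: dict | None = None,
    ) -> MuscleFitResults:
        params, run_list = run_pso(
            self._target_map(),
            split_seed=split_seed,
            init_seed=init_seed,
            runs=runs,
            n_iterations=n_iterations,
            n_particles=n_particles,
            window_s=self.window_s,
            dt_ms=self.dt_ms,
            velocity_sign=velocity_sign,
            fixed_params=fixed_params,
        )
        return MuscleFitResults(params=params, runs=run_list, model=self)
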
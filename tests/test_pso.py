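"""Neighbourhood particle swarm optimiser."""

import numpy as np
import pytest

from vnsim.muscle import PARAM_NAMES, PARAM_BOUNDS, DingParams
from vnsim.patterns import enumerate_design
from vnsim.pso import (
    Swarm,
    _ForceNormEvaluator,
    cost,
    run_pso,
    select_bests,
    step_swarm,
)


class TestCost:
    def test_perfect_fit_zero(self):
        design = enumerate_design(rate_grid=(5.0, 20.0), amplitudes=(1.0,))
        ev = _ForceNormEvaluator(design, window_s=2.0, dt_ms=0.5)
        targets = ev.force_norms(DingParams())
        assert cost(DingParams(), design, targets, evaluator=ev) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_residual(self):
        design = enumerate_design(rate_grid=(20.0,), amplitudes=(1.0,))
        ev = _ForceNormEvaluator(design, window_s=2.0, dt_ms=0.5)
        targets = ev.force_norms(DingParams()) + 0.5
        assert cost(DingParams(), design, targets, evaluator=ev) == pytest.approx(0.5)

    def test_two_residual_rmse(self):
        from vnsim.patterns import Condition

        design = [
            Condition(amplitude=1.0, intra_burst_frequency=f, mean_pulse_rate=f)
            for f in (5.0, 20.0)
        ]
        ev = _ForceNormEvaluator(design, window_s=2.0, dt_ms=0.5)
        targets = ev.force_norms(DingParams()) + np.array([0.3, 0.4])
        assert cost(DingParams(), design, targets, evaluator=ev) == pytest.approx(
            np.sqrt(0.125), abs=1e-9
        )

    def test_empty_pattern_set_rejected(self):
        with pytest.raises(ValueError):
            cost(DingParams(), [], np.array([]))


class TestSelectBests:
    def setup_method(self):
        self.hood = np.array([10, 11, 12, 13, 14])
        self.costs = np.full(100, np.inf)
        self.costs[self.hood] = [0.5, 0.1, 0.3, 0.2, 0.4]
        # ranking: 11 (best), 13, 12, 14, 10

    def test_neighborhood_best_pulled_by_global(self):
        b1, b2 = select_bests(11, self.hood, self.costs, global_best=77)
        assert (b1, b2) == (77, 13)

    def test_second_best_pulled_by_best_and_third(self):
        b1, b2 = select_bests(13, self.hood, self.costs, global_best=77)
        assert (b1, b2) == (11, 12)

    def test_others_pulled_by_best_and_second(self):
        for i in (12, 14, 10):
            assert select_bests(i, self.hood, self.costs, 77) == (11, 13)

    def test_tie_breaks_by_particle_index(self):
        self.costs[self.hood] = 0.2  # all tied
        b1, b2 = select_bests(12, self.hood, self.costs, global_best=77)
        assert (b1, b2) == (10, 11)


class TestStepSwarm:
    def _swarm(self, seed=0, n=10):
        rng = np.random.default_rng(seed)
        swarm = Swarm.initialise(rng, n)
        swarm.costs = rng.uniform(0.1, 1.0, size=n)
        return swarm, rng

    def test_global_best_frozen(self):
        swarm, rng = self._swarm()
        gbest = swarm.global_best
        before = swarm.unit_positions[gbest].copy()
        step_swarm(swarm, rng)
        assert np.array_equal(swarm.unit_positions[gbest], before)

    def test_exactly_one_frozen_particle(self):
        swarm, rng = self._swarm(seed=3)
        before = swarm.unit_positions.copy()
        step_swarm(swarm, rng)
        unchanged = np.all(swarm.unit_positions == before, axis=1)
        assert unchanged.sum() == 1

    def test_positions_stay_in_bounds(self):
        swarm, rng = self._swarm(seed=5, n=20)
        for _ in range(10):
            swarm.costs = rng.uniform(0.1, 1.0, size=20)
            step_swarm(swarm, rng)
            assert np.all(swarm.unit_positions >= 0.0)
            assert np.all(swarm.unit_positions <= 1.0)

    def test_velocity_sign_toggle_changes_update(self):
        swarm_a, _ = self._swarm(seed=7)
        swarm_b, _ = self._swarm(seed=7)
        step_swarm(swarm_a, np.random.default_rng(42), velocity_sign="printed")
        step_swarm(swarm_b, np.random.default_rng(42), velocity_sign="conventional")
        assert not np.array_equal(swarm_a.unit_positions, swarm_b.unit_positions)


class TestRunPSO:
    def test_determinism_and_elitism(self):
        design = enumerate_design(rate_grid=(5.0, 20.0, 50.0), amplitudes=(1.0,))
        ev = _ForceNormEvaluator(design, window_s=2.0, dt_ms=0.5)
        targets = dict(zip(design, ev.force_norms(DingParams())))
        kwargs = dict(
            runs=1, n_iterations=6, n_particles=20, window_s=2.0, dt_ms=0.5,
            split_seed=1, init_seed=2,
        )
        best_a, runs_a = run_pso(targets, **kwargs)
        best_b, runs_b = run_pso(targets, **kwargs)
        assert np.array_equal(runs_a[0].best_history, runs_b[0].best_history)
        assert np.all(np.diff(runs_a[0].best_history) <= 1e-12)  # elitism
        assert best_a.within_bounds()

    def test_train_test_split_disjoint_and_complete(self):
        design = enumerate_design(rate_grid=(2.0, 10.0, 30.0), amplitudes=(1.0,))
        ev = _ForceNormEvaluator(design, window_s=2.0, dt_ms=0.5)
        targets = dict(zip(design, ev.force_norms(DingParams())))
        _, runs = run_pso(
            targets, runs=2, n_iterations=3, n_particles=10,
            window_s=2.0, dt_ms=0.5,
        )
        for r in runs:
            train = {c.label for c in r.train_patterns}
            test = {c.label for c in r.test_patterns}
            assert train.isdisjoint(test)
            assert train | test == {c.label for c in design}

    def test_convex_surrogate_convergence(self):
        # sanity oracle: on a quadratic bowl the swarm converges to the
        # minimiser from every initial population
        centre = np.array([0.4, 0.6, 0.3, 0.7, 0.5, 0.45, 0.55, 0.35])
        for seed in range(3):
            rng = np.random.default_rng(seed)
            swarm = Swarm.initialise(rng, 50)
            for _ in range(150):
                swarm.costs = np.sum(
                    (swarm.unit_positions - centre) ** 2, axis=1
                )
                step_swarm(swarm, rng, velocity_sign="conventional")
            swarm.costs = np.sum((swarm.unit_positions - centre) ** 2, axis=1)
            best = swarm.unit_positions[swarm.global_best]
            assert np.max(np.abs(best - centre)) < 0.01
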
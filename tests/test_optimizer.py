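"""Swarm optimizer: sizing heuristic, update rules, convergence behavior."""

import numpy as np
import pytest

from cgcalib.optimizer import (
    OptimizerConfig,
    default_swarm_size,
    initialize_swarm,
    optimize,
    step,
)

BOUNDS_5D = np.array([[-5.0, 5.0]] * 5)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestSwarmSize:
    @pytest.mark.parametrize("dim,expected", [(77, 27), (48, 23), (1, 12)])
    def test_population_heuristic(self, dim, expected):
        assert default_swarm_size(dim) == expected

    def test_dimension_must_be_positive(self):
        with pytest.raises(ValueError):
            default_swarm_size(0)


class TestInitialize:
    def test_first_particle_is_the_seed_exactly(self):
        seed_vec = np.array([0.3, -2.0, 4.9, 0.0, 1.0])
        state = initialize_swarm(BOUNDS_5D, seed_vec, np.random.default_rng(0))
        assert np.array_equal(state.particles[0].position, seed_vec)
        assert all(np.all(p.velocity == 0) for p in state.particles)

    def test_identical_rng_seeds_give_identical_states(self):
        s1 = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(5))
        s2 = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(5))
        for p1, p2 in zip(s1.particles, s2.particles):
            assert np.array_equal(p1.position, p2.position)

    def test_non_seed_particles_uniform_within_bounds(self):
        bounds = np.array([[0.0, 1.0]] * 3)
        state = initialize_swarm(bounds, None, np.random.default_rng(123),
                                 swarm_size=10_000)
        pos = np.array([p.position for p in state.particles])
        assert np.all((pos >= 0) & (pos <= 1))
        assert np.all((pos.mean(axis=0) > 0.45) & (pos.mean(axis=0) < 0.55))

    def test_out_of_bounds_seed_clamped_with_warning(self):
        seed_vec = np.array([9.0, 0.0, 0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="clamped"):
            state = initialize_swarm(BOUNDS_5D, seed_vec, np.random.default_rng(0))
        assert state.particles[0].position[0] == 5.0

    def test_malformed_bounds_rejected(self):
        with pytest.raises(ValueError):
            initialize_swarm(np.array([[1.0, -1.0]]), None)


class TestStep:
    def test_no_improvement_increments_stale_counter(self):
        state = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(0),
                                 swarm_size=4)
        step(state, [5.0, 6.0, 7.0, 8.0])     # first: global best set
        assert state.stale_iterations == 0
        step(state, [9.0, 9.0, 9.0, 9.0])     # all worse
        assert state.stale_iterations == 1
        assert state.global_best_loss == 5.0

    def test_strict_improvement_resets_stale_counter(self):
        state = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(0),
                                 swarm_size=4)
        step(state, [5.0, 6.0, 7.0, 8.0])
        step(state, [9.0, 9.0, 9.0, 9.0])
        step(state, [9.0, 4.0, 9.0, 9.0])
        assert state.stale_iterations == 0
        assert state.global_best_loss == 4.0

    def test_tie_does_not_reset_stale_counter(self):
        state = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(0),
                                 swarm_size=4)
        step(state, [5.0, 6.0, 7.0, 8.0])
        step(state, [5.0, 5.0, 5.0, 5.0])     # equal, not better
        assert state.stale_iterations == 1

    def test_non_finite_losses_treated_as_failures(self):
        state = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(0),
                                 swarm_size=3)
        step(state, [np.nan, np.inf, 2.0])
        assert state.global_best_loss == 2.0

    def test_positions_stay_within_bounds(self):
        state = initialize_swarm(BOUNDS_5D, None, np.random.default_rng(7),
                                 swarm_size=8)
        rng = np.random.default_rng(1)
        for _ in range(30):
            step(state, rng.uniform(0, 100, 8))
            for p in state.particles:
                assert np.all(p.position >= BOUNDS_5D[:, 0])
                assert np.all(p.position <= BOUNDS_5D[:, 1])

    def test_plain_update_matches_hand_stepped_reference(self):
        """Three plain-PSO iterations on a 2-D quadratic, re-derived by an
        independent implementation of the documented update recurrence."""
        bounds = np.array([[-4.0, 4.0], [-4.0, 4.0]])
        quad = lambda x: float(x[0] ** 2 + 2 * x[1] ** 2)  # noqa: E731

        state = initialize_swarm(bounds, None, np.random.default_rng(42),
                                 swarm_size=3, mode="plain")
        # independent replica of initialization and updates, consuming an
        # identically-seeded random stream in the same order
        rng = np.random.default_rng(42)
        pos = rng.uniform(bounds[:, 0], bounds[:, 1], size=(3, 2))
        vel = np.zeros((3, 2))
        pbest = pos.copy()
        pbest_f = np.full(3, np.inf)
        gbest = pos[0].copy()
        gbest_f = np.inf
        span = bounds[:, 1] - bounds[:, 0]

        for _ in range(3):
            losses = np.array([quad(p.position) for p in state.particles])
            step(state, losses)

            f = np.array([quad(x) for x in pos])
            for i in range(3):
                if f[i] < pbest_f[i]:
                    pbest_f[i] = f[i]
                    pbest[i] = pos[i].copy()
                if f[i] < gbest_f:
                    gbest_f = f[i]
                    gbest = pos[i].copy()
            for i in range(3):
                r1 = rng.random(2)
                r2 = rng.random(2)
                v = 0.72 * vel[i] + 1.49 * r1 * (pbest[i] - pos[i]) \
                    + 1.49 * r2 * (gbest - pos[i])
                if not np.any(np.abs(v) > 0):
                    v = 0.002 * span * rng.standard_normal(2)
                v = np.clip(v, -0.2 * span, 0.2 * span)
                x = pos[i] + v
                for _ in range(10):
                    below, above = x < bounds[:, 0], x > bounds[:, 1]
                    if not (below.any() or above.any()):
                        break
                    x[below] = 2 * bounds[below, 0] - x[below]
                    x[above] = 2 * bounds[above, 1] - x[above]
                    v[below] *= -1
                    v[above] *= -1
                pos[i] = np.clip(x, bounds[:, 0], bounds[:, 1])
                vel[i] = v

        assert gbest_f == pytest.approx(state.global_best_loss)
        for i, p in enumerate(state.particles):
            assert np.allclose(p.position, pos[i], atol=1e-12)


class TestOptimize:
    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_sphere_minimum_found(self, seed):
        _, best_loss, _, _ = optimize(
            sphere, BOUNDS_5D,
            OptimizerConfig(max_iterations=200, stale_limit=200, seed=seed),
        )
        assert best_loss < 1e-2

    def test_constant_objective_stops_after_exactly_ten_stale_iterations(self):
        _, _, history, reason = optimize(
            lambda x: 1.0, BOUNDS_5D, OptimizerConfig(max_iterations=500, seed=0)
        )
        assert reason == "stale_iterations"
        # first iteration sets the best; then 10 iterations without improvement
        assert len(history.iterations) == 11

    def test_global_best_sequence_non_increasing(self):
        _, _, history, _ = optimize(
            sphere, BOUNDS_5D, OptimizerConfig(max_iterations=60, seed=2)
        )
        best = [it["best_loss"] for it in history.iterations]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))

    @pytest.mark.parametrize("mode", ["fst", "plain"])
    def test_fixed_seed_runs_are_bit_reproducible(self, mode):
        runs = [
            optimize(sphere, BOUNDS_5D,
                     OptimizerConfig(max_iterations=40, seed=9, mode=mode))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]
        h0 = [it["losses"] for it in runs[0][2].iterations]
        h1 = [it["losses"] for it in runs[1][2].iterations]
        assert h0 == h1

    def test_fst_at_least_as_good_as_plain_on_sphere(self):
        medians = {}
        for mode in ("fst", "plain"):
            finals = [
                optimize(sphere, BOUNDS_5D,
                         OptimizerConfig(max_iterations=200, stale_limit=200,
                                         seed=s, mode=mode))[1]
                for s in range(20)
            ]
            medians[mode] = np.median(finals)
        assert medians["fst"] <= medians["plain"]

    def test_always_failing_objective_aborts(self):
        with pytest.raises(RuntimeError, match="failed"):
            optimize(lambda x: np.nan, BOUNDS_5D, OptimizerConfig(seed=0))

    def test_seeded_run_improves_on_or_keeps_seed(self):
        seed_vec = np.full(5, 0.5)
        _, best_loss, _, _ = optimize(
            sphere, BOUNDS_5D, OptimizerConfig(max_iterations=50, seed=4),
            seed_vector=seed_vec,
        )
        assert best_loss <= sphere(seed_vec)
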
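"""Unit and property tests for the RDBPSO optimizer and the PSO baseline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sphere
from rdbpso.optimizer import (
    GlobalMemory,
    Objective,
    OptimizerConfig,
    ParticleState,
    candidate_combinations,
    consolidate_global_memory,
    dropout_select,
    generate_candidate,
    initialize_swarm,
    optimize,
    optimize_standard_pso,
    pair_particles,
    update_memory,
)


def particle(f_y: float, f_y_second: float, index: int = 0, d: int = 2) -> ParticleState:
    return ParticleState(
        index=index,
        x=np.zeros(d),
        y=np.full(d, f_y),
        f_y=f_y,
        y_second=np.full(d, f_y_second),
        f_y_second=f_y_second,
    )


class TestInitialization:
    def test_lower_fitness_draw_becomes_best(self):
        obj = Objective(lambda x: float(x[0]), [0.0], [1.0])
        particles, _ = initialize_swarm(obj, OptimizerConfig(n_particles=5, seed=3), np.random.default_rng(3))
        for p in particles:
            assert p.f_y <= p.f_y_second
            assert np.allclose(p.x, p.y)

    def test_constant_objective_tie_keeps_first_draw_as_best(self):
        # replay the draws to know which position came first
        obj = Objective(lambda x: 5.0, [0.0] * 2, [1.0] * 2)
        rng = np.random.default_rng(11)
        particles, _ = initialize_swarm(obj, OptimizerConfig(n_particles=4, seed=11), rng)
        replay = np.random.default_rng(11)
        for p in particles:
            first = replay.uniform(obj.lower, obj.upper)
            second = replay.uniform(obj.lower, obj.upper)
            assert np.array_equal(p.y, first)
            assert np.array_equal(p.y_second, second)

    def test_consumes_exactly_two_evaluations_per_particle(self):
        obj = make_sphere()
        initialize_swarm(obj, OptimizerConfig(n_particles=30, seed=0), np.random.default_rng(0))
        assert obj.n_evaluations == 60

    def test_non_finite_fitness_aborts_with_diagnostic(self):
        obj = Objective(lambda x: float("nan"), [0.0], [1.0])
        with pytest.raises(ValueError, match="particle 0"):
            initialize_swarm(obj, OptimizerConfig(n_particles=2, seed=0), np.random.default_rng(0))


class TestMemoryUpdate:
    @pytest.mark.parametrize(
        "candidate_fitness, expected",
        [
            (1.0, (1.0, 2.0)),  # better than best: demotes the old best
            (3.0, (2.0, 3.0)),  # between the layers: replaces second only
            (2.0, (2.0, 2.0)),  # equal to best: goes to the second layer
            (9.0, (2.0, 4.0)),  # worse than both: discarded
        ],
    )
    def test_hierarchical_update(self, candidate_fitness, expected):
        p = particle(2.0, 4.0)
        update_memory(p, np.array([7.0, 7.0]), candidate_fitness)
        assert (p.f_y, p.f_y_second) == expected

    def test_non_finite_candidate_discarded_with_warning(self):
        p = particle(2.0, 4.0)
        with pytest.warns(RuntimeWarning):
            update_memory(p, np.array([0.0, 0.0]), float("nan"))
        assert (p.f_y, p.f_y_second) == (2.0, 4.0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    def test_fuzz_ordering_invariant_and_two_best_oracle(self, fitnesses):
        """After any candidate sequence: f_y <= f_y_second, and the memories
        hold the two best values ever offered (including the initial pair)."""
        p = particle(2.0, 4.0)
        for f in fitnesses:
            update_memory(p, np.array([f, f]), f)
            assert p.f_y <= p.f_y_second
        expected = sorted([2.0, 4.0] + fitnesses)[:2]
        assert [p.f_y, p.f_y_second] == expected


class TestCandidateGeneration:
    def test_identical_parents_return_exactly_that_point(self):
        obj = make_sphere(3)
        v = np.array([1.0, -2.0, 0.5])
        out = generate_candidate(v, v, obj, np.random.default_rng(0))
        assert np.array_equal(out, v)

    def test_zero_spread_coordinate_is_exact(self):
        obj = make_sphere(2, half_width=10.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = generate_candidate(np.array([0.0, 5.0]), np.array([2.0, 5.0]), obj, rng)
            assert out[1] == 5.0

    def test_monte_carlo_moments(self):
        """Sample mean -> (p1+p2)/2 and sample std -> |p1-p2|, within 4 SE."""
        obj = make_sphere(2, half_width=100.0)  # wide box: clipping never triggers
        rng = np.random.default_rng(42)
        p1, p2 = np.array([0.0, 0.0]), np.array([2.0, 4.0])
        draws = np.array([generate_candidate(p1, p2, obj, rng) for _ in range(100_000)])
        n = len(draws)
        mean, std = draws.mean(axis=0), draws.std(axis=0)
        target_mean, target_std = np.array([1.0, 2.0]), np.array([2.0, 4.0])
        se_mean = target_std / np.sqrt(n)
        se_std = target_std / np.sqrt(2 * n)
        assert np.all(np.abs(mean - target_mean) < 4 * se_mean)
        assert np.all(np.abs(std - target_std) < 4 * se_std)

    def test_candidates_respect_bounds(self):
        obj = make_sphere(2, half_width=1.0)
        rng = np.random.default_rng(2)
        for _ in range(200):
            out = generate_candidate(np.array([-1.0, -1.0]), np.array([1.0, 1.0]), obj, rng)
            assert np.all(out >= obj.lower) and np.all(out <= obj.upper)


class TestPairingAndCombinations:
    def test_lower_fitness_leads(self):
        particles = [particle(2.0, 3.0, index=0), particle(1.0, 5.0, index=1)]
        (leader, worker), = pair_particles(particles, np.random.default_rng(0))
        assert (leader, worker) == (1, 0)

    def test_equal_fitness_tie_breaks_to_lower_index(self):
        particles = [particle(1.0, 2.0, index=0), particle(1.0, 2.0, index=1)]
        for seed in range(5):
            (leader, worker), = pair_particles(particles, np.random.default_rng(seed))
            assert (leader, worker) == (0, 1)

    def test_even_swarm_partitions_into_pairs(self):
        particles = [particle(float(i), float(i) + 1, index=i) for i in range(30)]
        pairs = pair_particles(particles, np.random.default_rng(7))
        assert len(pairs) == 15
        seen = sorted(i for pair in pairs for i in pair)
        assert seen == list(range(30))

    def test_odd_swarm_leaves_a_global_led_worker(self):
        particles = [particle(float(i), float(i) + 1, index=i) for i in range(5)]
        pairs = pair_particles(particles, np.random.default_rng(0))
        assert len(pairs) == 3
        assert pairs[-1][0] is None

    def test_pairing_requires_two_particles(self):
        with pytest.raises(ValueError):
            pair_particles([particle(1.0, 2.0)], np.random.default_rng(0))

    def test_combination_lists_are_canonical(self):
        leader = particle(1.0, 2.0, index=0)
        worker = particle(3.0, 4.0, index=1)
        gm = GlobalMemory(
            gbest=np.full(2, -1.0), gbest_fitness=0.5,
            gsecond=np.full(2, -2.0), gsecond_fitness=0.7,
        )
        lead = candidate_combinations("leader", (leader, worker), gm)
        work = candidate_combinations("worker", (leader, worker), gm)
        assert len(lead) == len(work) == 4
        globals_ = [gm.gbest, gm.gsecond]
        for p1, p2 in lead:
            assert any(p1 is g for g in globals_)
            assert p2 is leader.y or p2 is leader.y_second
        for p1, p2 in work:
            assert p1 is leader.y or p1 is leader.y_second
            assert p2 is worker.y or p2 is worker.y_second
        # canonical order: global memory alternates, leader memory layer switches halfway
        assert lead[0][0] is gm.gbest and lead[1][0] is gm.gsecond
        assert lead[0][1] is leader.y and lead[2][1] is leader.y_second

    def test_unknown_role_rejected(self):
        gm = GlobalMemory(np.zeros(1), 0.0, np.zeros(1), 1.0)
        with pytest.raises(ValueError):
            candidate_combinations("boss", (particle(1, 2), particle(3, 4)), gm)


class TestDropout:
    def test_selects_two_distinct_entries(self):
        combos = [(np.array([i]), np.array([i])) for i in range(4)]
        rng = np.random.default_rng(0)
        for _ in range(100):
            chosen = dropout_select(combos, rng)
            assert len(chosen) == 2
            ids = [int(c[0][0]) for c in chosen]
            assert ids[0] != ids[1]

    def test_uniform_selection_frequency(self):
        """Each combination appears in the selected pair with frequency 1/2."""
        combos = [(np.array([i]), np.array([i])) for i in range(4)]
        rng = np.random.default_rng(123)
        hits = np.zeros(4)
        trials = 10_000
        for _ in range(trials):
            for c in dropout_select(combos, rng):
                hits[int(c[0][0])] += 1
        freq = hits / trials
        assert np.all(np.abs(freq - 0.5) < 0.02)

    def test_rejects_wrong_count(self):
        with pytest.raises(ValueError):
            dropout_select([(np.zeros(1), np.zeros(1))] * 3, np.random.default_rng(0))


class TestConsolidation:
    def test_two_lowest_of_pooled_memories(self):
        particles = [particle(3.0, 5.0, index=0), particle(1.0, 4.0, index=1)]
        gm = consolidate_global_memory(particles)
        assert (gm.gbest_fitness, gm.gsecond_fitness) == (1.0, 3.0)

    def test_single_particle_pool(self):
        gm = consolidate_global_memory([particle(2.0, 7.0)])
        assert (gm.gbest_fitness, gm.gsecond_fitness) == (2.0, 7.0)

    def test_both_entries_may_share_a_particle(self):
        particles = [particle(1.0, 1.5, index=0), particle(2.0, 3.0, index=1)]
        gm = consolidate_global_memory(particles)
        assert (gm.gbest_fitness, gm.gsecond_fitness) == (1.0, 1.5)

    def test_matches_sorted_pool_oracle_on_random_swarms(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            fits = np.sort(rng.uniform(0, 10, size=(8, 2)), axis=1)
            particles = [
                particle(float(a), float(b), index=i) for i, (a, b) in enumerate(fits)
            ]
            gm = consolidate_global_memory(particles)
            pooled = np.sort(fits.ravel())
            assert gm.gbest_fitness == pooled[0]
            assert gm.gsecond_fitness == pooled[1]

    def test_empty_swarm_rejected(self):
        with pytest.raises(ValueError):
            consolidate_global_memory([])


class TestOptimize:
    def test_sphere_trace_non_increasing_and_budgeted(self, sphere):
        trace = optimize(sphere, OptimizerConfig(n_particles=30, max_iterations=100, seed=1))
        assert np.all(np.diff(trace.best_fitness_per_iteration) <= 0)
        assert np.all(trace.evaluations_per_iteration == 60)
        assert sphere.n_evaluations == 6060  # 2N init + 2N per iteration

    def test_odd_swarm_keeps_two_evaluations_per_particle(self):
        obj = make_sphere()
        trace = optimize(obj, OptimizerConfig(n_particles=5, max_iterations=20, seed=2))
        assert np.all(trace.evaluations_per_iteration == 10)

    def test_identical_seed_gives_bit_identical_traces(self):
        t1 = optimize(make_sphere(), OptimizerConfig(max_iterations=30, seed=9))
        t2 = optimize(make_sphere(), OptimizerConfig(max_iterations=30, seed=9))
        assert np.array_equal(t1.best_fitness_per_iteration, t2.best_fitness_per_iteration)
        assert np.array_equal(t1.global_memory.gbest, t2.global_memory.gbest)

    def test_convergence_on_sphere(self):
        """Median final best over 20 seeds < 1% of the initial best."""
        ratios = []
        for seed in range(20):
            obj = make_sphere()
            trace = optimize(obj, OptimizerConfig(n_particles=30, max_iterations=100, seed=seed))
            ratios.append(
                trace.best_fitness_per_iteration[-1] / trace.best_fitness_per_iteration[0]
            )
        assert np.median(ratios) < 1e-2

    def test_trace_exports(self, sphere, tmp_path):
        trace = optimize(sphere, OptimizerConfig(max_iterations=5, seed=0))
        assert '"seed": 0' in trace.to_json()
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        assert out.read_text().startswith("iteration,best_fitness,evaluations")


class TestStandardPSO:
    def test_identical_seed_identical_trace(self):
        t1 = optimize_standard_pso(make_sphere(), OptimizerConfig(max_iterations=30, seed=4))
        t2 = optimize_standard_pso(make_sphere(), OptimizerConfig(max_iterations=30, seed=4))
        assert np.array_equal(t1.best_fitness_per_iteration, t2.best_fitness_per_iteration)

    def test_improves_on_sphere_for_nearly_all_seeds(self):
        improved = 0
        for seed in range(100):
            obj = make_sphere()
            trace = optimize_standard_pso(
                obj, OptimizerConfig(n_particles=30, max_iterations=100, seed=seed)
            )
            if trace.best_fitness_per_iteration[-1] < trace.best_fitness_per_iteration[0]:
                improved += 1
        assert improved >= 95

    def test_zero_width_bounds_collapse(self):
        obj = Objective(lambda x: float((x**2).sum()), [2.0, 2.0], [2.0, 2.0])
        trace = optimize_standard_pso(obj, OptimizerConfig(n_particles=5, max_iterations=10, seed=0))
        assert np.all(trace.best_fitness_per_iteration == 8.0)
        assert np.array_equal(trace.global_memory.gbest, [2.0, 2.0])
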
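import math

import numpy as np
import pytest

from cherryrules import (
    EvolutionConfig,
    Individual,
    ObjectiveVector,
    RuleGenome,
    TentMapStream,
    binary_tournament,
    chaotic_mutation,
    crossover,
    dominates,
    environmental_selection,
    evolve,
    tent_sequence,
)
from cherryrules.spea2 import (
    EvolutionError,
    assign_density,
    assign_fitness,
    assign_raw_fitness,
    assign_strength,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (no vectorisation, no shared code paths)


def oracle_dominates(a, b):
    ge = all(x >= y for x, y in zip(a, b))
    gt = any(x > y for x, y in zip(a, b))
    return ge and gt


def oracle_fitness(objs, k):
    n = len(objs)
    S = [sum(oracle_dominates(objs[i], objs[j]) for j in range(n)) for i in range(n)]
    R = [
        sum(S[j] for j in range(n) if oracle_dominates(objs[j], objs[i]))
        for i in range(n)
    ]
    D = []
    for i in range(n):
        dists = sorted(
            math.dist(objs[i], objs[j]) for j in range(n) if j != i
        )
        sigma = dists[min(k, n - 1) - 1]
        D.append(1.0 / (sigma + 2.0))
    F = [r + d for r, d in zip(R, D)]
    return S, R, D, F


def _pool(objs):
    g = RuleGenome(np.full(3, 0.5), np.zeros(3), np.ones(3))
    return [
        Individual(g, ObjectiveVector(*map(float, o))) for o in objs
    ]


class TestDominance:
    def test_strict_in_two_equal_in_one(self):
        assert dominates(ObjectiveVector(0.8, 0.7, 0.6), ObjectiveVector(0.7, 0.7, 0.5))

    def test_identical_vectors_do_not_dominate(self):
        v = ObjectiveVector(0.5, 0.5, 0.5)
        assert not dominates(v, v)

    def test_incomparable_pair(self):
        a, b = ObjectiveVector(0.9, 0.2, 0.5), ObjectiveVector(0.1, 0.9, 0.5)
        assert not dominates(a, b) and not dominates(b, a)


class TestFitnessAssignment:
    def test_strength_on_dominance_chain(self):
        pool = _pool([(0.9, 0.9, 0.9), (0.5, 0.5, 0.5), (0.1, 0.1, 0.1)])
        assign_strength(pool)
        assert [i.S for i in pool] == [2, 1, 0]

    def test_strength_zero_when_incomparable(self):
        pool = _pool([(0.9, 0.1, 0.5), (0.1, 0.9, 0.5), (0.5, 0.5, 0.1)])
        assign_strength(pool)
        assert [i.S for i in pool] == [0, 0, 0]

    def test_duplicates_contribute_no_strength(self):
        pool = _pool([(0.5, 0.5, 0.5), (0.5, 0.5, 0.5)])
        assign_strength(pool)
        assert [i.S for i in pool] == [0, 0]

    def test_raw_fitness_on_chain(self):
        pool = _pool([(0.9, 0.9, 0.9), (0.5, 0.5, 0.5), (0.1, 0.1, 0.1)])
        assign_strength(pool)
        assign_raw_fitness(pool)
        assert [i.R for i in pool] == [0, 2, 3]

    def test_density_two_points_distance_one(self):
        pool = _pool([(0.0, 0.0, 0.0), (1.0, 0.0, 0.0)])
        assign_density(pool, k=1)
        assert [i.D for i in pool] == pytest.approx([1 / 3, 1 / 3])

    def test_density_coincident_points(self):
        pool = _pool([(0.3, 0.3, 0.3), (0.3, 0.3, 0.3)])
        assign_density(pool, k=1)
        assert [i.D for i in pool] == pytest.approx([0.5, 0.5])

    def test_density_singleton_convention(self):
        pool = _pool([(0.3, 0.3, 0.3)])
        assign_density(pool, k=1)
        assert pool[0].D == 0.5

    def test_matches_brute_force_oracle_on_random_pools(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            n = int(rng.integers(2, 50))
            objs = [tuple(rng.uniform(size=3)) for _ in range(n)]
            k = int(rng.integers(1, n))
            pool = _pool(objs)
            assign_fitness(pool, k)
            S, R, D, F = oracle_fitness(objs, k)
            assert [i.S for i in pool] == S
            assert [i.R for i in pool] == R
            np.testing.assert_allclose([i.D for i in pool], D, atol=1e-12)
            np.testing.assert_allclose([i.F for i in pool], F, atol=1e-12)

    def test_fitness_below_one_iff_nondominated(self):
        rng = np.random.default_rng(77)
        objs = [tuple(rng.uniform(size=3)) for _ in range(40)]
        pool = _pool(objs)
        assign_fitness(pool, k=6)
        for i, ind in enumerate(pool):
            nondom = not any(
                oracle_dominates(objs[j], objs[i]) for j in range(len(objs))
            )
            assert (ind.F < 1.0) == nondom


class TestEnvironmentalSelection:
    def _selected(self, objs, capacity, k=1):
        pool = _pool(objs)
        assign_fitness(pool, k)
        return environmental_selection(pool, capacity, k), pool

    def test_truncation_removes_most_crowded(self):
        objs = [(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (0.0, 0.9, 0.1)]
        archive, pool = self._selected(objs, capacity=2)
        kept = {tuple(i.obj.as_array()) for i in archive}
        assert (0.0, 0.9, 0.1) not in kept
        assert len(archive) == 2

    def test_underfull_archive_filled_with_lowest_f_dominated(self):
        objs = [
            (0.9, 0.9, 0.9), (0.8, 0.95, 0.9),         # non-dominated pair
            (0.5, 0.5, 0.5), (0.4, 0.4, 0.4), (0.1, 0.1, 0.1),
        ]
        archive, pool = self._selected(objs, capacity=4, k=2)
        assert len(archive) == 4
        fs = sorted(i.F for i in pool if i.F >= 1.0)
        filled = sorted(i.F for i in archive if i.F >= 1.0)
        assert filled == pytest.approx(fs[:2])

    def test_exact_capacity_returns_nondominated_set(self):
        objs = [(0.9, 0.1, 0.5), (0.1, 0.9, 0.5), (0.05, 0.05, 0.05)]
        archive, _ = self._selected(objs, capacity=2)
        assert {tuple(i.obj.as_array()) for i in archive} == {
            (0.9, 0.1, 0.5), (0.1, 0.9, 0.5),
        }

    def test_capacity_must_be_positive(self):
        pool = _pool([(0.5, 0.5, 0.5)])
        assign_fitness(pool, 1)
        with pytest.raises(EvolutionError):
            environmental_selection(pool, 0, 1)


class TestTournament:
    class _FixedDraw:
        def __init__(self, pairs):
            self._pairs = iter(pairs)

        def integers(self, low, high, size):
            return np.array(next(self._pairs))

    def test_lower_fitness_wins_when_both_drawn(self):
        pool = _pool([(0.9, 0.9, 0.9), (0.1, 0.1, 0.1)])
        pool[0].F, pool[1].F = 0.2, 1.5
        rng = self._FixedDraw([(0, 1), (1, 0)])
        assert binary_tournament(pool, rng).F == 0.2
        assert binary_tournament(pool, rng).F == 0.2

    def test_tie_goes_to_first_drawn(self):
        pool = _pool([(0.9, 0.9, 0.9), (0.1, 0.1, 0.1)])
        pool[0].F = pool[1].F = 0.4
        rng = self._FixedDraw([(1, 0)])
        assert binary_tournament(pool, rng) is pool[1]

    def test_singleton_archive(self):
        pool = _pool([(0.5, 0.5, 0.5)])
        pool[0].F = 0.4
        assert binary_tournament(pool, np.random.default_rng(1)) is pool[0]

    def test_empty_archive_rejected(self):
        with pytest.raises(EvolutionError):
            binary_tournament([], np.random.default_rng(0))

    def test_win_probability_is_three_quarters(self):
        """P(better wins) = P(drawn at least once) = 1 - (1/2)^2 = 0.75."""
        pool = _pool([(0.9, 0.9, 0.9), (0.1, 0.1, 0.1)])
        pool[0].F, pool[1].F = 0.2, 0.9
        rng = np.random.default_rng(123)
        wins = sum(binary_tournament(pool, rng).F == 0.2 for _ in range(10_000))
        assert wins / 10_000 == pytest.approx(0.75, abs=0.015)


class TestVariation:
    def _parents(self, rng, d=10):
        return (
            RuleGenome(*rng.uniform(size=(3, d))),
            RuleGenome(*rng.uniform(size=(3, d))),
        )

    def test_no_crossover_copies_parents(self):
        rng = np.random.default_rng(3)
        pa, pb = self._parents(rng)
        ca, cb = crossover(pa, pb, p_c=0.0, rng=rng)
        np.testing.assert_array_equal(ca.as_matrix(), pa.as_matrix())
        np.testing.assert_array_equal(cb.as_matrix(), pb.as_matrix())
        assert ca is not pa  # copies, not aliases

    def test_gene_triples_conserved(self):
        """The multiset of per-feature (incl, lo, hi) triples is invariant."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            pa, pb = self._parents(rng)
            ca, cb = crossover(pa, pb, p_c=1.0, rng=rng)
            before = np.concatenate([pa.as_matrix(), pb.as_matrix()], axis=1)
            after = np.concatenate([ca.as_matrix(), cb.as_matrix()], axis=1)
            # compare as sorted sets of column triples
            before_cols = sorted(map(tuple, before.T))
            after_cols = sorted(map(tuple, after.T))
            assert before_cols == after_cols

    def test_no_mutation_is_identity(self):
        rng = np.random.default_rng(6)
        g = RuleGenome(*rng.uniform(size=(3, 10)))
        out = chaotic_mutation(g, 0.0, TentMapStream(0.3), rng)
        np.testing.assert_array_equal(out.as_matrix(), g.as_matrix())

    def test_full_mutation_takes_tent_values_in_order(self):
        rng = np.random.default_rng(7)
        g = RuleGenome(*np.full((3, 2), 0.5))
        out = chaotic_mutation(g, 1.0, TentMapStream(0.3), rng)
        np.testing.assert_allclose(
            out.as_matrix().ravel(), tent_sequence(0.3, 6)
        )

    def test_mutation_rate_and_range_statistics(self):
        rng = np.random.default_rng(8)
        stream = TentMapStream(0.456)
        changed = total = 0
        for _ in range(350):
            g = RuleGenome(*rng.uniform(size=(3, 100)))
            out = chaotic_mutation(g, 0.1, stream, rng)
            m = out.as_matrix()
            assert ((m > 0) & (m < 1)).all()
            changed += int((m != g.as_matrix()).sum())
            total += m.size
        assert changed / total == pytest.approx(0.1, abs=0.002)


class TestEvolve:
    def test_zero_generations_selects_initial_population(self, planted_dataset):
        cfg = EvolutionConfig(max_generations=0, prng_seed=1)
        rs = evolve(planted_dataset, "H", cfg)
        assert len(rs) >= 1

    def test_returned_set_is_mutually_nondominated(self, planted_dataset):
        cfg = EvolutionConfig(max_generations=15, prng_seed=2)
        rs = evolve(planted_dataset, "H", cfg)
        for i, a in enumerate(rs.objectives):
            for j, b in enumerate(rs.objectives):
                if i != j:
                    assert not dominates(a, b)

    def test_deterministic_given_seeds(self, planted_dataset):
        cfg = EvolutionConfig(max_generations=10, prng_seed=9, chaos_seed=0.33)
        a = evolve(planted_dataset, "H", cfg)
        b = evolve(planted_dataset, "H", cfg)
        assert [r for r in a.rules] == [r for r in b.rules]
        assert a.objectives == b.objectives

    def test_single_class_dataset_rejected(self, planted_dataset):
        only_h = planted_dataset.subset(planted_dataset.labels == "H")
        with pytest.raises(EvolutionError):
            evolve(only_h, "H", EvolutionConfig(max_generations=1))

    def test_missing_target_class_rejected(self, planted_dataset):
        no_m = planted_dataset.subset(planted_dataset.labels != "M")
        with pytest.raises(EvolutionError):
            evolve(no_m, "M", EvolutionConfig(max_generations=1))

    def test_archive_capacity_respected_throughout(self, planted_dataset):
        sizes = []
        cfg = EvolutionConfig(max_generations=12, archive_size=8, prng_seed=3)
        evolve(
            planted_dataset, "H", cfg,
            on_generation=lambda g, pop, arch: sizes.append(len(arch)),
        )
        assert sizes and all(s <= 8 for s in sizes)


class TestConfigValidation:
    def test_default_knn_k_is_sqrt_of_pool(self):
        assert EvolutionConfig().effective_k() == round(math.sqrt(40))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 1},
            {"crossover_prob": 1.5},
            {"mutation_prob": -0.1},
            {"chaos_seed": 0.0},
            {"knn_k": 0},
            {"knn_k": 40},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(EvolutionError):
            EvolutionConfig(**kwargs)
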
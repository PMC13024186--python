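"""Chaos-embedded SPEA2 evolutionary loop for interval-rule mining.

Strength-Pareto fitness: every individual i in the union of population
and archive gets

* strength S(i) — the number of pool members it dominates;
* raw fitness R(i) — the sum of the strengths of its dominators
  (0 exactly for non-dominated members);
* density D(i) = 1 / (sigma_k + 2), sigma_k the Euclidean distance in
  objective space to the k-th nearest other member;
* fitness F(i) = R(i) + D(i), minimised.

Because D <= 1/2, F < 1 holds exactly for the non-dominated members, and
environmental selection admits them all, filling an under-full archive
with the best dominated individuals and truncating an over-full one by
repeatedly removing the most crowded member.

Chaos enters in exactly two places: the initial population is filled
row-major from one guarded tent-map stream, and chaotic mutation replaces
mutating genes with the next values of that same stream.  All other
randomness (tournament draws, crossover decisions and masks, mutation
coin flips) uses an ordinary seeded PRNG, so a run is fully determined by
the pair (chaos_seed, prng_seed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chaos import TentMapStream
from .dataset_io import LabeledDataset
from .rule_model import (
    ObjectiveVector,
    ParetoRuleSet,
    Rule,
    RuleGenome,
    decode_genome,
    evaluate_rule,
    objectives,
)


class EvolutionError(ValueError):
    """The evolutionary run cannot proceed (degenerate data or config)."""


@dataclass
class Individual:
    """A candidate rule with its objectives and SPEA2 bookkeeping."""

    genome: RuleGenome
    obj: ObjectiveVector | None = None
    S: int = 0
    R: int = 0
    D: float = 0.0
    F: float = 0.0


@dataclass
class EvolutionConfig:
    """Parameters of one evolutionary rule-mining run.

    Defaults mirror the experimental protocol: population and archive of
    20, inclusion threshold 0.5, crossover probability 0.8 and mutation
    probability 0.1; the generation budget defaults to 100.
    """

    population_size: int = 20
    archive_size: int = 20
    max_generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    lambda_threshold: float = 0.5
    knn_k: int | None = None
    chaos_seed: float = 0.7
    prng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.archive_size < 2:
            raise EvolutionError("population and archive sizes must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise EvolutionError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.lambda_threshold < 1.0:
            raise EvolutionError("lambda_threshold must lie in (0, 1)")
        if not 0.0 < self.chaos_seed < 1.0:
            raise EvolutionError("chaos_seed must lie strictly in (0, 1)")
        if self.max_generations < 0:
            raise EvolutionError("max_generations must be non-negative")
        k = self.effective_k()
        if not 1 <= k < self.population_size + self.archive_size:
            raise EvolutionError("knn_k must satisfy 1 <= k < N + N_archive")

    def effective_k(self) -> int:
        """The density neighbour index: round(sqrt(N + N_archive)) by default."""
        if self.knn_k is not None:
            return self.knn_k
        return int(round(math.sqrt(self.population_size + self.archive_size)))


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """Pareto dominance over (accuracy, precision, recall), maximised."""
    av, bv = a.as_array(), b.as_array()
    return bool(np.all(av >= bv) and np.any(av > bv))


def _objective_matrix(pool: Sequence[Individual]) -> np.ndarray:
    return np.array([ind.obj.as_array() for ind in pool])


def _dominance_matrix(objs: np.ndarray) -> np.ndarray:
    """dom[i, j] is True iff individual i dominates individual j."""
    ge = np.all(objs[:, None, :] >= objs[None, :, :], axis=2)
    gt = np.any(objs[:, None, :] > objs[None, :, :], axis=2)
    return ge & gt


def assign_strength(pool: Sequence[Individual]) -> None:
    """S(i): how many pool members individual i dominates."""
    dom = _dominance_matrix(_objective_matrix(pool))
    for ind, s in zip(pool, dom.sum(axis=1)):
        ind.S = int(s)


def assign_raw_fitness(pool: Sequence[Individual]) -> None:
    """R(i): summed strengths of all dominators of i (0 if non-dominated)."""
    dom = _dominance_matrix(_objective_matrix(pool))
    S = np.array([ind.S for ind in pool])
    raw = S @ dom  # raw[i] = sum_j S[j] * dom[j, i]
    for ind, r in zip(pool, raw):
        ind.R = int(r)


def assign_density(pool: Sequence[Individual], k: int) -> None:
    """D(i) = 1 / (sigma_k + 2) from k-th nearest neighbour distances.

    ``k`` is clamped to the pool size minus one; a singleton pool gets
    the limiting value D = 1/2 (sigma treated as 0).
    """
    n = len(pool)
    if n == 1:
        pool[0].D = 0.5
        return
    if k < 1:
        raise ValueError("k must be positive")
    k = min(k, n - 1)
    objs = _objective_matrix(pool)
    diff = objs[:, None, :] - objs[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    np.fill_diagonal(dist, np.inf)
    part = np.sort(dist, axis=1)
    for ind, sigma in zip(pool, part[:, k - 1]):
        ind.D = 1.0 / (float(sigma) + 2.0)


def assign_fitness(pool: Sequence[Individual], k: int) -> None:
    """Full SPEA2 fitness assignment: S, R, D, then F = R + D."""
    assign_strength(pool)
    assign_raw_fitness(pool)
    assign_density(pool, k)
    for ind in pool:
        ind.F = ind.R + ind.D


def _truncate(members: list[Individual], capacity: int) -> list[Individual]:
    """Iteratively drop the most crowded member until capacity is met.

    The removed member is the one with the lexicographically smallest
    sorted vector of distances to all remaining members; remaining ties
    fall to the lowest index.
    """
    members = list(members)
    objs = _objective_matrix(members)
    diff = objs[:, None, :] - objs[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    alive = list(range(len(members)))
    while len(alive) > capacity:
        sub = dist[np.ix_(alive, alive)]
        np.fill_diagonal(sub, np.inf)
        ranked = np.sort(sub, axis=1)
        # lexicographic argmin over sorted distance rows, lowest index wins ties
        victim = 0
        for i in range(1, len(alive)):
            for a, b in zip(ranked[i], ranked[victim]):
                if a != b:
                    if a < b:
                        victim = i
                    break
        alive.pop(victim)
    return [members[i] for i in alive]


def environmental_selection(
    pool: Sequence[Individual], capacity: int, k: int
) -> list[Individual]:
    """SPEA2 archive update from a fitness-assigned pool.

    All individuals with F < 1 (the non-dominated set) enter; if fewer
    than ``capacity`` the archive is filled with dominated individuals in
    ascending F order, and if more the truncation operator removes the
    most crowded members one at a time.
    """
    if capacity < 1:
        raise EvolutionError("archive capacity must be positive")
    nondom = [ind for ind in pool if ind.F < 1.0]
    if len(nondom) > capacity:
        return _truncate(nondom, capacity)
    if len(nondom) < capacity:
        dominated = sorted(
            (ind for ind in pool if ind.F >= 1.0), key=lambda ind: ind.F
        )
        nondom = nondom + dominated[: capacity - len(nondom)]
    return list(nondom)


def binary_tournament(
    archive: Sequence[Individual], rng: np.random.Generator
) -> Individual:
    """Draw two archive members with replacement; lower fitness F wins."""
    if not archive:
        raise EvolutionError("cannot select from an empty archive")
    i, j = rng.integers(0, len(archive), size=2)
    a, b = archive[int(i)], archive[int(j)]
    return a if a.F <= b.F else b


def crossover(
    parent_a: RuleGenome,
    parent_b: RuleGenome,
    p_c: float,
    rng: np.random.Generator,
) -> tuple[RuleGenome, RuleGenome]:
    """Uniform crossover at gene-triple granularity.

    With probability ``p_c`` the whole (incl, lo, hi) triple of each
    feature is swapped between the offspring with probability 1/2,
    keeping interval encodings coherent; otherwise the offspring are
    plain copies of the parents.
    """
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal genome length")
    child_a, child_b = parent_a.copy(), parent_b.copy()
    if rng.random() < p_c:
        swap = rng.random(len(parent_a)) < 0.5
        for vec_a, vec_b in (
            (child_a.incl, child_b.incl),
            (child_a.lo, child_b.lo),
            (child_a.hi, child_b.hi),
        ):
            tmp = vec_a[swap].copy()
            vec_a[swap] = vec_b[swap]
            vec_b[swap] = tmp
    return child_a, child_b


def chaotic_mutation(
    genome: RuleGenome,
    p_m: float,
    stream: TentMapStream,
    rng: np.random.Generator,
) -> RuleGenome:
    """Replace each gene, independently with probability ``p_m``, by the
    next value of the shared guarded tent stream.

    The PRNG decides which genes mutate; the tent stream supplies the new
    values, which the guard keeps strictly inside (0, 1).
    """
    flat = genome.as_matrix().ravel()
    hits = np.flatnonzero(rng.random(flat.size) < p_m)
    for idx in hits:
        flat[idx] = stream.next()
    return RuleGenome.from_matrix(flat.reshape(3, -1))


GenerationHook = Callable[[int, list[Individual], list[Individual]], None]


def _evaluate(
    ind: Individual,
    data: LabeledDataset,
    target_class: str,
    lambda_threshold: float,
) -> None:
    rule = decode_genome(ind.genome, data.schema, target_class, lambda_threshold)
    ind.obj = objectives(evaluate_rule(rule, data))


def evolve(
    data: LabeledDataset,
    target_class: str,
    config: EvolutionConfig,
    *,
    on_generation: GenerationHook | None = None,
    trace_path=None,
) -> ParetoRuleSet:
    """Run the chaos-embedded SPEA2 loop for one target class.

    Starting from a chaotically initialised population and an empty
    archive, each generation assigns strength/raw-fitness/density to the
    union pool, performs environmental selection into the archive, then
    breeds a full replacement population by binary tournament on the
    archive, crossover and chaotic mutation.  After the final generation
    one last selection is applied, so ``max_generations = 0`` returns the
    environmental selection of the initial population.  Returns the
    decoded non-dominated rules of the final archive with their training
    objective vectors.
    """
    counts = data.class_counts()
    if counts.get(target_class, 0) == 0:
        raise EvolutionError(f"no samples of target class {target_class}")
    if counts.get(target_class, 0) == len(data):
        raise EvolutionError("dataset contains only the target class")

    d = len(data.schema)
    k = config.effective_k()
    stream = TentMapStream(config.chaos_seed)
    rng = np.random.default_rng(config.prng_seed)

    init = stream.take(config.population_size * 3 * d).reshape(
        config.population_size, 3, d
    )
    population = [Individual(RuleGenome.from_matrix(m)) for m in init]
    for ind in population:
        _evaluate(ind, data, target_class, config.lambda_threshold)

    archive: list[Individual] = []
    trace_file = None
    writer = None
    if trace_path is not None:
        trace_file = open(trace_path, "w", newline="")
        writer = csv.writer(trace_file)
        writer.writerow(
            ["generation", "archive_size", "best_accuracy", "mean_accuracy",
             "best_precision", "best_recall"]
        )
    try:
        for gen in range(config.max_generations + 1):
            pool = population + archive
            assign_fitness(pool, k)
            archive = environmental_selection(pool, config.archive_size, k)
            if on_generation is not None:
                on_generation(gen, list(population), list(archive))
            if writer is not None:
                accs = [ind.obj.accuracy for ind in archive]
                writer.writerow(
                    [gen, len(archive), max(accs),
                     float(np.mean(accs)),
                     max(ind.obj.precision for ind in archive),
                     max(ind.obj.recall for ind in archive)]
                )
            if gen == config.max_generations:
                break
            offspring: list[Individual] = []
            while len(offspring) < config.population_size:
                pa = binary_tournament(archive, rng)
                pb = binary_tournament(archive, rng)
                ca, cb = crossover(
                    pa.genome, pb.genome, config.crossover_prob, rng
                )
                for child_genome in (ca, cb):
                    if len(offspring) >= config.population_size:
                        break
                    mutated = chaotic_mutation(
                        child_genome, config.mutation_prob, stream, rng
                    )
                    child = Individual(mutated)
                    _evaluate(child, data, target_class, config.lambda_threshold)
                    offspring.append(child)
            population = offspring
    finally:
        if trace_file is not None:
            trace_file.close()

    # keep only the truly non-dominated members (fill individuals drop out)
    final = [ind for ind in archive if ind.R == 0]
    rules = [
        decode_genome(ind.genome, data.schema, target_class, config.lambda_threshold)
        for ind in final
    ]
    objs = [ind.obj for ind in final]
    result = ParetoRuleSet(rules=rules, objectives=objs, target_class=target_class)
    for i, a in enumerate(result.objectives):
        for j, b in enumerate(result.objectives):
            if i != j and dominates(a, b):
                raise AssertionError("archive returned a dominated rule")
    return result
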
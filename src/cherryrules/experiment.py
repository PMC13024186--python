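"""Repeated-experiment harness: per-class one-vs-rest runs and statistics.

The mining protocol runs the evolutionary loop separately per target
class (one-vs-rest), repeating each run with a fresh stratified 70/30
split and fresh seeds, then summarises the per-run best accuracy,
precision and recall on both splits with min/max/mean/median/std — the
shape of the study's reported statistics tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chaos import EPS, GOLDEN_RATIO_FRAC
from .dataset_io import CLASS_LABELS, LabeledDataset, stratified_split
from .rule_model import (
    ObjectiveVector,
    ParetoRuleSet,
    evaluate_rule,
    objectives,
    rule_to_text,
)
from .spea2 import EvolutionConfig, evolve

_METRICS = ("accuracy", "precision", "recall")
_STATS = ("min", "max", "mean", "median", "std")


@dataclass
class RunResult:
    """One evolutionary run: the rule set and per-rule objectives."""

    run_index: int
    rule_set: ParetoRuleSet
    train_objectives: list[ObjectiveVector]
    test_objectives: list[ObjectiveVector]


@dataclass
class ExperimentReport:
    """All runs of a repeated experiment plus aggregate statistics."""

    runs: dict[str, list[RunResult]]
    aggregates: pd.DataFrame  # columns: class, phase, metric, min..std

    def aggregate(self, label: str, phase: str, metric: str, stat: str) -> float:
        frame = self.aggregates
        row = frame[
            (frame["class"] == label)
            & (frame["phase"] == phase)
            & (frame["metric"] == metric)
        ]
        return float(row[stat].iloc[0])


def _derive_chaos_seed(base: float, run: int) -> float:
    """A distinct tent-map seed per run, kept strictly inside (0, 1)."""
    x = (base + run * GOLDEN_RATIO_FRAC) % 1.0
    return min(max(x, EPS), 1.0 - EPS)


def run_experiment(
    data: LabeledDataset,
    config: EvolutionConfig,
    n_runs: int = 10,
    train_fraction: float = 0.7,
    classes: tuple[str, ...] = CLASS_LABELS,
) -> ExperimentReport:
    """Repeat the one-vs-rest mining protocol and aggregate statistics.

    Run ``r`` of every class uses split seed and PRNG seed
    ``config.prng_seed + r`` and a chaos seed derived from
    ``config.chaos_seed`` and ``r``, so both the split and the search are
    re-randomised per run while the whole report stays deterministic
    given the base seeds.  Aggregates summarise, over runs, each metric's
    per-run best value among the returned rules.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    runs: dict[str, list[RunResult]] = {c: [] for c in classes}
    rows = []
    for label in classes:
        best: dict[tuple[str, str], list[float]] = {
            (phase, m): [] for phase in ("train", "test") for m in _METRICS
        }
        for r in range(n_runs):
            train, test = stratified_split(
                data, train_fraction, seed=config.prng_seed + r
            )
            run_cfg = EvolutionConfig(
                population_size=config.population_size,
                archive_size=config.archive_size,
                max_generations=config.max_generations,
                crossover_prob=config.crossover_prob,
                mutation_prob=config.mutation_prob,
                lambda_threshold=config.lambda_threshold,
                knn_k=config.knn_k,
                chaos_seed=_derive_chaos_seed(config.chaos_seed, r),
                prng_seed=config.prng_seed + r,
            )
            rule_set = evolve(train, label, run_cfg)
            test_objs = [
                objectives(evaluate_rule(rule, test)) for rule in rule_set.rules
            ]
            runs[label].append(
                RunResult(r, rule_set, list(rule_set.objectives), test_objs)
            )
            for phase, objs in (("train", rule_set.objectives), ("test", test_objs)):
                for m in _METRICS:
                    best[(phase, m)].append(max(getattr(o, m) for o in objs))
        for phase in ("train", "test"):
            for m in _METRICS:
                vals = np.array(best[(phase, m)])
                rows.append(
                    {
                        "class": label,
                        "phase": phase,
                        "metric": m,
                        "min": vals.min(),
                        "max": vals.max(),
                        "mean": vals.mean(),
                        "median": float(np.median(vals)),
                        "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
    return ExperimentReport(runs=runs, aggregates=pd.DataFrame(rows))


def export_pareto_front(rs: ParetoRuleSet, path) -> None:
    """Write a rule set's objective front to CSV.

    One row per rule with its accuracy, precision, recall and rendered
    text; floats use shortest-repr serialisation so re-import reproduces
    the objective values exactly.
    """
    if len(rs) == 0:
        raise ValueError("cannot export an empty rule set")
    frame = pd.DataFrame(
        {
            "accuracy": [o.accuracy for o in rs.objectives],
            "precision": [o.precision for o in rs.objectives],
            "recall": [o.recall for o in rs.objectives],
            "rule": [rule_to_text(r) for r in rs.rules],
        }
    )
    frame.to_csv(path, index=False)


def read_pareto_front(path) -> pd.DataFrame:
    """Re-import an exported front (floats parsed back exactly)."""
    return pd.read_csv(path)
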
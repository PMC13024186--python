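"""Structural interpretability metrics over Pareto rule sets.

Short conjunctive rules are what make evolutionary rule mining useful to
field experts; these metrics quantify that claim: average and maximum
antecedent length, the fraction of samples covered by at least one rule,
and a feature-importance ranking by occurrence frequency across rules.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .dataset_io import LabeledDataset
from .rule_model import ParetoRuleSet, rule_match_mask


class MetricError(ValueError):
    """A metric was requested on an empty rule set or dataset."""


def average_rule_length(rs: ParetoRuleSet) -> float:
    """Mean number of antecedent conditions per rule (ARL)."""
    if len(rs) == 0:
        raise MetricError("average_rule_length of an empty rule set")
    return float(np.mean([len(r) for r in rs.rules]))


def max_rule_length(rs: ParetoRuleSet) -> int:
    """Largest antecedent condition count among the rules."""
    if len(rs) == 0:
        raise MetricError("max_rule_length of an empty rule set")
    return max(len(r) for r in rs.rules)


def rule_coverage(
    rs: ParetoRuleSet, data: LabeledDataset, *, target_only: bool = False
) -> float:
    """Fraction of samples matched by at least one rule's antecedent (RC).

    By default all samples count, regardless of label; with
    ``target_only`` both the matched set and the denominator are
    restricted to samples of the rule set's target class.
    """
    if len(rs) == 0:
        raise MetricError("rule_coverage of an empty rule set")
    if len(data) == 0:
        raise MetricError("rule_coverage over an empty dataset")
    X, labels = data.X, data.labels
    if target_only:
        keep = labels == rs.target_class
        if not keep.any():
            raise MetricError("no samples of the target class in the data")
        X = X[keep]
    covered = np.zeros(X.shape[0], dtype=bool)
    for rule in rs.rules:
        covered |= rule_match_mask(rule, X, data.schema)
    return float(covered.mean())


def feature_frequency(rs: ParetoRuleSet) -> list[tuple[str, int]]:
    """Per-feature count of rules using that feature, ranked.

    Sorted by descending count, ties broken alphabetically.  A feature
    appearing several times inside one rule (impossible for decoded
    genomes, possible for hand-built rules) still counts once per rule.
    """
    if len(rs) == 0:
        raise MetricError("feature_frequency of an empty rule set")
    counts: Counter[str] = Counter()
    for rule in rs.rules:
        counts.update(set(rule.features))
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def metrics_table(
    rule_sets: dict[str, ParetoRuleSet], data: LabeledDataset
) -> pd.DataFrame:
    """One row per class: ARL, max rule length, RC, dominant features."""
    rows = []
    for label, rs in rule_sets.items():
        freq = feature_frequency(rs)
        rows.append(
            {
                "class": label,
                "average_rule_length": average_rule_length(rs),
                "max_rule_length": max_rule_length(rs),
                "rule_coverage": rule_coverage(rs, data),
                "dominant_features": ", ".join(f for f, _ in freq[:2]),
            }
        )
    return pd.DataFrame(rows)
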
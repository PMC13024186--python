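"""Interval-rule genome encoding, rule matching, and objective metrics.

An individual encodes one candidate if-then rule as three parallel
vectors in [0, 1], one entry per schema feature:

* inclusion scores — feature ``i`` enters the antecedent iff its score
  exceeds the threshold ``lambda``;
* lower-bound scores and upper-bound scores — mapped affinely onto each
  feature's [min, max] range to give the interval endpoints.

The decoded rule is a conjunction of closed intervals over the active
features with a fixed target class; samples of all other classes count as
negatives (one-vs-rest).  Rule quality is the objective triple
(accuracy, precision, recall) computed from the rule's confusion counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .dataset_io import CLASS_LABELS, FeatureSchema, LabeledDataset, Sample


class EvaluationError(ValueError):
    """Rule evaluation was asked for on unusable input."""


@dataclass
class RuleGenome:
    """Three parallel unit-interval vectors: inclusion, lower, upper."""

    incl: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.incl = np.asarray(self.incl, dtype=float)
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if not (self.incl.shape == self.lo.shape == self.hi.shape):
            raise ValueError("genome vectors must have equal length")
        for name, vec in (("incl", self.incl), ("lo", self.lo), ("hi", self.hi)):
            if np.any((vec < 0.0) | (vec > 1.0)):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    def __len__(self) -> int:
        return self.incl.size

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RuleGenome":
        """Build from a (3, n_features) matrix: rows incl, lo, hi."""
        m = np.asarray(m, dtype=float)
        return cls(incl=m[0].copy(), lo=m[1].copy(), hi=m[2].copy())

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.incl, self.lo, self.hi])

    def copy(self) -> "RuleGenome":
        return RuleGenome(self.incl.copy(), self.lo.copy(), self.hi.copy())


class Condition(NamedTuple):
    """One antecedent term: ``lower <= feature <= upper`` (inclusive)."""

    feature: str
    lower: float
    upper: float


@dataclass(frozen=True)
class Rule:
    """A decoded if-then interval rule targeting one infestation class."""

    conditions: tuple[Condition, ...]
    target_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.conditions:
            raise ValueError("a rule needs at least one condition")
        if self.target_class not in CLASS_LABELS:
            raise ValueError(f"target_class must be one of {CLASS_LABELS}")
        for c in self.conditions:
            if c.lower > c.upper:
                raise ValueError(f"condition on {c.feature} has lower > upper")

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(c.feature for c in self.conditions)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a rule against a labeled dataset."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ObjectiveVector:
    """The (accuracy, precision, recall) triple; all maximised."""

    accuracy: float
    precision: float
    recall: float

    def as_array(self) -> np.ndarray:
        return np.array([self.accuracy, self.precision, self.recall])


def decode_genome(
    genome: RuleGenome,
    schema: FeatureSchema,
    target_class: str,
    lambda_threshold: float = 0.5,
) -> Rule:
    """Decode a genome into a rule against the given schema.

    Feature ``i`` is active iff ``incl[i] > lambda_threshold``.  Active
    bounds are ``min_i + score * (max_i - min_i)``; if the decoded lower
    bound exceeds the upper they are swapped.  An all-inactive genome is
    repaired by activating the single feature with the highest inclusion
    score, so decoding is total.
    """
    if len(genome) != len(schema):
        raise ValueError("genome length must match schema size")
    active = genome.incl > lambda_threshold
    if not active.any():
        active[int(np.argmax(genome.incl))] = True
    lo_raw = schema.min_values + genome.lo * schema.ranges
    hi_raw = schema.min_values + genome.hi * schema.ranges
    conditions = []
    for i in np.flatnonzero(active):
        a, b = lo_raw[i], hi_raw[i]
        if a > b:
            a, b = b, a
        conditions.append(Condition(schema.names[i], float(a), float(b)))
    return Rule(tuple(conditions), target_class)


def rule_match_mask(rule: Rule, X: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    """Boolean antecedent-satisfaction mask over the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    mask = np.ones(X.shape[0], dtype=bool)
    for cond in rule.conditions:
        col = X[:, schema.index(cond.feature)]
        mask &= (col >= cond.lower) & (col <= cond.upper)
    return mask


def rule_matches(rule: Rule, sample: Sample, schema: FeatureSchema) -> bool:
    """True iff every condition holds for the sample (inclusive bounds)."""
    return bool(rule_match_mask(rule, sample.values[None, :], schema)[0])


def evaluate_rule(rule: Rule, data: LabeledDataset) -> ConfusionCounts:
    """Confusion counts of a rule over a labeled dataset.

    Per sample: antecedent true and label equals the target -> TP;
    both false -> TN; antecedent true, label different -> FP; antecedent
    false, label equals the target -> FN.
    """
    if len(data) == 0:
        raise EvaluationError("cannot evaluate a rule on an empty dataset")
    matched = rule_match_mask(rule, data.X, data.schema)
    positive = data.labels == rule.target_class
    tp = int(np.sum(matched & positive))
    tn = int(np.sum(~matched & ~positive))
    fp = int(np.sum(matched & ~positive))
    fn = int(np.sum(~matched & positive))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def objectives(counts: ConfusionCounts) -> ObjectiveVector:
    """Accuracy, precision and recall from confusion counts.

    Precision (recall) is defined as 0 when its denominator TP+FP
    (TP+FN) is zero: a rule that never fires earns nothing in a
    maximisation context.
    """
    if counts.total < 1:
        raise ValueError("confusion counts are all zero")
    acc = (counts.TP + counts.TN) / counts.total
    prec = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    rec = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    return ObjectiveVector(accuracy=acc, precision=prec, recall=rec)


def rule_to_text(rule: Rule) -> str:
    """Render a rule as ``IF (lo < name < hi) and ... THEN C``.

    Bounds are printed to three decimals.  The bounds themselves are
    inclusive; the ``<`` glyph is display convention only.
    """
    parts = [
        f"({c.lower:.3f} < {c.feature} < {c.upper:.3f})" for c in rule.conditions
    ]
    return f"IF {' and '.join(parts)} THEN {rule.target_class}"


_RULE_RE = re.compile(r"^IF\s+(.+)\s+THEN\s+([LMH])$")
_COND_RE = re.compile(r"^\(\s*(-?[\d.]+)\s*<\s*(\w+)\s*<\s*(-?[\d.]+)\s*\)$")


def rule_from_text(text: str) -> Rule:
    """Parse the :func:`rule_to_text` rendering back into a rule."""
    m = _RULE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable rule text: {text!r}")
    conds = []
    for part in re.split(r"\s+and\s+", m.group(1)):
        cm = _COND_RE.match(part.strip())
        if not cm:
            raise ValueError(f"unparseable condition: {part!r}")
        conds.append(Condition(cm.group(2), float(cm.group(1)), float(cm.group(3))))
    return Rule(tuple(conds), m.group(2))


@dataclass
class ParetoRuleSet:
    """Mutually non-dominated rules for one target class.

    Each rule carries the objective vector measured on the training split
    it was evolved against.
    """

    rules: list[Rule]
    objectives: list[ObjectiveVector]
    target_class: str

    def __post_init__(self) -> None:
        if len(self.rules) != len(self.objectives):
            raise ValueError("rules and objectives must pair up")
        for r in self.rules:
            if r.target_class != self.target_class:
                raise ValueError("all rules must share the target class")

    def __len__(self) -> int:
        return len(self.rules)

    def best_by(self, metric: str) -> tuple[Rule, ObjectiveVector]:
        """The rule maximising one of accuracy/precision/recall."""
        idx = int(np.argmax([getattr(o, metric) for o in self.objectives]))
        return self.rules[idx], self.objectives[idx]
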
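"""Synthetic pomological datasets.

The field dataset behind the study design (381 cherry fruit samples from
trapped-fly monitoring, classes L/M/H of 204/101/76) is not distributed,
so this module generates stand-ins with the same composition, plus
planted-rule datasets with known ground truth for recovery testing.

The compositional generator draws each feature from a clamped normal
whose centre moves along the feature range with the class: the
``class_shift`` knob interpolates between completely exchangeable class
distributions (a negative control: no classifier should beat the
majority baseline) and cleanly separated ones.  Only the ranges and
counts of the real data are emulated; its covariance structure is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import (
    CLASS_LABELS,
    FeatureSchema,
    LabeledDataset,
    labels_from_trap_counts,
)
from .rule_model import Rule, rule_match_mask


class GenerationError(RuntimeError):
    """Synthetic-data generation failed (infeasible constraints)."""


#: Class composition of the emulated field dataset.
DEFAULT_CLASS_COUNTS: dict[str, int] = {"L": 204, "M": 101, "H": 76}

#: Per-class admissible trap-count ranges (inclusive).  Low and Medium are
#: bounded by the labelling thresholds; the High upper bound of 30 is a
#: generator choice — the field protocol only requires "more than 10".
DEFAULT_TRAP_RANGES: dict[str, tuple[int, int]] = {
    "L": (0, 5),
    "M": (6, 10),
    "H": (11, 30),
}

#: Normal spread as a fraction of each feature range, before clamping.
_FEATURE_SD_FRAC = 0.18


@dataclass
class GeneratorConfig:
    """Configuration of the compositional generator.

    ``class_shift`` in [0, 1] displaces the per-class feature centres:
    0 makes the classes statistically exchangeable, larger values pull
    L below and H above the range midpoint.  The default of 0.25 gives
    overlapping but learnable classes, the regime a field dataset of
    this kind plausibly sits in.
    """

    schema: FeatureSchema = field(default_factory=FeatureSchema.default)
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    trap_count_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TRAP_RANGES)
    )
    class_shift: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_shift <= 1.0:
            raise ValueError("class_shift must lie in [0, 1]")
        for label, count in self.class_counts.items():
            if label not in CLASS_LABELS or count < 1:
                raise ValueError(f"bad class count {label}={count}")
        for label, (lo, hi) in self.trap_count_ranges.items():
            if lo > hi or lo < 0:
                raise ValueError(f"bad trap range for {label}")
            derived = set(labels_from_trap_counts(np.arange(lo, hi + 1)))
            if derived != {label}:
                raise ValueError(
                    f"trap range {lo}-{hi} inconsistent with label {label}"
                )


#: Ordered class offsets applied to the range-midpoint centre.
_CLASS_OFFSETS = {"L": -0.5, "M": 0.0, "H": 0.5}


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate a labeled dataset with the configured composition.

    Every feature value is clamped into the schema range; every sample
    carries a trap count drawn uniformly from its class's range, so the
    two labelling paths (assigned label vs. trap-count thresholds) agree
    by construction.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    mids = schema.min_values + 0.5 * schema.ranges
    sd = _FEATURE_SD_FRAC * schema.ranges

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    traps: list[np.ndarray] = []
    for label in CLASS_LABELS:
        n = config.class_counts.get(label, 0)
        if n == 0:
            continue
        centre = mids + _CLASS_OFFSETS[label] * config.class_shift * schema.ranges
        X = rng.normal(loc=centre, scale=sd, size=(n, len(schema)))
        np.clip(X, schema.min_values, schema.max_values, out=X)
        lo, hi = config.trap_count_ranges[label]
        blocks.append(X)
        labels.append(np.full(n, label, dtype="U1"))
        traps.append(rng.integers(lo, hi + 1, size=n))
    return LabeledDataset(
        schema,
        np.concatenate(blocks),
        np.concatenate(labels),
        np.concatenate(traps),
    )


@dataclass(frozen=True)
class PlantedRule:
    """Ground truth for recovery tests: a rule plus a label-noise rate."""

    rule: Rule
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must lie in [0, 1)")


_MAX_REJECTION_TRIES = 1000


def generate_planted_rule_dataset(
    schema: FeatureSchema,
    planted: PlantedRule,
    n_samples: int,
    positive_fraction: float,
    seed: int,
) -> LabeledDataset:
    """Generate data whose labels are (noisily) determined by one rule.

    ``round(positive_fraction * n_samples)`` samples are drawn inside the
    planted rule's intervals (uniform within each condition, uniform over
    the schema range elsewhere) and labeled with the rule's target class;
    the rest are drawn uniformly over the schema box, rejection-sampled
    off the rule, and labeled with the other classes in alternation.
    Each label is then independently flipped to a different class with
    probability ``noise_rate``.  Trap counts are drawn consistently with
    the final labels.  Deterministic given ``seed``.
    """
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError("positive_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    rule = planted.rule
    d = len(schema)
    n_pos = int(round(positive_fraction * n_samples))
    n_neg = n_samples - n_pos

    lo = schema.min_values.copy()
    hi = schema.max_values.copy()
    rule_lo, rule_hi = lo.copy(), hi.copy()
    for cond in rule.conditions:
        j = schema.index(cond.feature)
        rule_lo[j], rule_hi[j] = cond.lower, cond.upper
        if not (lo[j] <= cond.lower <= cond.upper <= hi[j]):
            raise ValueError(f"planted bounds on {cond.feature} leave the schema")

    X_pos = rng.uniform(rule_lo, rule_hi, size=(n_pos, d))

    X_neg = rng.uniform(lo, hi, size=(n_neg, d))
    for _ in range(_MAX_REJECTION_TRIES):
        inside = rule_match_mask(rule, X_neg, schema)
        if not inside.any():
            break
        X_neg[inside] = rng.uniform(lo, hi, size=(int(inside.sum()), d))
    else:
        raise GenerationError(
            "could not draw enough negatives outside the planted rule; "
            "its volume is too close to the whole feature box"
        )

    others = [c for c in CLASS_LABELS if c != rule.target_class]
    labels = np.concatenate(
        [
            np.full(n_pos, rule.target_class, dtype="U1"),
            np.array([others[i % len(others)] for i in range(n_neg)], dtype="U1"),
        ]
    )
    X = np.concatenate([X_pos, X_neg])

    flip = rng.random(n_samples) < planted.noise_rate
    for i in np.flatnonzero(flip):
        choices = [c for c in CLASS_LABELS if c != labels[i]]
        labels[i] = choices[int(rng.integers(len(choices)))]

    perm = rng.permutation(n_samples)
    X, labels = X[perm], labels[perm]

    traps = np.empty(n_samples, dtype=int)
    for label, (tlo, thi) in DEFAULT_TRAP_RANGES.items():
        m = labels == label
        traps[m] = rng.integers(tlo, thi + 1, size=int(m.sum()))
    return LabeledDataset(schema, X, labels, traps)
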
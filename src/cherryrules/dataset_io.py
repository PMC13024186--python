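"""Tabular I/O for pomological sample data.

Reads and writes flat CSV tables of numeric fruit-trait measurements,
derives infestation-class labels (L/M/H) from adult trap counts, and
performs the stratified train/test split used by the mining experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three infestation-level class labels, in canonical order.
CLASS_LABELS: tuple[str, str, str] = ("L", "M", "H")

#: Canonical measured fruit features with their observed (min, max) ranges.
#: Units: Color is a 1-5 ripeness scale; Weight and Core_weight in grams;
#: Width/Length/StemLength in millimetres; Hardness in N; SCKM (soluble
#: solid content) in degrees Brix; NaOH a maturity index; Acidity in
#: percent malic acid.
DEFAULT_FEATURE_RANGES: tuple[tuple[str, float, float], ...] = (
    ("Color", 1.00, 5.00),
    ("Weight", 2.86, 7.03),
    ("Width", 14.28, 23.26),
    ("Length", 15.23, 29.89),
    ("StemLength", 13.01, 19.81),
    ("Hardness", 14.44, 61.14),
    ("Core_weight", 0.60, 10.0),
    ("SCKM", 12.7, 17.0),
    ("NaOH", 8.83, 15.48),
    ("Acidity", 0.59, 1.07),
)

#: Trap-count class boundaries: counts of 0-5 adults map to Low, 6-10 to
#: Medium, and strictly more than 10 to High.
TRAP_COUNT_LOW_MAX = 5
TRAP_COUNT_MEDIUM_MAX = 10


class SchemaError(ValueError):
    """A required column is missing or the schema is malformed."""


class EmptyInputError(ValueError):
    """An input table contained no usable rows."""


class SplitError(ValueError):
    """A stratified split cannot be performed (class too small)."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered numeric feature names with their measurement ranges.

    The schema is the coordinate frame in which rule genomes are decoded:
    genome scores in [0, 1] are mapped affinely onto ``[min, max]`` per
    feature.
    """

    names: tuple[str, ...]
    min_values: np.ndarray
    max_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(
            self, "min_values", np.asarray(self.min_values, dtype=float)
        )
        object.__setattr__(
            self, "max_values", np.asarray(self.max_values, dtype=float)
        )
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names must be unique")
        if not (
            len(self.names) == self.min_values.size == self.max_values.size
        ):
            raise SchemaError("names/min/max lengths differ")
        if not np.all(self.min_values < self.max_values):
            raise SchemaError("every feature needs min < max")

    @classmethod
    def default(cls) -> "FeatureSchema":
        """The canonical ten-feature pomological schema."""
        names, lo, hi = zip(*DEFAULT_FEATURE_RANGES)
        return cls(names=names, min_values=np.array(lo), max_values=np.array(hi))

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None

    @property
    def ranges(self) -> np.ndarray:
        return self.max_values - self.min_values


@dataclass(frozen=True)
class Sample:
    """One fruit sample: feature vector plus label and/or trap count."""

    values: np.ndarray
    trap_count: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}")
        if self.trap_count is not None and self.trap_count < 0:
            raise ValueError("trap_count must be non-negative")


@dataclass
class LabeledDataset:
    """A fully labeled sample table, stored column-major for fast matching.

    ``X`` has one row per sample, columns aligned to ``schema.names``;
    ``labels`` holds single-character class labels; ``trap_counts`` is
    optional and, when present, consistent with the labels.
    """

    schema: FeatureSchema
    X: np.ndarray
    labels: np.ndarray
    trap_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.schema):
            raise ValueError("X must be (n_samples, n_features)")
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("labels length must match X rows")
        bad = set(self.labels) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.trap_counts is not None:
            self.trap_counts = np.asarray(self.trap_counts, dtype=int)
            if self.trap_counts.shape != self.labels.shape:
                raise ValueError("trap_counts length must match labels")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASS_LABELS}

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        tc = None if self.trap_counts is None else self.trap_counts[indices]
        return LabeledDataset(self.schema, self.X[indices], self.labels[indices], tc)

    def samples(self) -> Iterator[Sample]:
        for i in range(len(self)):
            tc = None if self.trap_counts is None else int(self.trap_counts[i])
            yield Sample(self.X[i], trap_count=tc, label=str(self.labels[i]))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.schema.names))
        if self.trap_counts is not None:
            frame["trap_count"] = self.trap_counts
        frame["class"] = self.labels
        return frame


def label_from_trap_count(count: int) -> str:
    """Map an adult trap count to its infestation class.

    Counts of at most 5 are Low, 6 through 10 Medium, and strictly more
    than 10 High.  A count of exactly 10 is Medium.
    """
    count = int(count)
    if count < 0:
        raise ValueError("trap count must be non-negative")
    if count <= TRAP_COUNT_LOW_MAX:
        return "L"
    if count <= TRAP_COUNT_MEDIUM_MAX:
        return "M"
    return "H"


def labels_from_trap_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`label_from_trap_count`."""
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("trap counts must be non-negative")
    labels = np.full(counts.shape, "H", dtype="U1")
    labels[counts <= TRAP_COUNT_MEDIUM_MAX] = "M"
    labels[counts <= TRAP_COUNT_LOW_MAX] = "L"
    return labels


def read_samples_csv(
    path,
    schema: FeatureSchema | None = None,
    *,
    class_column: str = "class",
    trap_count_column: str = "trap_count",
) -> LabeledDataset:
    """Read a labeled sample table from CSV.

    The header must contain every schema feature and at least one of the
    class / trap-count columns.  Rows with unparseable or missing feature
    values (or an unrecognised class label) are dropped; the number of
    rejected rows is logged at WARNING level.
    """
    schema = schema or FeatureSchema.default()
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    missing = [name for name in schema.names if name not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_class = class_column in frame.columns
    has_traps = trap_count_column in frame.columns
    if not (has_class or has_traps):
        raise SchemaError(
            f"need a {class_column!r} or {trap_count_column!r} column"
        )

    feats = frame[list(schema.names)].apply(pd.to_numeric, errors="coerce")
    ok = feats.notna().all(axis=1)
    traps = None
    if has_traps:
        traps = pd.to_numeric(frame[trap_count_column], errors="coerce")
        ok &= traps.notna() & (traps >= 0)
    if has_class:
        labels = frame[class_column].astype(str).str.strip()
        ok &= labels.isin(CLASS_LABELS)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d unparseable row(s) in %s", n_rejected, path)
    if not ok.any():
        raise EmptyInputError(f"no parseable rows in {path}")

    feats = feats[ok]
    if has_class:
        label_arr = labels[ok].to_numpy(dtype="U1")
    else:
        label_arr = labels_from_trap_counts(traps[ok].to_numpy(dtype=int))
    trap_arr = None if traps is None else traps[ok].to_numpy(dtype=int)
    return LabeledDataset(schema, feats.to_numpy(dtype=float), label_arr, trap_arr)


def write_samples_csv(data: LabeledDataset, path) -> None:
    """Write a labeled dataset to CSV (comma-separated, dot decimal, UTF-8).

    Floats are serialised with shortest-repr precision, so a write/read
    round trip reproduces every value exactly.
    """
    data.to_frame().to_csv(path, index=False)


def stratified_split(
    data: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into train/test preserving class proportions.

    Each class contributes ``round_half_up(train_fraction * class_count)``
    samples to the training part; no global adjustment is applied, so the
    overall fraction may deviate slightly from ``train_fraction``.
    Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in CLASS_LABELS:
        idx = np.flatnonzero(data.labels == label)
        if idx.size == 0:
            continue
        if idx.size < 2:
            raise SplitError(f"class {label} has fewer than 2 samples")
        # round half up, independently per class
        n_train = int(np.floor(train_fraction * idx.size + 0.5))
        perm = rng.permutation(idx.size)
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx)) if any(a.size for a in test_idx) else np.array([], dtype=int)
    return data.subset(train), data.subset(test)
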
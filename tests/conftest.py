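import numpy as np
import pytest

from cherryrules import (
    Condition,
    FeatureSchema,
    LabeledDataset,
    PlantedRule,
    Rule,
    generate_planted_rule_dataset,
)


@pytest.fixture(scope="session")
def schema():
    return FeatureSchema.default()


@pytest.fixture(scope="session")
def toy_schema():
    """Two features with simple ranges: easy to reason about by hand."""
    return FeatureSchema(
        names=("A", "B"), min_values=np.array([0.0, 10.0]),
        max_values=np.array([10.0, 20.0]),
    )


@pytest.fixture(scope="session")
def planted_weight_rule():
    """The canonical ground-truth rule for recovery tests."""
    return Rule((Condition("Weight", 3.5, 5.5),), "H")


@pytest.fixture(scope="session")
def planted_dataset(schema, planted_weight_rule):
    """A clean (noise-free) planted-rule dataset."""
    return generate_planted_rule_dataset(
        schema, PlantedRule(planted_weight_rule, noise_rate=0.0),
        n_samples=200, positive_fraction=0.4, seed=11,
    )


@pytest.fixture
def tiny_dataset(toy_schema):
    """Six hand-placed samples over the toy schema."""
    X = np.array(
        [
            [1.0, 11.0],
            [2.0, 12.0],
            [3.0, 13.0],
            [7.0, 17.0],
            [8.0, 18.0],
            [9.0, 19.0],
        ]
    )
    labels = np.array(["L", "L", "L", "H", "H", "H"])
    return LabeledDataset(toy_schema, X, labels)
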
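"""Shared fixtures: small generated datasets and desk-scale configurations."""

import numpy as np
import pytest

from iterfs import (
    LabeledDataset,
    PlantedSpec,
    generate_planted,
    validate_config,
)


@pytest.fixture
def fast_config():
    """Protocol scaled for unit tests: 2 cheap classifiers, small forests."""
    return validate_config(
        master_seed=17,
        n_iterations=20,
        classifier_ids=("logistic", "knn"),
        boruta_trees=50,
        boruta_max_runs=30,
        boruta_n_repeats=2,
        rf_trees=50,
    )


@pytest.fixture
def planted_signal():
    """150 x 10 Gaussian table with one strong planted feature (d = 2)."""
    return generate_planted(PlantedSpec(n=150, p=10, informative=((0, 2.0),), seed=5))


@pytest.fixture
def null_dataset():
    """Label-independent Gaussian table (no feature carries information)."""
    return generate_planted(PlantedSpec(n=150, p=10, informative=(), seed=23))


@pytest.fixture
def leak_dataset():
    """One feature equal to the 0/1 label plus independent noise features."""
    rng = np.random.default_rng(3)
    n = 80
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 5))
    X[:, 0] = y
    labels = np.where(y == 1, "b", "a")
    return LabeledDataset(X, ("leak", "n1", "n2", "n3", "n4"), labels, ("a", "b"))
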
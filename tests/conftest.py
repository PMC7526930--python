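"""Shared fixtures.

Expensive objects (the resolved literature database, a small fitted
ensemble) are session-scoped so the suite fits a tight time budget.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from chrysopt import database
from chrysopt.ensemble import fit_bagged_ensemble
from chrysopt.regressors import ANFISConfig, MLPConfig, RBFConfig

logging.getLogger("chrysopt").setLevel(logging.WARNING)

#: small member configs used wherever a test needs a fitted ensemble but not
#: the default model capacity (keeps the suite fast)
SMALL_MEMBERS = {
    "mlp": MLPConfig(epochs=120, seed=0),
    "rbf": RBFConfig(n_centers=8, seed=0),
    "anfis": ANFISConfig(n_rules=3, epochs=25, seed=0),
}


@pytest.fixture(scope="session")
def records():
    return database.load_database()


@pytest.fixture(scope="session")
def resolved_rows(records):
    return database.resolve_records(records)


@pytest.fixture(scope="session")
def dataset(resolved_rows):
    return database.encode(resolved_rows)


@pytest.fixture(scope="session")
def small_ensemble(dataset):
    """B=2 bagged ensemble on the full literature table (fast, reused)."""
    return fit_bagged_ensemble(
        dataset.features, dataset.targets, SMALL_MEMBERS, b=2, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
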
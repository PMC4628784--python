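"""Shared fixtures: one default synthetic dataset per session, plus the
coding-potential model trained on its corpora and the cascade run on it."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lncforge.coding import train_coding_model
from lncforge.discovery import filter_cascade
from lncforge.intervals import spliced_sequence
from lncforge.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATASET_SEED = 11


@pytest.fixture(scope="session")
def dataset():
    return simulate_dataset(SimulationConfig(seed=DATASET_SEED))


@pytest.fixture(scope="session")
def coding_model(dataset):
    return train_coding_model(dataset.coding_train, dataset.noncoding_train)


@pytest.fixture(scope="session")
def sequences(dataset):
    return {t.transcript_id: spliced_sequence(t, dataset.genome) for t in dataset.assembly}


@pytest.fixture(scope="session")
def cascade_report(dataset, coding_model, sequences):
    return filter_cascade(dataset.assembly, sequences, coding_model, dataset.expression,
                          known=dataset.known)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
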
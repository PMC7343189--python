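"""Shared fixtures: synthetic datasets and (expensive) trained models.

Training fixtures are session-scoped so the end-to-end benchmark models
are fitted once and shared between the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cosplice.model import ModelConfig, SpliceRNN
from cosplice.synth import loo_preset, profile_preset, simulate, strong_signal_preset

SEED = 2026


@pytest.fixture(scope="session")
def strong_data():
    return simulate(strong_signal_preset(), seed=SEED)


@pytest.fixture(scope="session")
def strong_dataset(strong_data):
    return strong_data.to_dataset(flank_bp=100)


@pytest.fixture(scope="session")
def lstm_results(strong_dataset):
    return SpliceRNN(strong_dataset, ModelConfig.benchmark("lstm")).fit(seed=SEED)


@pytest.fixture(scope="session")
def gru_results(strong_dataset):
    return SpliceRNN(strong_dataset, ModelConfig.benchmark("gru")).fit(seed=SEED)


@pytest.fixture(scope="session")
def loo_data():
    return simulate(loo_preset(), seed=SEED)


@pytest.fixture(scope="session")
def profile_data():
    return simulate(profile_preset(), seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
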
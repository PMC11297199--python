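"""Shared fixtures.

The session-scoped ``trained`` fixture runs the full desk-scale experiment
once (simulate a cohort, train the causal TCN, keep the results object) so
the end-to-end, informed-model and ablation tests can share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from scrubsight import LabelVocabulary, WindowParams
from scrubsight.model import InstrumentAnticipationModel
from scrubsight.synthetic import SimulatorConfig, short_config
from scrubsight.temporal import ModelConfig, TrainConfig


@pytest.fixture(scope="session")
def vocab() -> LabelVocabulary:
    return LabelVocabulary()


@pytest.fixture(scope="session")
def window_params() -> WindowParams:
    return WindowParams(delta=3.0, tau=3.0, sigma=1.0, rho=10.0)


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimulatorConfig:
    """Scaled-down surgeries (~6 min) for fast unit tests."""
    return short_config(seed=11)


@pytest.fixture(scope="session")
def trained():
    """Desk-scale end-to-end run: default simulator, causal TCN, 50 epochs."""
    model = InstrumentAnticipationModel.from_simulator(
        sim_config=SimulatorConfig(seed=0),
        n_videos=13,
        split=(10 / 13, 0.0, 3 / 13),
        seed=1,
        model_config=ModelConfig(backbone="causal-tcn", stages=1, layers=4, hidden=32, seed=0),
    )
    results = model.fit(TrainConfig(epochs=50, seed=0))
    return results


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
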
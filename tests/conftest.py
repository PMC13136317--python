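"""Shared fixtures: compact configs and session-scoped trained models.

Training-based fixtures are session-scoped so the expensive seeded runs
(local-regime dominance model, mixed-task ablation suite) are executed once
and shared by every test that inspects them.
"""

import numpy as np
import pytest

from adsaf.config import ModelConfig, StreamConfig
from adsaf.experiments import (
    ablation_experiment,
    small_model_config,
    small_stream_config,
    train_on_regime,
)


@pytest.fixture(scope="session")
def small_stream() -> StreamConfig:
    return small_stream_config()


@pytest.fixture(scope="session")
def small_model(small_stream) -> ModelConfig:
    return small_model_config("full_adsaf", 0.1)


@pytest.fixture(scope="session")
def trained_local_model():
    """Full model trained on one local-regime task (seed 1).

    Shared by the attention-focus, Grad-CAM localization and robustness
    smoke tests.  Seed 1 is one of the standard dominance replicate seeds.
    """
    ckpt, history, ds = train_on_regime("local", "full_adsaf", seed=1,
                                        max_epochs=30)
    return {"checkpoint": ckpt, "history": history, "dataset": ds}


@pytest.fixture(scope="session")
def ablation_results():
    """The 3-seed mixed-task ablation + paired noise robustness suite."""
    return ablation_experiment(seeds=(0, 1, 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
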
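import numpy as np
import pytest

from moo_reid import nn
from moo_reid.config import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model_config():
    """Width-reduced default configuration for fast forward passes."""
    return ModelConfig(
        input_size=(96, 48),
        channels_per_stage=(64, 128, 256, 512),
        s2attention={"stride": 1},
    )


@pytest.fixture
def baseline_small_config():
    """All-standard, all-flags-off counterpart of small_model_config."""
    return ModelConfig(
        input_size=(96, 48),
        stage_plan=("standard",) * 4,
        channels_per_stage=(64, 128, 256, 512),
        use_s2attention=False,
        use_nam=False,
        use_qaconv=False,
    )


@pytest.fixture(autouse=True)
def _seed_layer_init():
    nn.seed_all(0)
    yield
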
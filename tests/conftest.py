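import numpy as np
import pytest

from semgait.model import ModelConfig
from semgait.simulate import SimConfig, generate_session


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A short session: 8 cycles at the default 1.5 kHz."""
    return SimConfig(n_cycles=8, seed=42)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg)


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    """Narrow widths for fast structural/optimization tests."""
    return ModelConfig(conv1d_channels=(6, 8), conv2d_channels=4,
                       gru_hidden=8, fc_hidden=16)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
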
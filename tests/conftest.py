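import numpy as np
import pytest

from sonoseg.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Smallest full network: 2 levels + ViT bottleneck, 8x8 input."""
    return ModelConfig(input_size=(8, 8, 1), channel_schedule=(4, 8),
                       r_enc=3, heads=2, mlp_hidden=6)


@pytest.fixture
def small_config():
    """Desk-scale network used for learning tests (64x64 input)."""
    return ModelConfig(input_size=(64, 64, 1), channel_schedule=(8, 16, 32, 64),
                       heads=4, mlp_hidden=128)
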
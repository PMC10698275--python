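import numpy as np
import pytest

from pwdiff.pointwise_model import ModelConfig, PointwiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest architecture that still exercises every layer type."""
    return dict(conv_blocks=1, conv_channels=8, encoder_layers=1,
                attention_heads=2, embed_dim=16)


@pytest.fixture(scope="session")
def tiny_model(tiny_model_config):
    return PointwiseModel(ModelConfig(target="D", **tiny_model_config), rng=0)
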
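import numpy as np
import pytest

from bgmbc.encoder import EncoderConfig
from bgmbc.synthetic import SyntheticConfig, generate_encoded_dataset


@pytest.fixture
def tiny_encoder():
    """Small stub-encoder geometry for fast unit tests."""
    return EncoderConfig(
        hidden_size=16, n_layers=2, n_heads=2, max_len=32, feature_width=16
    )


@pytest.fixture
def small_dataset():
    """An 80-node encoded dataset with 3 strongly informative columns."""
    cfg = SyntheticConfig(n_records=80, n_features=20, n_informative=3, seed=1)
    table, scores, dims = generate_encoded_dataset(cfg)
    return table, scores, dims


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
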
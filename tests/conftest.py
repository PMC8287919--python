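import numpy as np
import pytest

from attnteract.model import Model, ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_model():
    """A small random-weight model (L=60, F=3, 2 heads) for fast checks."""
    cfg = ModelConfig(seq_len=60, n_filters=3, filter_len=5, pool_window=3,
                      n_heads=2, d_k=4, attn_out=4, task="binary")
    return Model(cfg, seed=7)


def random_onehot(rng, n, length):
    """(n, 4, length) one-hot batch of random DNA."""
    x = np.zeros((n, 4, length))
    idx = rng.integers(0, 4, (n, length))
    for i in range(n):
        x[i, idx[i], np.arange(length)] = 1.0
    return x
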
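import numpy as np
import pytest

from crossclust.data import ExpressionDataset
from crossclust.encoder import Encoder, EncoderConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_encoder():
    """Small encoder for fast unit tests (8 genes -> 3 latent dims)."""
    return Encoder(EncoderConfig(input_dim=8, hidden_dims=[6, 5], latent_dim=3, seed=7))


def linear_encoder(W: np.ndarray) -> Encoder:
    """Depth-0 encoder computing exactly X @ W, for hand-checkable embeddings."""
    v, d = W.shape
    enc = Encoder(EncoderConfig(input_dim=v, hidden_dims=[], latent_dim=d, seed=0))
    enc.params["W0"] = np.asarray(W, dtype=float)
    enc.params["b0"] = np.zeros(d)
    return enc


@pytest.fixture
def small_labeled_dataset(rng):
    mat = rng.poisson(2.0, size=(12, 8)).astype(float)
    labels = ["A"] * 5 + ["B"] * 4 + ["C"] * 3
    return ExpressionDataset(
        mat, [f"g{i}" for i in range(8)], [f"c{i}" for i in range(12)],
        "source:unit", labels,
    )
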
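import numpy as np
import pytest

from hyperelm import SynthConfig, generate_dataset
from hyperelm.elm import _seed_streams, init_input_weights
from hyperelm.helm import assemble_hidden, channel_hidden_matrix
from hyperelm.hypercomplex import HCMatrix, hc_hermitian, hc_identity, hc_matmul


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hc_matrix(rng, d, rows, cols, diag_boost=0.0):
    comps = rng.normal(size=(d + 1, rows, cols))
    if diag_boost and rows == cols:
        comps[0] += diag_boost * np.eye(rows)
    return HCMatrix(comps)


@pytest.fixture
def small_dataset():
    """Tiny 4-channel dataset: 5 classes x 8 samples of 16x16 images."""
    return generate_dataset(
        SynthConfig(n_classes=5, samples_per_class=8, n_channels=4,
                    image_size=16, seed=3)
    )


@pytest.fixture
def single_channel_dataset():
    return generate_dataset(
        SynthConfig(n_classes=5, samples_per_class=8, n_channels=1,
                    image_size=16, seed=3)
    )


def helm_gram_fixture(n_channels, n_hidden=24, activation="sigmoid",
                      ridge=1e-2, seed=7):
    """The ridge-regularized hypercomplex Gram matrix of a small HELM."""
    ds = generate_dataset(
        SynthConfig(n_classes=5, samples_per_class=8, n_channels=n_channels,
                    image_size=16, seed=3)
    )
    rngs = _seed_streams(seed, n_channels)
    alphas = [init_input_weights(ds.n_features, n_hidden, r) for r in rngs]
    H = assemble_hidden([
        channel_hidden_matrix(X, a, activation)
        for X, a in zip(ds.channels, alphas)
    ])
    return hc_matmul(hc_hermitian(H), H) + ridge * hc_identity(n_hidden, n_channels - 1)
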
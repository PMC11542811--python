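import numpy as np
import pytest

from plastinet.datasets import SyntheticSpec, make_synthetic
from plastinet.network import TrainingConfig, init_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synthetic():
    """A quickly learnable synthetic (train, valid) pair, 64 features, 10 classes."""
    spec = SyntheticSpec(
        n_classes=10, n_features=64, n_train=800, n_valid=400, prototype_scale=1.0, noise_sd=0.4, seed=7
    )
    return make_synthetic(spec)


@pytest.fixture
def fast_config():
    return TrainingConfig(seed=3, eval_every=200, max_epochs=10)


@pytest.fixture
def tiny_weights(rng):
    return init_weights(5, 4, 3, init_sd=0.5, rng=rng)
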
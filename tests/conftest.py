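import numpy as np
import pytest

from specnet.datasets import SynthConfig, generate_dataset
from specnet.preprocessing import preprocess_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, well-separated 3-class design on a short grid (fast to train)."""
    return SynthConfig(
        n_classes=3,
        samples_per_class=12,
        train_per_class=9,
        n_points=201,
        separability=2.0,
        noise_sd=0.01,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_ds(tiny_cfg):
    return generate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_prep(tiny_ds):
    return preprocess_dataset(tiny_ds)


@pytest.fixture(scope="session")
def mid_ds():
    """3 classes on a 401-point grid: long enough for 20x20 spectral images."""
    cfg = SynthConfig(
        n_classes=3,
        samples_per_class=12,
        train_per_class=9,
        n_points=401,
        separability=2.0,
        noise_sd=0.01,
        seed=7,
    )
    return preprocess_dataset(generate_dataset(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
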
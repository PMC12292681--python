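import numpy as np
import pytest

from mctgnet import EEGDataset, MultiScaleConfig, SynthConfig, generate_synthetic_mi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small front-end config for fast unit tests (L = (256//4)//4 = 16)."""
    return MultiScaleConfig(
        f1=4, depth_multiplier=2, kernels=(8, 16, 24), pool1=4,
        refine_kernel=8, pool2=4, embed_dim=8, dropout=0.0,
    )


@pytest.fixture
def tiny_dataset(rng):
    trials = rng.standard_normal((6, 4, 256))
    labels = rng.integers(0, 2, size=6)
    return EEGDataset(trials, labels)


@pytest.fixture(scope="session")
def small_synth():
    """A small separable synthetic MI problem shared across tests."""
    cfg = SynthConfig(
        channels=8, samples=500, classes=2, trials_per_class=12,
        test_trials_per_class=8, erd_depth=0.5, noise_sigma=1.0, seed=7,
    )
    return cfg, generate_synthetic_mi(cfg)
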
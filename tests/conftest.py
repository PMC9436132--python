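import numpy as np
import pytest

import gipct as g


@pytest.fixture(scope="session")
def study32():
    """Default desk-scale study conditions at 32x32."""
    return g.default_study(32)


@pytest.fixture(scope="session")
def breast32():
    return g.make_breast_phantom((32, 32), 4, seed=42, delta_range=(0, 1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_denoiser(study32):
    """One denoiser trained at the study conditions, shared by the tests
    that exercise the full Plug-and-Play pipeline."""
    pairs = g.make_training_set(study32, 50, seed=11)
    config = g.TrainingConfig(seed=5)
    net, state, log = g.train_denoiser(pairs, config)
    return net, state, log, pairs
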
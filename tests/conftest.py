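import numpy as np
import pytest

from spikemap.snn_core import (
    LayerSpec,
    NetworkConfig,
    NeuronParams,
    INF_THRESHOLD,
    standard_config,
)
from spikemap.synthetic_data import make_shape_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2-class, quickly separable; for fast training smoke tests."""
    return make_shape_dataset(n_classes=2, image_size=16, n_per_class=24, rng_seed=3)


@pytest.fixture(scope="session")
def dataset():
    return make_shape_dataset(n_classes=4, image_size=16, n_per_class=100, rng_seed=1)


@pytest.fixture
def tiny_config():
    """Single small conv layer + GAP + linear; cheap forward/backward."""
    return NetworkConfig(
        layers=(
            LayerSpec("conv", 4, neuron=NeuronParams(0.99, 1.0), bntt=True),
            LayerSpec("gap"),
            LayerSpec("linear", 2, neuron=NeuronParams(1.0, INF_THRESHOLD)),
        ),
        total_timesteps=8,
        num_classes=2,
        input_shape=(1, 12, 12),
    )


@pytest.fixture(scope="session")
def testbed():
    """Full trained testbed shared by acceptance and trend tests.

    Trains three models; ~1 minute on one CPU, paid once per session.
    """
    from spikemap.experiments import build_testbed

    return build_testbed(seed=1)
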
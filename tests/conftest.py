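import numpy as np
import pytest

from glioscope.nn.model import BlockSpec, MnasLite, ModelConfig
from glioscope.phantom import PhantomSpec, make_dataset
from glioscope.sco import SearchSpace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_space():
    return SearchSpace(lb=np.zeros(3), ub=np.ones(3))


@pytest.fixture
def box_space():
    return SearchSpace(lb=np.full(2, -5.0), ub=np.full(2, 5.0))


@pytest.fixture(scope="session")
def tiny_model_config():
    """One-block 8x8 model, small enough for finite differences."""
    return ModelConfig(
        input_hw=(8, 8),
        in_channels=1,
        stem_channels=4,
        blocks=(BlockSpec(expansion=2, kernel=3, stride=1, out_channels=4, se_ratio=2),),
        n_classes=2,
        dropout=0.0,
    )


@pytest.fixture
def tiny_model(tiny_model_config):
    return MnasLite(tiny_model_config, seed=0)


@pytest.fixture(scope="session")
def small_phantom_set():
    """60-image phantom cohort shared across tests (generation is seeded)."""
    spec = PhantomSpec(n_per_class=30, seed=7)
    images, manifest = make_dataset(spec)
    return spec, images, manifest
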
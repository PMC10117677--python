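import numpy as np
import pytest

from tdsan import SynthConfig, TrainConfig, gen_domain_pair
from tdsan.model import ModelConfig, TDSANModel


@pytest.fixture(scope="session")
def tiny_pair():
    """Small two-domain synthetic pair for fast smoke tests."""
    return gen_domain_pair(SynthConfig(n_per_class=20, seed=3))


@pytest.fixture(scope="session")
def small_model():
    return TDSANModel(ModelConfig.reduced(), seed=0)


@pytest.fixture()
def tiny_train_cfg():
    return TrainConfig(model=ModelConfig.reduced(), batch_size=32, max_epochs=1, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
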
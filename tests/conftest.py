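import numpy as np
import pytest

from replaysim import network, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """Two-block architecture small enough for numerical gradient checks."""
    return network.ArchitectureSpec(input_shape=(16, 16, 3), blocks=((1, 4), (1, 8)),
                                    head=(16,), n_outputs=3, dropout_rate=0.5,
                                    preset="tiny")


@pytest.fixture
def tiny_model(tiny_spec):
    return network.build_model(tiny_spec, init_seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """3 texture classes, 8/3/4 images per class at 32x32."""
    protos = synthetic.generate_prototypes(3, seed=5)
    return synthetic.build_dataset(protos, n_train=8, n_val=3, n_test=4,
                                   size=(32, 32), seed=5)


@pytest.fixture
def small_model(small_dataset):
    spec = network.ArchitectureSpec.mini(n_outputs=small_dataset.n_classes,
                                         input_shape=(32, 32, 3))
    return network.build_model(spec, init_seed=3)
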
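import numpy as np
import pytest

from dcmerp import neural_mass as nm


@pytest.fixture(scope="session")
def model_space():
    return nm.build_model_space()


@pytest.fixture(scope="session")
def m1(model_space):
    return model_space[0]


@pytest.fixture(scope="session")
def m5(model_space):
    return model_space[4]


@pytest.fixture(scope="session")
def compiled_m1(m1):
    return nm.compile_variant(m1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
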
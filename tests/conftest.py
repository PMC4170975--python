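import numpy as np
import pytest

from ddgboost.structures import make_toy_complex, make_toy_fold


@pytest.fixture(scope="session")
def toy_fold():
    return make_toy_fold(11, 12)


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_complex(21, 10, 10, gap=3.5)


@pytest.fixture(scope="session")
def far_dimer():
    return make_toy_complex(22, 8, 8, gap=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
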
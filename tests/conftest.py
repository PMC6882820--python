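import numpy as np
import pytest

from pcscreen.core import center_columns
from pcscreen.simulation import gen_chain_model, sample_mvn, toy_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy():
    return toy_model()


@pytest.fixture(scope="session")
def toy_data():
    """n=100 centered draws from the toy covariance (fixed seed)."""
    m = toy_model()
    return center_columns(sample_mvn(m, 100, seed=42))


@pytest.fixture(scope="session")
def chain20():
    return gen_chain_model(20, neighbors=1)


@pytest.fixture(scope="session")
def chain20_data(chain20):
    """n=500 centered draws from the p=20 chain model (fixed seed)."""
    return center_columns(sample_mvn(chain20, 500, seed=7))


def random_spd(p, rng, jitter=0.5):
    """Random symmetric positive-definite matrix with controlled conditioning."""
    A = rng.standard_normal((p, p))
    return A @ A.T / p + jitter * np.eye(p)
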
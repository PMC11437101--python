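import numpy as np
import pytest

from cmdsim import phc_crypto as phc
from cmdsim import rdbn_model as rdbn


@pytest.fixture(scope="session")
def kp128():
    """One 128-bit Paillier keypair shared across the session."""
    return phc.generate_keypair(128, 7)


@pytest.fixture(scope="session")
def pk128(kp128):
    return kp128.public


@pytest.fixture
def tiny_model():
    """2 hidden layers x 5 units, 4 features, 3 classes, residual stack."""
    cfg = rdbn.TrainConfig(hidden_layers=2, hidden_units=5, dropout=0.0,
                           seed=3)
    return rdbn.build_model(4, 3, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
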
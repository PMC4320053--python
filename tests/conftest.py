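import numpy as np
import pytest

from rhibayes.config import load_default_config
from rhibayes.model import ModelParams, Priors


@pytest.fixture(scope="session")
def default_config():
    return load_default_config()


@pytest.fixture(scope="session")
def calibrated_params(default_config):
    """Shipped model parameters with the calibrated prior widths."""
    return default_config.model


@pytest.fixture()
def moderate_params():
    """Parameters with moderate prior widths, where raw densities are
    representable and quadrature oracles converge comfortably."""
    return ModelParams(
        sigma_v=1.0, sigma_p=15.0, sigma_tv=20.0, sigma_tt=20.0,
        priors=Priors(mu_x=0.0, sigma_x=100.0, mu_t=0.0, sigma_t=200.0, p_common=0.5),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
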
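import logging

import numpy as np
import pytest

from nirsconn.glmm import ModelParameters
from nirsconn.synth import SimulationConfig, simulate_cluster_network, simulate_hemo

logging.getLogger("nirsconn").setLevel(logging.ERROR)


@pytest.fixture
def small_config():
    """12 long / 4 short channels, 300 s: fast but long enough to epoch."""
    return SimulationConfig(
        duration=300.0, n_long_channels=12, n_short_channels=4, seed=7
    )


@pytest.fixture
def small_network():
    return simulate_cluster_network(12, 3, seed=1, coupling=0.8)


@pytest.fixture
def small_hemo(small_network, small_config):
    return simulate_hemo(small_network, small_config)


@pytest.fixture
def degree_params():
    """Moderate random-effect SDs around a mean degree of 15."""
    return ModelParameters(
        beta0=np.log(15.0), sigma_u=0.2, sigma_w=0.15
    )
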
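import pytest

from cmas import OpticalConfig, TwinConfig
from cmas.scenarios import ALGAE_CURVE, ALGAE_SERIES, SPERM_CURVE, SPERM_SERIES


@pytest.fixture
def sperm_curve():
    return SPERM_CURVE


@pytest.fixture
def algae_curve():
    return ALGAE_CURVE


@pytest.fixture
def sperm_series():
    return SPERM_SERIES


@pytest.fixture
def algae_series():
    return ALGAE_SERIES


@pytest.fixture
def default_optics():
    return OpticalConfig()


@pytest.fixture
def ideal_twin():
    """Noiseless, lossless instrument — the analytic limit."""
    return TwinConfig(noise_sd=0.0, loss_fraction=0.0, rng_seed=0)
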
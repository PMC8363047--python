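import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mnph import BloodProperties, water_like

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood():
    return BloodProperties()


@pytest.fixture(scope="session")
def soft_tissue():
    """Homogeneous perfused soft-tissue-like medium."""
    return water_like(perfusion=2e-3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
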
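import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synmix import ProtocolParams, generate_scs_database

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def protocol():
    return ProtocolParams()


@pytest.fixture(scope="session")
def scs_db():
    """Default 43-entry synthetic SCS database used by mixing tests."""
    return generate_scs_database(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
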
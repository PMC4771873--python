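import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluxgate import get_preset, symmetric_k

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def symk():
    return symmetric_k()


@pytest.fixture(scope="session")
def traak():
    return get_preset("traak_wt_symK")


@pytest.fixture(scope="session")
def traak_family():
    """Noise-free standard step family for the TRAAK preset (session-cached)."""
    from fluxgate.synth import generate_family

    return generate_family(get_preset("traak_wt_symK"))


@pytest.fixture(scope="session")
def leak_family():
    from fluxgate.synth import generate_family

    return generate_family(get_preset("twik1_leak"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
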
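import pytest
from hypothesis import HealthCheck, settings

from hs2econ import HypoglycaemiaCEModel, default_parameters

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def results():
    """Baseline fitted model, shared across tests (read-only)."""
    return HypoglycaemiaCEModel().fit()
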
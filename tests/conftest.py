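import pytest
from hypothesis import HealthCheck, settings

from observezone import build_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rapid_cohort():
    """Derivation observe-zone cohort reconstructed from published counts."""
    return build_fixture("RAPID_CPU")


@pytest.fixture(scope="session")
def bacc_cohort():
    """External validation observe-zone cohort from published counts."""
    return build_fixture("BACC")
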
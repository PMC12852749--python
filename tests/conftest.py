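import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from riverwqi import load_standards

    return load_standards()


@pytest.fixture(scope="session")
def aswan():
    from riverwqi import preset_scenario

    return preset_scenario("aswan2024")
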
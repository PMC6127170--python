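import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from crnsynth import library


@pytest.fixture
def worked_example():
    """Pairing + two catalytic conversions over {A, B, X}."""
    return library.worked_example()


@pytest.fixture
def div2():
    return library.division_by_two_crn()


@pytest.fixture
def max_schema():
    return library.maximum_schema()
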
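import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spt15():
    from aidscan.data import load_reference

    return load_reference("SPT15", flank=23)


@pytest.fixture(scope="session")
def ura3():
    from aidscan.data import load_reference

    return load_reference("URA3", flank=23)


@pytest.fixture(scope="session")
def ade1():
    from aidscan.data import load_reference

    return load_reference("ADE1", flank=23)
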
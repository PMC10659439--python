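import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fig3():
    from rdgkit.simulate import fixture_rdg

    return fixture_rdg("fig3")


@pytest.fixture(scope="session")
def gpx4():
    from rdgkit.simulate import fixture_rdg

    return fixture_rdg("gpx4_like")


@pytest.fixture(scope="session")
def peg10():
    from rdgkit.simulate import fixture_rdg

    return fixture_rdg("peg10_like")


@pytest.fixture(scope="session")
def chain2():
    from rdgkit.simulate import fixture_rdg

    return fixture_rdg("leaky_chain", k=2)
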
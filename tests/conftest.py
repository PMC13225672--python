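import pytest
from hypothesis import HealthCheck, settings

import popswitch as ps

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ac_model():
    return ps.allen_clark_demo()


@pytest.fixture(scope="session")
def pielou_model():
    return ps.pielou_demo()


@pytest.fixture(scope="session")
def fixture_model():
    return ps.make_fixture(ps.FixtureSpec(seed=1))


@pytest.fixture()
def tau035():
    return ps.TauSequence(c=0.35)
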
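import pytest
from hypothesis import HealthCheck, settings

import tearisk as tr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_records():
    return tr.load_fixture_tables()


@pytest.fixture(scope="session")
def printed_transfer():
    return tr.load_printed_transfer()


@pytest.fixture(scope="session")
def toxicology():
    return tr.default_toxicology()


@pytest.fixture(scope="session")
def populations():
    return tr.default_populations()
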
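import pytest

from vowelmap import StudyConfig, make_study_fixture
from vowelmap.synthetic import default_spec


@pytest.fixture(scope="session")
def spec():
    return default_spec(seed=0)


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def fixture_bundle():
    """The full synthetic study at published sample sizes (seed 0)."""
    return make_study_fixture(seed=0)


@pytest.fixture(scope="session")
def cg_tokens(fixture_bundle):
    return fixture_bundle.cg_tokens


@pytest.fixture(scope="session")
def nl_tokens(fixture_bundle):
    return fixture_bundle.nl_tokens
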
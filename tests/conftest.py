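import random

import pytest

from diseasechain import synthetic_data


@pytest.fixture(scope="session")
def diabetes():
    return synthetic_data.fixture_diabetes()


@pytest.fixture(scope="session")
def stenosis():
    return synthetic_data.fixture_stenosis_hierarchy()


@pytest.fixture(scope="session")
def rules():
    return synthetic_data.fixture_interop_rules()


@pytest.fixture(scope="session")
def vocabs():
    return synthetic_data.fixture_vocabularies()


@pytest.fixture
def rng():
    return random.Random(20240901)
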
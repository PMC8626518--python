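import pytest

from stabkin.fixtures import FixtureSpec, make_two_pathway_network, scaffold_network, \
    reference_tables


@pytest.fixture(scope="session")
def toy_network():
    return make_two_pathway_network(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def pyrrolone():
    return scaffold_network("pyrrolone")


@pytest.fixture(scope="session")
def furanone():
    return scaffold_network("furanone")


@pytest.fixture(scope="session")
def thiophenone():
    return scaffold_network("thiophenone")


@pytest.fixture(scope="session")
def tables():
    return reference_tables()
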
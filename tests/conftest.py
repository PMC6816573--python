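import pytest

from codonopt import GeneticCode, assign_addresses, build_wheel, load_index_table


@pytest.fixture(scope="session")
def table():
    return load_index_table()


@pytest.fixture(scope="session")
def sgc():
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def wheel():
    return build_wheel("AGCTTCGA", "AAA")


@pytest.fixture(scope="session")
def addresses(wheel, sgc):
    return assign_addresses(wheel, sgc)
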
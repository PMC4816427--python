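import pytest

from mirchar.fixtures import table1_library, table3_library, table4_library


@pytest.fixture(scope="session")
def table1():
    return table1_library()


@pytest.fixture(scope="session")
def table3():
    return table3_library()


@pytest.fixture(scope="session")
def table4():
    return table4_library()
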
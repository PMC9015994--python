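import pytest

from lutedose import ICRP107, packaged_table


@pytest.fixture(scope="session")
def icrp107():
    return ICRP107


@pytest.fixture(scope="session")
def svalue_table():
    return packaged_table()
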
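import pytest

from copd_bia import load_builtin


@pytest.fixture(scope="session")
def commercial_derived():
    return load_builtin("commercial_derived")


@pytest.fixture(scope="session")
def commercial_replication():
    return load_builtin("commercial_replication")


@pytest.fixture(scope="session")
def medicare_derived():
    return load_builtin("medicare_derived")


@pytest.fixture(scope="session")
def medicare_replication():
    return load_builtin("medicare_replication")
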
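import pytest

from pancsim import (ManagementPolicy, TestCharacteristics, annual_policy,
                     default_life_table, load_preset)


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def prog_config():
    return load_preset("progressive_only")


@pytest.fixture(scope="session")
def ind_config():
    return load_preset("indolent_included")


@pytest.fixture(scope="session")
def chars():
    return TestCharacteristics()


@pytest.fixture(scope="session")
def mgmt():
    return ManagementPolicy()


@pytest.fixture(scope="session")
def policy_annual():
    return annual_policy()
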
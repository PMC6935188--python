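import pytest

from fasdscreen import load_parameters
from fasdscreen.synthetic import make_life_table, zero_mortality_table


@pytest.fixture(scope="session")
def meconium_params():
    return load_parameters(comparison="meconium")


@pytest.fixture(scope="session")
def nst_params():
    return load_parameters(comparison="nst")


@pytest.fixture(scope="session")
def default_life_table():
    return make_life_table(end_age=18)


@pytest.fixture(scope="session")
def immortal_life_table():
    return zero_mortality_table(end_age=18)
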
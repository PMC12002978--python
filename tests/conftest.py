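import pytest

from bansim import default_parameter_table, mean_draw, zero_variance_table


@pytest.fixture(scope="session")
def table():
    return default_parameter_table()


@pytest.fixture(scope="session")
def means(table):
    return mean_draw(table)


@pytest.fixture(scope="session")
def zv_table(table):
    return zero_variance_table(table)
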
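import pytest

from ocumark.cea import run_comparison
from ocumark.parameters import default_parameter_set
from ocumark.synthetic import default_life_table


@pytest.fixture(scope="session")
def params():
    return default_parameter_set()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def base_cea(params, life_table):
    """Base-case comparison, shared across read-only tests."""
    return run_comparison(params, life_table)
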
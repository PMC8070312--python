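import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photokin import load_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    """The six fixture degradation series, ordered by composition x."""
    return sorted(load_fixture("table2"), key=lambda s: s.x)


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def bandgaps():
    return load_fixture("bandgaps")


@pytest.fixture()
def rng():
    return np.random.default_rng(20210409)
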
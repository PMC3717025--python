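import numpy as np
import pytest

from hemovoi import build_default_table, point_estimate_draw


@pytest.fixture(scope="session")
def table():
    return build_default_table()


@pytest.fixture(scope="session")
def point_draw(table):
    return point_estimate_draw(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
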
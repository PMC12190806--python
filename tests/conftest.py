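import warnings

import numpy as np
import pytest

from effscape import synthetic
from effscape.core import load_table2


@pytest.fixture(scope="session")
def table2():
    """Packaged six-population x two-season census, empty unit included."""
    return load_table2()


@pytest.fixture(scope="session")
def table2_clean(table2):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return table2.drop_empty()


@pytest.fixture(scope="session")
def scenario():
    return synthetic.paper_like(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
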
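import numpy as np
import pytest

from lcrkit.align import AlignParams
from lcrkit.simulate import SimParams, default_catalog, dense_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def dense_cat():
    return dense_catalog()


@pytest.fixture(scope="session")
def aln_params():
    return AlignParams()


@pytest.fixture(scope="session")
def sim_params():
    return SimParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_928)
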
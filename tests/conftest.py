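import numpy as np
import pytest

from solvkit import synth
from solvkit.dispersion import DispersionParams


@pytest.fixture(scope="session")
def toy_table():
    return synth.toy_element_table()


@pytest.fixture(scope="session")
def planted_params():
    return DispersionParams(s8=9.01)


@pytest.fixture(scope="session")
def small_fit_dataset(planted_params):
    records, truth = synth.gen_fit_dataset(
        10, planted_params=planted_params, seed=11
    )
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
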
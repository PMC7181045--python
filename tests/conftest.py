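import numpy as np
import pytest

from alegpr import fermentation as fm
from alegpr.data import Dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture()
def small_dataset():
    """9 samples, 7 inputs, two unlabeled rows."""
    rs = np.random.default_rng(7)
    X = rs.normal(size=(9, 7))
    y = rs.normal(size=9)
    y[[2, 5]] = np.nan
    return Dataset(ids=np.arange(9), X=X, y=y)


@pytest.fixture(scope="session")
def default_batch():
    """One simulated batch under the default study conditions (seed 1)."""
    return fm.simulate_batch(fm.KineticParams(), seed=1)


@pytest.fixture(scope="session")
def default_dataset():
    return fm.generate_dataset(fm.KineticParams(), seed=0)
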
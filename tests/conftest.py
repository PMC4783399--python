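import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hippocomp import datasets

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def table2():
    return datasets.load_fixture("table2")


@pytest.fixture(scope="session")
def table4():
    return datasets.load_fixture("table4").set_index("group_id")


@pytest.fixture(scope="session")
def group_means(table2):
    """13 groups with printed counts × 5 populations mean-count matrix."""
    return datasets.count_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20160309)


@pytest.fixture
def random_nonneg_matrix(rng):
    """A generic small strictly-positive table for CA property tests."""
    values = rng.uniform(0.5, 9.0, size=(6, 4))
    return pd.DataFrame(
        values,
        index=[f"r{i}" for i in range(6)],
        columns=[f"c{j}" for j in range(4)],
    )
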
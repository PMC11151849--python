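import numpy as np
import pytest

from mycorun import SimConfig, generate_rl_dataset, generate_rr_dataset, load_study_tables
from mycorun.pipeline import dataset_xy


@pytest.fixture(scope="session")
def tables():
    return load_study_tables()


@pytest.fixture(scope="session")
def rl_default(tables):
    """The default synthetic running-length dataset (2,048 rows, seed 1)."""
    return generate_rl_dataset(tables, SimConfig(seed=1))


@pytest.fixture(scope="session")
def rr_default(tables):
    """The default synthetic running-rate dataset (256 rows, seed 1)."""
    return generate_rr_dataset(tables, SimConfig(seed=1))


@pytest.fixture(scope="session")
def rl_xy(rl_default):
    return dataset_xy(rl_default, "rl")


@pytest.fixture(scope="session")
def rr_xy(rr_default):
    return dataset_xy(rr_default, "rr")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
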
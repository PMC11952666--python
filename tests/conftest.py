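import numpy as np
import pandas as pd
import pytest

from phosnet.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small complete dataset shared by read-only tests."""
    cfg = SimConfig(seed=11, n_proteins=300, n_phosphosites=200,
                    n_kinases=3, module_sizes=(60, 60, 60),
                    substrates_per_kinase=20)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def two_group_meta():
    def make(n_per_group: int) -> pd.Series:
        return pd.Series(["control"] * n_per_group + ["mutant"] * n_per_group)
    return make
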
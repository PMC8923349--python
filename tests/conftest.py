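import numpy as np
import pandas as pd
import pytest

from thermocrispr import SimConfig, TraitTable, phylo_covariance, read_tree, simulate_dataset


@pytest.fixture(scope="session")
def balanced_tree():
    # ((A:1,B:1):0.5,(C:0.7,D:0.7):0.8); hand-checkable covariance
    return read_tree("((A:1.0,B:1.0):0.5,(C:0.7,D:0.7):0.8):0.0;")


@pytest.fixture(scope="session")
def small_dataset():
    """60-tip synthetic dataset shared across fast tests."""
    return simulate_dataset(SimConfig(n_tips=60, seed=42))


@pytest.fixture(scope="session")
def medium_dataset():
    """300-tip synthetic dataset for window/scan tests."""
    return simulate_dataset(SimConfig(n_tips=300, seed=7))


@pytest.fixture(scope="session")
def medium_cov(medium_dataset):
    return phylo_covariance(medium_dataset.tree)


@pytest.fixture
def toy_table():
    return TraitTable(
        pd.DataFrame(
            {
                "species_id": ["A", "B", "C", "D"],
                "topt_c": [10.0, 20.0, 50.0, 60.0],
                "arrays": [1, 1, 3, 5],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
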
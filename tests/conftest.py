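import numpy as np
import pytest

import ipgtools as ig


@pytest.fixture(scope="session")
def small_dataset():
    """Default synthetic genome (3 chromosomes, ~1500 bins, 5 states)."""
    truth, contacts, tracks = ig.simulate_dataset(seed=1)
    return truth, contacts, tracks


@pytest.fixture()
def toy_bins():
    """Two tiny chromosomes at 10-kb bins."""
    return ig.BinTable.from_chromsizes({"chrA": 200_000, "chrB": 150_000}, 10_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_symmetric_matrix(bins, rng, density=1.0):
    n = bins.n_bins
    vals = rng.random((n, n)) + 0.1
    vals = (vals + vals.T) / 2
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = mask | mask.T
        vals = vals * mask
    np.fill_diagonal(vals, 0.0)
    return ig.ContactMatrix(bins, vals)
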
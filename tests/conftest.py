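import numpy as np
import pytest

import sharkpcm as sp


@pytest.fixture(scope="session")
def three_taxon_tree():
    return sp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def sharklike():
    return sp.make_sharklike_dataset(seed=3)


@pytest.fixture(scope="session")
def sharklike_obs(sharklike):
    return sp.TraitObservations.from_replicates(sharklike.replicates)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240417)


def random_yule(seed, n=8):
    return sp.simulate_yule_tree(n, 1.0, seed=seed)
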
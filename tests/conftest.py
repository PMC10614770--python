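import numpy as np
import pytest

from nucsim.fixtures import ToySpec, make_toy_nucleus


SMALL_SPEC = ToySpec(n_chains=2, beads_per_chain=20, compartment_block=4,
                     n_nucleolus=6, n_speckle=10, n_lamina=60, seed=3)

DIPLOID_SPEC = ToySpec(n_chains=4, beads_per_chain=15, compartment_block=4,
                       n_nucleolus=4, n_speckle=8, n_lamina=60,
                       diploid_pairs=True, seed=5)


@pytest.fixture(scope="session")
def small_toy():
    """A tiny nucleus shared by read-only tests."""
    return make_toy_nucleus(SMALL_SPEC)


@pytest.fixture(scope="session")
def diploid_toy():
    """A toy with homolog chain pairs, for homolog-averaging checks."""
    return make_toy_nucleus(DIPLOID_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
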
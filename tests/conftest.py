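import numpy as np
import pytest

from psgscan.selection import BranchSiteParams
from psgscan.simulate import simulate_codon_alignment, simulate_tree


@pytest.fixture(scope="session")
def four_taxon_tree():
    return simulate_tree(4, 0.05, seed=3).with_foreground("sp1")


@pytest.fixture(scope="session")
def default_params():
    return BranchSiteParams(kappa=2.0, omega0=0.2, omega2=4.0, p0=0.5, p1=0.3)


@pytest.fixture(scope="session")
def null_params():
    return BranchSiteParams(kappa=2.0, omega0=0.2, omega2=1.0, p0=0.5, p1=0.3)


@pytest.fixture(scope="session")
def small_alignment(four_taxon_tree, default_params):
    aln, truth = simulate_codon_alignment(four_taxon_tree, default_params, 20, seed=5)
    return aln, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
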
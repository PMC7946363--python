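import numpy as np
import pytest

from hapsweep.demography import get_model
from hapsweep.hapstats import HaplotypeMatrix


@pytest.fixture(scope="session")
def model_b():
    """Constant Ne = 2.7e6, the model fit to autosomal short-intron theta_W."""
    return get_model("B")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_matrix(rng, n=None, l_sites=None, missing_frac=0.0):
    """A random small haplotype matrix for oracle comparisons."""
    n = n or int(rng.integers(2, 21))
    l_sites = l_sites or int(rng.integers(1, 11))
    alleles = rng.integers(0, 2, size=(n, l_sites)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(alleles.shape) < missing_frac
        # never blank out an entire row
        for i in range(n):
            if mask[i].all():
                mask[i, int(rng.integers(l_sites))] = False
        alleles[mask] = -1
    positions = np.cumsum(rng.integers(1, 100, size=l_sites)).astype(np.int64)
    return HaplotypeMatrix(alleles=alleles, positions=positions)


@pytest.fixture
def make_random_matrix(rng):
    def _make(**kwargs):
        return random_matrix(rng, **kwargs)

    return _make
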
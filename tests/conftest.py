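import numpy as np
import pytest

from ailmap import sim
from ailmap.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def gmap():
    return sim.GeneticMap()


@pytest.fixture(scope="session")
def grid(gmap):
    return sim.snp_grid(gmap)


def make_gm(haps, positions=None, chrom="1", phased=True, ids=None):
    """Small GenotypeMatrix from an (n, m, 2) allele array."""
    haps = np.asarray(haps, dtype=np.int8)
    n, m, _ = haps.shape
    if positions is None:
        positions = np.arange(m) * 10
    if ids is None:
        ids = np.array([f"s{p}" for p in positions])
    return GenotypeMatrix(chrom, np.asarray(positions), np.asarray(ids),
                          [f"i{i}" for i in range(n)], haps, phased)


def gm_from_chromatids(chromatids, positions=None, **kw):
    """GenotypeMatrix from a (2n, m) chromatid array (rows 2i, 2i+1 pair up)."""
    c = np.asarray(chromatids, dtype=np.int8)
    haps = c.reshape(c.shape[0] // 2, 2, c.shape[1]).transpose(0, 2, 1)
    return make_gm(haps, positions, **kw)
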
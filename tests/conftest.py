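import numpy as np
import pytest

from crossbredsim import genome as gn
from crossbredsim.config import make_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def tiny_genome():
    """2 chromosomes, 200 markers + 20 QTL, 40-individual pool."""
    return make_fixture("tiny-genome", seed=7)


@pytest.fixture()
def small_map():
    r = np.random.default_rng(99)
    return gn.GenomeMap.random(2, 50.0, 60, 10, r)


def make_cohort(gmap, n, breed="P1", seed=0, freqs=None):
    """Random-mating cohort at given allele frequencies (default 0.5)."""
    r = np.random.default_rng(seed)
    p = np.full(gmap.n_loci, 0.5) if freqs is None else np.asarray(freqs)
    bits = (r.random((n, 2, gmap.n_loci)) < p).astype(np.uint8)
    sex = gn._balanced_sexes(n, r)
    return gn.Cohort(
        ids=np.arange(n, dtype=np.int64),
        sex=sex,
        breed=breed,
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        generation=0,
        packed=gn.pack_haplotypes(bits),
        n_loci=gmap.n_loci,
    )
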
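import numpy as np
import pytest

from epiproto.dataset import GenotypeDataset
from epiproto.prototype_selection import build_library


@pytest.fixture(scope="session")
def library():
    """Default K=7 prototype library at prevalence = heritability = 0.02."""
    return build_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_dataset(rng):
    """30 individuals x 6 SNPs with a couple of missing genotypes."""
    geno = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
    geno[3, 1] = -1
    geno[17, 4] = -1
    pheno = np.zeros(30, dtype=np.int8)
    pheno[:15] = 1
    return GenotypeDataset(genotypes=geno, phenotype=pheno, orient=False)
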
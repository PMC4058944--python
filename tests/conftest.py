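import numpy as np
import pytest

from plasmacnv.allele_model import SnpSite
from plasmacnv.simulate import TrioSimConfig, simulate_trio


@pytest.fixture
def het_site():
    """Mother heterozygous A/C, father homozygous C, with balanced counts."""
    return SnpSite(
        chrom="chr1",
        pos=1000,
        maternal_haps=("A", "C"),
        paternal_haps=("C", "C"),
        maternal_counts={"A": 16, "C": 16, "G": 0, "T": 0},
        plasma_counts={"A": 40, "C": 40, "G": 0, "T": 0},
    )


@pytest.fixture(scope="session")
def small_trio():
    """A 3000-SNP CNV-free synthetic trio dataset (about 3 Mb)."""
    cfg = TrioSimConfig(n_snps=3000, seed=7)
    return simulate_trio(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
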
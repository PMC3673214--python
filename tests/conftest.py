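import numpy as np
import pytest

from lmmset.genio import GenotypeData, SnpRecord
from lmmset.simulate import SimConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_genotype_data(dosage, phenotype=None, cm_spacing=0.5, chrom="1"):
    """Wrap a raw dosage matrix in GenotypeData with evenly spaced SNPs."""
    dosage = np.asarray(dosage, dtype=float)
    n, s = dosage.shape
    snps = [
        SnpRecord(snp_id=f"rs{j}", chromosome=chrom,
                  position_bp=int(j * cm_spacing * 1e6),
                  position_cm=j * cm_spacing,
                  allele_minor="A", allele_major="B")
        for j in range(s)
    ]
    individuals = [(f"F{i}", f"I{i}") for i in range(n)]
    return GenotypeData(individuals=individuals, snps=snps, dosage=dosage,
                        phenotype=None if phenotype is None
                        else np.asarray(phenotype, dtype=float))


@pytest.fixture
def tiny_data():
    """3 individuals x 2 SNPs, one heterozygous call per individual."""
    dosage = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 1.0]])
    return make_genotype_data(dosage, phenotype=[0.1, 1.2, -0.3])


@pytest.fixture(scope="session")
def small_cohort():
    """A structured 300 x 600 cohort shared across tests (read-only)."""
    cfg = SimConfig(n_individuals=300, n_snps=600, n_sets=30,
                    set_size_fixed=4, seed=7)
    data = simulate_genotypes(cfg)
    return data, cfg
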
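import numpy as np
import pytest

from popdog import GenotypePanel, Individual, SimConfig, SnpRecord, simulate_panel


def make_panel(genotypes, populations=None, chroms=None, positions=None, alleles=None):
    """Build a small panel from a genotype matrix (rows = individuals)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_snp = genotypes.shape
    if populations is None:
        populations = ["pop1"] * n_ind
    if chroms is None:
        chroms = ["1"] * n_snp
    if positions is None:
        positions = list(range(1000, 1000 + 1000 * n_snp, 1000))
    if alleles is None:
        alleles = [("A", "B")] * n_snp
    individuals = [
        Individual(id=f"ind{i + 1}", population=p) for i, p in enumerate(populations)
    ]
    snps = [
        SnpRecord(f"snp{j + 1}", str(c), int(p), a, b)
        for j, (c, p, (a, b)) in enumerate(zip(chroms, positions, alleles))
    ]
    return GenotypePanel(individuals, snps, genotypes)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two moderately diverged populations with some missingness."""
    cfg = SimConfig(
        n_pops=2,
        n_per_pop=25,
        n_chrom=2,
        chrom_length_bp=8_000_000,
        fst_param=0.1,
        founders_per_pop=30,
        missing_rate=0.02,
        seed=42,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def multi_pop_panel():
    """Five populations, enough windows for a small scan."""
    cfg = SimConfig(
        n_pops=5,
        n_per_pop=12,
        n_chrom=2,
        chrom_length_bp=10_000_000,
        fst_param=0.1,
        founders_per_pop=30,
        seed=7,
    )
    return simulate_panel(cfg)
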
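"""Per-population genetic-variability indices and allele-sharing distances.

Implements the standard breed-level summary battery for SNP-array panels:
proportion of polymorphic markers (P_N), rarefied allelic richness (A_R),
expected/observed heterozygosity (H_E, H_O), a method-of-moments inbreeding
coefficient (F), and the 1 − IBS allele-sharing distance matrix between
individuals that feeds the neighbor-joining trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel


@dataclass
class DiversityIndices:
    population: str
    n_individuals: int
    p_n: float
    a_r: float
    h_e: float
    h_o: float
    f_mean: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(v).any():
            raise ValueError("distance matrix diagonal must be zero")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix must be finite")
        self.values = v

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{d:.6f}" for d in row) + "\n")


def _single_population(panel: GenotypePanel) -> None:
    if len(panel.populations) != 1:
        raise ValueError("panel must be restricted to a single population")


def proportion_polymorphic(panel: GenotypePanel) -> float:
    """Fraction of the panel's SNPs segregating within this population.

    The panel is expected to be pre-restricted to the SNP subset of interest
    (e.g. a cohort-wide MAF floor) and to one population; P_N is then the
    fraction of those SNPs with within-population MAF > 0.
    """
    _single_population(panel)
    if panel.n_snps == 0:
        raise ValueError("empty SNP set")
    maf = panel.minor_allele_frequency()
    maf = np.minimum(maf, 1 - maf)
    return float(np.nanmean(maf > 0))


def heterozygosity(panel: GenotypePanel) -> tuple[float, float]:
    """Mean expected (2p(1−p)) and observed heterozygosity over SNPs.

    SNPs with zero non-missing calls are excluded from both means.
    """
    _single_population(panel)
    called = panel.genotypes != MISSING
    n_called = called.sum(axis=0)
    ok = n_called > 0
    if not ok.any():
        raise ValueError("no SNP has any called genotype")
    p = panel.minor_allele_frequency()[ok]
    h_e = 2 * p * (1 - p)
    het = (panel.genotypes == 1).sum(axis=0)[ok]
    h_o = het / n_called[ok]
    return float(h_e.mean()), float(h_o.mean())


def allelic_richness(panel: GenotypePanel, g: int) -> float:
    """Rarefied allelic richness at standardized sample size ``g`` copies.

    Per SNP with N non-missing allele copies of which N_a are allele a,

        A_R = sum_a [1 − C(N−N_a, g) / C(N, g)],

    the expected number of distinct alleles in a random subsample of g
    copies. SNPs with N < g are excluded; the mean over SNPs is returned.
    For biallelic data the result lies in [1, 2].
    """
    _single_population(panel)
    if g < 1:
        raise ValueError("g must be >= 1")
    called = panel.genotypes != MISSING
    n = 2 * called.sum(axis=0)
    nb = np.where(called, panel.genotypes, 0).sum(axis=0)
    na = n - nb
    ok = n >= g
    if not ok.any():
        raise ValueError(f"no SNP has >= {g} allele copies")
    n, na, nb = n[ok], na[ok], nb[ok]

    def log_choose(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    def present_prob(copies):
        # P(allele appears in a subsample of g) = 1 - C(n-copies, g)/C(n, g)
        miss = np.where(
            n - copies >= g, np.exp(log_choose(n - copies, g) - log_choose(n, g)), 0.0
        )
        return np.where(copies > 0, 1.0 - miss, 0.0)

    return float((present_prob(na) + present_prob(nb)).mean())


def inbreeding_coefficient(panel: GenotypePanel) -> np.ndarray:
    """Method-of-moments per-individual inbreeding coefficient F.

        F = (O_hom − E_hom) / (L_used − E_hom)

    with O_hom the individual's observed homozygous count over its
    non-missing SNPs and E_hom the Hardy–Weinberg expectation with the
    small-sample correction 2p(1−p)·n/(n−1), n counted in allele copies.
    Individuals for which every SNP is uninformative get NaN.
    """
    _single_population(panel)
    called = panel.genotypes != MISSING
    n_copies = 2 * called.sum(axis=0)
    p = panel.minor_allele_frequency()
    with np.errstate(invalid="ignore", divide="ignore"):
        e_het_snp = 2 * p * (1 - p) * n_copies / (n_copies - 1)
    e_het_snp = np.where(n_copies > 1, e_het_snp, np.nan)
    usable = called & ~np.isnan(e_het_snp)

    o_hom = ((panel.genotypes != 1) & usable).sum(axis=1).astype(float)
    e_hom = np.where(usable, 1.0 - e_het_snp, 0.0).sum(axis=1)
    l_used = usable.sum(axis=1).astype(float)
    denom = l_used - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / denom
    return np.where(np.abs(denom) > 1e-9, f, np.nan)


def ibs_distance_matrix(panel: GenotypePanel) -> DistanceMatrix:
    """1 − IBS allele-sharing distance between all pairs of individuals.

    For each pair, similarity = shared allele copies / (2 × jointly called
    SNPs); genotype codes sharing: identical → 2 (het–het counts 2, the
    PLINK convention), |difference| = 1 → 1, opposite homozygotes → 0.
    """
    if panel.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    g = panel.genotypes.astype(np.int16)
    called = g != MISSING
    n = panel.n_individuals
    dist = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        joint = both.sum(axis=1)
        if (joint == 0).any():
            bad = np.flatnonzero(joint == 0)[0] + i + 1
            raise ValueError(
                f"individuals {panel.individuals[i].id} and "
                f"{panel.individuals[bad].id} share no called SNPs"
            )
        shared = np.where(both, 2 - np.abs(g[i] - g[i + 1 :]), 0).sum(axis=1)
        d = 1.0 - shared / (2.0 * joint)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return DistanceMatrix(panel.individual_ids, dist)


def population_distance_matrix(dist: DistanceMatrix, populations: list[str]) -> DistanceMatrix:
    """Collapse an individual-level matrix to population level by averaging
    between-population entries (within-population diagonal set to 0)."""
    if len(populations) != len(dist.labels):
        raise ValueError("one population label per individual required")
    pops = list(dict.fromkeys(populations))
    out = np.zeros((len(pops), len(pops)))
    arr = np.asarray(populations)
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i < j:
                block = dist.values[np.ix_(arr == a, arr == b)]
                out[i, j] = out[j, i] = block.mean()
    return DistanceMatrix(pops, out)


def diversity_table(
    panel: GenotypePanel,
    maf_floor: float = 0.1,
    g: int | None = None,
) -> pd.DataFrame:
    """Per-population summary table (P_N, A_R, H_E, H_O, F).

    P_N and A_R are evaluated on the SNP subset passing a cohort-wide MAF
    floor (default 0.1). ``g`` defaults to twice the smallest population's
    individual count, the largest standardized size shared by all groups.
    """
    maf = panel.minor_allele_frequency()
    maf = np.minimum(maf, 1 - maf)
    subset = panel.take_snps(maf > maf_floor)
    pops = panel.populations
    if g is None:
        g = 2 * min(sum(ind.population == p for ind in panel.individuals) for p in pops)
    rows = []
    for pop in pops:
        sub_all = panel.subset(populations=[pop])
        sub_floor = subset.subset(populations=[pop])
        h_e, h_o = heterozygosity(sub_all)
        f = inbreeding_coefficient(sub_all)
        rows.append(
            DiversityIndices(
                population=pop,
                n_individuals=sub_all.n_individuals,
                p_n=proportion_polymorphic(sub_floor),
                a_r=allelic_richness(sub_floor, g=g),
                h_e=h_e,
                h_o=h_o,
                f_mean=float(np.nanmean(f)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
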
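"""In-memory genotype panel and quality-control filters.

The central container is :class:`GenotypePanel`: an individuals × SNPs matrix
of biallelic genotype codes counting copies of the minor allele (``allele_b``),
with ``-1`` marking a missing call. All downstream stages (diversity, LD, ROH,
F_ST, selection scans, structure) operate on this container.

Coordinates are 1-based physical positions, as in PLINK MAP/BIM files; interval
outputs throughout the package are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

AUTOSOMES = tuple(str(c) for c in range(1, 39))  # dog karyotype: 38 autosomes


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic marker.

    ``allele_a`` is the major (reference) allele, ``allele_b`` the minor
    allele whose copies the genotype codes count.
    """

    id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.id}: alleles must differ")


@dataclass(frozen=True)
class Individual:
    """One sample with its population (breed) assignment."""

    id: str
    population: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"individual {self.id}: population must be non-empty")


@dataclass
class QcReport:
    """Bookkeeping for one filtering step."""

    n_snps_in: int
    n_snps_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_individuals: list[tuple[str, str]] = field(default_factory=list)


class GenotypePanel:
    """Individuals × SNPs genotype matrix with map and population labels.

    Parameters
    ----------
    individuals
        Ordered samples.
    snps
        Ordered markers; within each chromosome, sorted by position.
    genotypes
        ``(n_individuals, n_snps)`` int8 array with entries in
        ``{0, 1, 2, MISSING}`` counting copies of ``allele_b``.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        snps: Sequence[SnpRecord],
        genotypes: np.ndarray,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(individuals), len(snps)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(individuals)} individuals x {len(snps)} SNPs"
            )
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        self.individuals = list(individuals)
        self.snps = list(snps)
        self.genotypes = genotypes
        self._check_sorted()

    def _check_sorted(self) -> None:
        last: dict[str, int] = {}
        for s in self.snps:
            if s.chrom in last and s.pos_bp < last[s.chrom]:
                raise ValueError(f"SNPs on chromosome {s.chrom} not sorted by position")
            last[s.chrom] = s.pos_bp

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def populations(self) -> list[str]:
        """Distinct population codes in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    @property
    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps], dtype=object)

    def population_mask(self, population: str) -> np.ndarray:
        mask = np.array([ind.population == population for ind in self.individuals])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.snp_ids,
                "chrom": self.chromosomes,
                "pos_bp": self.positions,
                "allele_a": [s.allele_a for s in self.snps],
                "allele_b": [s.allele_b for s in self.snps],
            }
        )

    # -- frequency bookkeeping -------------------------------------------
    def minor_allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele_b among non-missing calls.

        SNPs with zero calls get NaN.
        """
        called = self.genotypes != MISSING
        n_copies = 2 * called.sum(axis=0)
        b_copies = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = b_copies / n_copies
        return np.where(n_copies > 0, freq, np.nan)

    def snp_call_rate(self) -> np.ndarray:
        if self.n_individuals == 0:
            raise ValueError("panel has no individuals")
        return (self.genotypes != MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            raise ValueError("panel has no SNPs")
        return (self.genotypes != MISSING).mean(axis=1)

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        populations: Iterable[str] | None = None,
        individuals: Iterable[str] | None = None,
        chrom_filter: Callable[[str], bool] | None = None,
    ) -> "GenotypePanel":
        """Restrict the panel, preserving order on both axes."""
        row_mask = np.ones(self.n_individuals, dtype=bool)
        if populations is not None:
            wanted = set(populations)
            present = set(ind.population for ind in self.individuals)
            unknown = wanted - present
            if unknown:
                raise KeyError(f"unknown populations: {sorted(unknown)}")
            row_mask &= np.array([ind.population in wanted for ind in self.individuals])
        if individuals is not None:
            wanted_ids = set(individuals)
            present_ids = set(self.individual_ids)
            unknown = wanted_ids - present_ids
            if unknown:
                raise KeyError(f"unknown individuals: {sorted(unknown)}")
            row_mask &= np.array([ind.id in wanted_ids for ind in self.individuals])
        col_mask = np.ones(self.n_snps, dtype=bool)
        if chrom_filter is not None:
            col_mask = np.array([chrom_filter(s.chrom) for s in self.snps])
        return GenotypePanel(
            [ind for ind, keep in zip(self.individuals, row_mask) if keep],
            [s for s, keep in zip(self.snps, col_mask) if keep],
            self.genotypes[np.ix_(row_mask, col_mask)],
        )

    def autosomal(self) -> "GenotypePanel":
        """Drop sex-chromosome markers (everything not named 1..38)."""
        return self.subset(chrom_filter=lambda c: c in AUTOSOMES)

    def take_snps(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_snps, dtype=bool)
            idx[mask] = True
            mask = idx
        return GenotypePanel(
            self.individuals,
            [s for s, keep in zip(self.snps, mask) if keep],
            self.genotypes[:, mask],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypePanel({self.n_individuals} individuals x {self.n_snps} SNPs, "
            f"{len(self.populations)} populations)"
        )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_snps(
    panel: GenotypePanel, maf_min: float = 0.01, call_rate_min: float = 0.90
) -> tuple[GenotypePanel, QcReport]:
    """Drop SNPs with MAF below ``maf_min`` or call rate below ``call_rate_min``.

    MAF is computed over non-missing calls across all individuals. Retained
    SNPs satisfy MAF >= maf_min AND call rate >= call_rate_min.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must be in [0, 1]")
    if panel.n_individuals == 0:
        raise ValueError("panel has no individuals")
    maf = panel.minor_allele_frequency()
    maf = np.minimum(maf, 1 - maf)  # guard: allele_b should be minor already
    call = panel.snp_call_rate()
    with np.errstate(invalid="ignore"):
        low_maf = ~(maf >= maf_min)  # NaN (all-missing) counts as failing
        low_call = call < call_rate_min
    keep = ~(low_maf | low_call)
    removed = []
    for s, lm, lc in zip(panel.snps, low_maf, low_call):
        if lm:
            removed.append((s.id, "maf"))
        elif lc:
            removed.append((s.id, "call_rate"))
    out = panel.take_snps(keep)
    report = QcReport(
        n_snps_in=panel.n_snps,
        n_snps_out=out.n_snps,
        n_individuals_in=panel.n_individuals,
        n_individuals_out=out.n_individuals,
        removed_snps=removed,
    )
    return out, report


def filter_individuals(
    panel: GenotypePanel, call_rate_min: float = 0.95
) -> tuple[GenotypePanel, QcReport]:
    """Drop individuals whose genotype call rate is below ``call_rate_min``."""
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must be in [0, 1]")
    rate = panel.individual_call_rate()
    keep = rate >= call_rate_min
    if not keep.any():
        raise ValueError("all individuals removed by call-rate filter")
    removed = [
        (ind.id, "call_rate") for ind, k in zip(panel.individuals, keep) if not k
    ]
    out = GenotypePanel(
        [ind for ind, k in zip(panel.individuals, keep) if k],
        panel.snps,
        panel.genotypes[keep],
    )
    report = QcReport(
        n_snps_in=panel.n_snps,
        n_snps_out=out.n_snps,
        n_individuals_in=panel.n_individuals,
        n_individuals_out=out.n_individuals,
        removed_individuals=removed,
    )
    return out, report
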
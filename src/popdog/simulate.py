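"""Synthetic multi-population SNP-panel simulator.

Generates biallelic autosomal genotype panels with known, controllable
structure so that every analysis stage has ground truth:

* **Divergence** follows the Balding–Nichols model: each population's allele
  frequency at a SNP is Beta-distributed around an ancestral frequency with
  parameter ``F`` — the expected mean-square F_ST between the population and
  the ancestral pool, which makes ``F`` an analytic recovery target for the
  F_ST estimator.
* **LD and runs of homozygosity** arise from founder-mosaic copying: each
  population has a small pool of founder haplotypes and every simulated
  chromosome is a recombinant mosaic of them. Fewer founders means longer
  shared haplotypes, hence more LD and longer ROH — the two dials the
  downstream monotonicity checks turn.
* **Selection signatures** are planted by shifting the focal population's
  allele frequencies inside chosen windows before the genotype draw.
* **Introgression** is planted by mixing a source population's frequencies
  into a target population (``admix_events``), the signal the ABBA-BABA
  D-statistic detects.

Randomness is a single seed split into four named streams in fixed order
(frequencies, founders, mosaics, missingness), so panels are reproducible
and enlarging one stage does not perturb the others' draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import MISSING, GenotypePanel, Individual, SnpRecord

# Scale of the study system this simulator emulates: a dog SNP-array panel
# averaging ~12.5 SNPs per 200-kb window across 38 autosomes.
DEFAULT_SNP_DENSITY = 12.5 / 200_000


@dataclass(frozen=True)
class SelectionTarget:
    """A planted sweep: shift the focal population's frequencies in a window."""

    pop: str
    chrom: str
    start_bp: int
    end_bp: int
    freq_shift: float


@dataclass(frozen=True)
class AdmixEvent:
    """Planted gene flow: target frequencies become a (1-f)/f mixture."""

    source: str
    target: str
    fraction: float


@dataclass
class SimConfig:
    n_pops: int = 2
    n_per_pop: int | Sequence[int] = 50
    n_chrom: int = 2
    chrom_length_bp: int = 25_000_000
    snp_density: float = DEFAULT_SNP_DENSITY
    fst_param: float | Sequence[float] = 0.1
    founders_per_pop: int = 50
    recomb_rate: float = 1e-8
    missing_rate: float = 0.0
    consanguinity: float = 0.0
    selection_targets: list[SelectionTarget] = field(default_factory=list)
    admix_events: list[AdmixEvent] = field(default_factory=list)
    pop_names: list[str] | None = None
    seed: int = 0

    def resolved_pop_names(self) -> list[str]:
        if self.pop_names is not None:
            if len(self.pop_names) != self.n_pops:
                raise ValueError("pop_names length must equal n_pops")
            return list(self.pop_names)
        return [f"pop{k + 1}" for k in range(self.n_pops)]

    def resolved_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_pop):
            return [int(self.n_per_pop)] * self.n_pops
        sizes = [int(n) for n in self.n_per_pop]
        if len(sizes) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        return sizes

    def resolved_fst(self) -> list[float]:
        if np.isscalar(self.fst_param):
            fs = [float(self.fst_param)] * self.n_pops
        else:
            fs = [float(f) for f in self.fst_param]
            if len(fs) != self.n_pops:
                raise ValueError("fst_param length must equal n_pops")
        for f in fs:
            if not 0 <= f < 1:
                raise ValueError("fst_param must be in [0, 1)")
        return fs

    def validate(self) -> None:
        if self.founders_per_pop < 2:
            raise ValueError("founders_per_pop must be >= 2")
        for rate in (self.missing_rate, self.recomb_rate, self.consanguinity):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        names = set(self.resolved_pop_names())
        for t in self.selection_targets:
            if t.pop not in names:
                raise ValueError(f"selection target pop {t.pop!r} not simulated")
            if not (1 <= t.start_bp <= t.end_bp <= self.chrom_length_bp):
                raise ValueError("selection target interval outside chromosome")
        for e in self.admix_events:
            if e.source not in names or e.target not in names:
                raise ValueError("admix event names a population not simulated")
            if not 0 <= e.fraction <= 1:
                raise ValueError("admix fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    pop_names: list[str]
    chroms: np.ndarray           # per-SNP chromosome label
    positions: np.ndarray        # per-SNP bp position
    ancestral_freqs: np.ndarray  # per-SNP ancestral p (of allele "B")
    pop_freqs: np.ndarray        # (n_pops, n_snps) post-divergence p_k
    selected_windows: list[SelectionTarget]
    founders_per_pop: int
    seed: int
    # per-SNP True where the allele coding was flipped so that allele_b is
    # the realized minor allele; freqs above refer to the FLIPPED allele_b
    flipped: np.ndarray | None = None
    # internal state enabling in-place regeneration of planted intervals
    founder_haps: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    mosaic_index: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "pop_names": self.pop_names,
            "seed": self.seed,
            "founders_per_pop": self.founders_per_pop,
            "n_snps": int(self.positions.size),
            "selected_windows": [
                {
                    "pop": t.pop,
                    "chrom": t.chrom,
                    "start_bp": t.start_bp,
                    "end_bp": t.end_bp,
                    "freq_shift": t.freq_shift,
                }
                for t in self.selected_windows
            ],
        }


def _snp_map(config: SimConfig, rng: np.random.Generator):
    chroms, positions = [], []
    for c in range(1, config.n_chrom + 1):
        n = rng.poisson(config.snp_density * config.chrom_length_bp)
        pos = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=n))
        chroms.append(np.full(pos.size, str(c), dtype=object))
        positions.append(pos)
    return np.concatenate(chroms), np.concatenate(positions)


def _mosaic(
    rng: np.random.Generator,
    founders: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    chrom_length_bp: int,
    recomb_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One haplotype as a recombinant mosaic of founder haplotypes.

    Returns (allele vector, founder index per SNP).
    """
    n_f = founders.shape[0]
    idx = np.empty(positions.size, dtype=np.int32)
    for chrom in np.unique(chroms):
        on = chroms == chrom
        pos = positions[on]
        n_x = rng.poisson(recomb_rate * chrom_length_bp)
        breaks = np.sort(rng.integers(1, chrom_length_bp + 1, size=n_x))
        seg_of_snp = np.searchsorted(breaks, pos, side="right")
        seg_founder = rng.integers(0, n_f, size=n_x + 1)
        idx[on] = seg_founder[seg_of_snp]
    return founders[idx, np.arange(positions.size)], idx


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a genotype panel and its ground truth.

    The draw proceeds ancestral frequencies → population frequencies
    (Balding–Nichols) → planted admixture/selection adjustments → founder
    haplotypes → individual mosaics → missingness. Deterministic under a
    fixed ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_found, rng_mosaic, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    pop_names = config.resolved_pop_names()
    sizes = config.resolved_sizes()
    fsts = config.resolved_fst()

    chroms, positions = _snp_map(config, rng_freq)
    n_snps = positions.size
    p_anc = rng_freq.uniform(0.05, 0.95, size=n_snps)

    pop_freqs = np.empty((config.n_pops, n_snps))
    for k, f in enumerate(fsts):
        if f == 0:
            pop_freqs[k] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pop_freqs[k] = rng_freq.beta(a, b)

    for e in config.admix_events:
        src = pop_names.index(e.source)
        tgt = pop_names.index(e.target)
        pop_freqs[tgt] = (1 - e.fraction) * pop_freqs[tgt] + e.fraction * pop_freqs[src]

    realized_targets: list[SelectionTarget] = []
    for t in config.selection_targets:
        on = (chroms == t.chrom) & (positions >= t.start_bp) & (positions <= t.end_bp)
        if not on.any():
            warnings.warn(
                f"selection target {t} contains no SNPs; dropped", stacklevel=2
            )
            continue
        k = pop_names.index(t.pop)
        pop_freqs[k, on] = np.clip(pop_freqs[k, on] + t.freq_shift, 0.02, 0.98)
        realized_targets.append(t)

    truth = SimTruth(
        pop_names=pop_names,
        chroms=chroms,
        positions=positions,
        ancestral_freqs=p_anc,
        pop_freqs=pop_freqs,
        selected_windows=realized_targets,
        founders_per_pop=config.founders_per_pop,
        seed=config.seed,
    )

    individuals: list[Individual] = []
    hap_rows = []
    for k, name in enumerate(pop_names):
        founders = (
            rng_found.random((config.founders_per_pop, n_snps)) < pop_freqs[k]
        ).astype(np.int8)
        truth.founder_haps[name] = founders
        n_hap = 2 * sizes[k]
        mosaic_idx = np.empty((n_hap, n_snps), dtype=np.int32)
        haps = np.empty((n_hap, n_snps), dtype=np.int8)
        chrom_labels = np.unique(chroms)
        for j in range(sizes[k]):
            h1, h2 = 2 * j, 2 * j + 1
            for h in (h1, h2):
                haps[h], mosaic_idx[h] = _mosaic(
                    rng_mosaic, founders, chroms, positions,
                    config.chrom_length_bp, config.recomb_rate,
                )
            if config.consanguinity > 0:
                # autozygosity: the second haplotype copies the first's
                # founder mosaic on a whole-chromosome basis
                for chrom in chrom_labels:
                    if rng_mosaic.random() < config.consanguinity:
                        on = chroms == chrom
                        mosaic_idx[h2, on] = mosaic_idx[h1, on]
                        haps[h2, on] = haps[h1, on]
        truth.mosaic_index[name] = mosaic_idx
        hap_rows.append(haps)
        individuals += [
            Individual(id=f"{name}_i{j + 1}", population=name)
            for j in range(sizes[k])
        ]

    haps = np.concatenate(hap_rows, axis=0)
    geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng_miss.random(geno.shape) < config.missing_rate
        geno[drop] = MISSING

    # canonicalize coding: allele_b must be the realized minor allele (the
    # convention the PLINK readers re-derive), ties going to the
    # lexicographically first allele ("A")
    called = geno != MISSING
    b_copies = np.where(called, geno, 0).sum(axis=0)
    n_copies = 2 * called.sum(axis=0)
    flip = (2 * b_copies >= n_copies) & (n_copies > 0)
    geno[:, flip] = np.where(
        geno[:, flip] == MISSING, MISSING, 2 - geno[:, flip]
    ).astype(np.int8)
    truth.flipped = flip
    truth.ancestral_freqs = np.where(flip, 1 - p_anc, p_anc)
    truth.pop_freqs = np.where(flip, 1 - pop_freqs, pop_freqs)
    for name in pop_names:
        fh = truth.founder_haps[name]
        fh[:, flip] = 1 - fh[:, flip]

    snps = [
        SnpRecord(
            f"snp_{c}_{p}",
            c,
            int(p),
            "B" if fl else "A",
            "A" if fl else "B",
        )
        for c, p, fl in zip(chroms, positions, flip)
    ]
    return GenotypePanel(individuals, snps, geno), truth


def plant_selection(
    truth: SimTruth,
    panel: GenotypePanel,
    targets: Sequence[SelectionTarget],
    seed: int | None = None,
) -> tuple[GenotypePanel, SimTruth]:
    """Plant sweeps into an already-simulated panel.

    Shifts the focal population's frequency inside each target interval and
    regenerates that population's founder alleles (and hence genotypes,
    through the stored mosaic) at the affected SNPs only; everything outside
    the intervals is untouched.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(truth.seed if seed is None else seed).spawn(5)[4]
    )
    geno = panel.genotypes.copy()
    pop_freqs = truth.pop_freqs.copy()
    realized = list(truth.selected_windows)
    for t in targets:
        if t.freq_shift == 0:
            realized.append(t)
            continue
        if t.pop not in truth.pop_names:
            raise KeyError(f"unknown population {t.pop!r}")
        if not (truth.chroms == t.chrom).any():
            raise ValueError(f"target chromosome {t.chrom!r} absent from panel")
        on = (
            (truth.chroms == t.chrom)
            & (truth.positions >= t.start_bp)
            & (truth.positions <= t.end_bp)
        )
        if not on.any():
            warnings.warn(
                f"selection target {t} contains no SNPs; dropped", stacklevel=2
            )
            continue
        k = truth.pop_names.index(t.pop)
        shifted = np.clip(pop_freqs[k, on] + t.freq_shift, 0.02, 0.98)
        pop_freqs[k, on] = shifted
        founders = truth.founder_haps[t.pop]
        founders[:, on] = (
            rng.random((founders.shape[0], int(on.sum()))) < shifted
        ).astype(np.int8)
        mosaic = truth.mosaic_index[t.pop]
        cols = np.flatnonzero(on)
        haps = founders[mosaic[:, cols], cols]
        rows = np.flatnonzero(panel.population_mask(t.pop))
        new_geno = (haps[0::2] + haps[1::2]).astype(np.int8)
        old = geno[np.ix_(rows, cols)]
        new_geno[old == MISSING] = MISSING  # preserve the missingness pattern
        geno[np.ix_(rows, cols)] = new_geno
        realized.append(t)

    new_truth = SimTruth(
        pop_names=truth.pop_names,
        chroms=truth.chroms,
        positions=truth.positions,
        ancestral_freqs=truth.ancestral_freqs,
        pop_freqs=pop_freqs,
        selected_windows=realized,
        founders_per_pop=truth.founders_per_pop,
        seed=truth.seed,
        founder_haps=truth.founder_haps,
        mosaic_index=truth.mosaic_index,
    )
    return GenotypePanel(panel.individuals, panel.snps, geno), new_truth
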
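"""Population differentiation: mean-square F_ST and ABBA-BABA D-statistics.

The F_ST estimator is the ANOVA-style (Weir–Cockerham family) per-SNP
estimator built from within- and between-population mean squares of allele
frequency:

    MSG  = [1 / Σ_i (n_i − 1)] Σ_i n_i p_i (1 − p_i)
    MSP  = [1 / (s − 1)] Σ_i n_i (p_i − p̄)²,  p̄ = Σ n_i p_i / Σ n_i
    n_c  = [1 / (s − 1)] (Σ n_i − Σ n_i² / Σ n_i)
    F_ST = (MSP − MSG) / (MSP + (n_c − 1) MSG)

with n_i the i-th population's sample size in allele copies (2 × called
individuals) and s the number of populations. Negative raw values are
biologically meaningless and truncated to 0 for reporting, but the raw
values are preserved for downstream standardization (the d_i scan).

The MSG denominator is configurable (``msg_denominator``): ``"n-1"``
(default, Σ(n_i−1), the unbiased within-group mean square) or ``"n"``
(Σn_i).

The D-statistic is the frequency-based 4-taxon ABBA-BABA test with a
delete-one block jackknife over contiguous SNP blocks for significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclass
class AlleleFrequencyTable:
    """Per-population sample allele frequencies and sizes per SNP.

    ``freqs`` and ``sizes`` are ``(n_pops, n_snps)``; sizes count non-missing
    allele copies. SNPs where a population has no calls carry size 0 there.
    """

    populations: list[str]
    snp_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    freqs: np.ndarray
    sizes: np.ndarray


@dataclass
class FstComponents:
    """Per-SNP mean squares and the resulting F_ST for a population set."""

    populations: list[str]
    snp_ids: list[str]
    msg: np.ndarray
    msp: np.ndarray
    n_c: np.ndarray
    fst_raw: np.ndarray       # may be negative; NaN where undefined
    fst_reported: np.ndarray  # max(raw, 0); NaN where undefined

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.fst_raw)


@dataclass
class DstatResult:
    quartet: tuple[str, str, str, str]
    d: float
    z: float
    n_blocks: int
    n_snps: int


def allele_frequencies(
    panel: GenotypePanel, populations: list[str] | None = None
) -> AlleleFrequencyTable:
    """Sample frequency of allele_b and allele-copy counts per population."""
    pops = populations if populations is not None else panel.populations
    freqs = np.empty((len(pops), panel.n_snps))
    sizes = np.empty((len(pops), panel.n_snps))
    for k, pop in enumerate(pops):
        rows = panel.population_mask(pop)
        g = panel.genotypes[rows]
        called = g != MISSING
        n = 2 * called.sum(axis=0)
        b = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(n > 0, b / np.maximum(n, 1), np.nan)
        sizes[k] = n
    return AlleleFrequencyTable(
        populations=list(pops),
        snp_ids=panel.snp_ids,
        chroms=panel.chromosomes,
        positions=panel.positions,
        freqs=freqs,
        sizes=sizes,
    )


def per_snp_fst(
    table: AlleleFrequencyTable, msg_denominator: str = "n-1"
) -> FstComponents:
    """Per-SNP mean-square F_ST over the table's populations.

    SNPs are undefined (NaN) where fewer than two populations have n_i ≥ 2,
    or where the locus is monomorphic across all populations (0/0).
    """
    if msg_denominator not in ("n-1", "n"):
        raise ValueError("msg_denominator must be 'n-1' or 'n'")
    p = table.freqs
    n = table.sizes.astype(float)
    use = (n >= 2) & ~np.isnan(p)
    s_eff = use.sum(axis=0)
    ok = s_eff >= 2

    n_u = np.where(use, n, 0.0)
    p_u = np.where(use, p, 0.0)
    n_tot = n_u.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n_u * p_u).sum(axis=0) / n_tot
        denom_g = (
            (n_u - use).sum(axis=0) if msg_denominator == "n-1" else n_tot
        )
        msg = (n_u * p_u * (1 - p_u)).sum(axis=0) / denom_g
        msp = (n_u * (p_u - p_bar) ** 2 * use).sum(axis=0) / (s_eff - 1)
        n_c = (n_tot - (n_u**2).sum(axis=0) / n_tot) / (s_eff - 1)
        fst_den = msp + (n_c - 1) * msg
        fst_raw = (msp - msg) / fst_den

    defined = ok & (np.abs(fst_den) > 0)
    fst_raw = np.where(defined, fst_raw, np.nan)
    return FstComponents(
        populations=table.populations,
        snp_ids=table.snp_ids,
        msg=np.where(ok, msg, np.nan),
        msp=np.where(ok, msp, np.nan),
        n_c=np.where(ok, n_c, np.nan),
        fst_raw=fst_raw,
        fst_reported=np.where(defined, np.maximum(fst_raw, 0.0), np.nan),
    )


def mean_fst(components: FstComponents) -> float:
    """Mean reported F_ST over defined (informative) SNPs."""
    if not components.defined.any():
        raise ValueError("no defined SNP for this population set")
    return float(np.nanmean(components.fst_reported))


def pairwise_fst_matrix(
    panel: GenotypePanel, msg_denominator: str = "n-1"
) -> pd.DataFrame:
    """Symmetric matrix of mean reported pairwise F_ST between populations."""
    pops = panel.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    table = allele_frequencies(panel)
    out = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub = AlleleFrequencyTable(
                populations=[pops[i], pops[j]],
                snp_ids=table.snp_ids,
                chroms=table.chroms,
                positions=table.positions,
                freqs=table.freqs[[i, j]],
                sizes=table.sizes[[i, j]],
            )
            comp = per_snp_fst(sub, msg_denominator=msg_denominator)
            out[i, j] = out[j, i] = mean_fst(comp)
    return pd.DataFrame(out, index=pops, columns=pops)


def fst_table(components: FstComponents, table: AlleleFrequencyTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": components.snp_ids,
            "chrom": table.chroms,
            "pos_bp": table.positions,
            "msg": components.msg,
            "msp": components.msp,
            "n_c": components.n_c,
            "fst_raw": components.fst_raw,
            "fst_reported": components.fst_reported,
        }
    )


# ---------------------------------------------------------------------------
# ABBA-BABA
# ---------------------------------------------------------------------------

def d_statistic(
    table: AlleleFrequencyTable,
    quartet: tuple[str, str, str, str] | None = None,
    block_snps: int = 300,
) -> DstatResult:
    """Frequency-based ABBA-BABA D for the quartet (P1, P2, P3, Outgroup).

        D = Σ [ABBA − BABA] / Σ [ABBA + BABA],
        ABBA = (1−p1) p2 p3 (1−pO),  BABA = p1 (1−p2) p3 (1−pO)

    summed over SNPs with defined frequencies in all four populations.
    Z is from a delete-one jackknife over contiguous blocks of
    ``block_snps`` map-ordered SNPs; blocks absorb the partial remainder.
    """
    if quartet is None:
        if len(table.populations) != 4:
            raise ValueError("quartet required unless the table has 4 populations")
        quartet = tuple(table.populations)
    idx = [table.populations.index(q) for q in quartet]
    p1, p2, p3, po = (table.freqs[i] for i in idx)
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
    p1, p2, p3, po = p1[ok], p2[ok], p3[ok], po[ok]
    if p1.size == 0:
        raise ValueError("no SNP with defined frequencies in all four populations")
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    num, den = (abba - baba), (abba + baba)
    if den.sum() == 0:
        raise ValueError("D undefined: zero ABBA+BABA total")
    d = float(num.sum() / den.sum())

    n_blocks = max(p1.size // block_snps, 1)
    bounds = np.linspace(0, p1.size, n_blocks + 1).astype(int)
    if n_blocks < 2:
        return DstatResult(quartet, d, float("nan"), n_blocks, int(p1.size))
    num_tot, den_tot = num.sum(), den.sum()
    d_loo = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        d_loo[b] = (num_tot - num[lo:hi].sum()) / (den_tot - den[lo:hi].sum())
    var = (n_blocks - 1) / n_blocks * ((d_loo - d_loo.mean()) ** 2).sum()
    if var > 0:
        z = d / np.sqrt(var)
    else:  # constant jackknife track: zero D is exactly calibrated
        z = 0.0 if d == 0 else float(np.copysign(np.inf, d))
    return DstatResult(quartet, d, float(z), n_blocks, int(p1.size))
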
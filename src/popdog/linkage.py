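"""Linkage disequilibrium and runs of homozygosity.

LD is measured as the squared Pearson correlation of genotype dosages
(composite LD; no phasing required). The module provides the pairwise r²
engine, decay-curve binning, the r²₀.₃ LD-extent summary (distance at which
smoothed mean r² decays to 0.3), greedy LD pruning, and a window-vote
run-of-homozygosity caller patterned on the classic 50-SNP sliding-window
algorithm (≤1 heterozygous and ≤5 missing calls per window, 200-kb minimum
segment length).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .panel import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RohSegment:
    individual: str
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _pair_r2(
    g: np.ndarray, called: np.ndarray, i: int, js: np.ndarray
) -> np.ndarray:
    """r² of dosage column i against columns js, pairwise-complete."""
    both = called[:, i : i + 1] & called[:, js]
    n = both.sum(axis=0).astype(float)
    x = np.where(both, g[:, i : i + 1], 0.0)
    y = np.where(both, g[:, js], 0.0)
    sx, sy = x.sum(axis=0), y.sum(axis=0)
    sxx, syy = (x * x).sum(axis=0), (y * y).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var = (n * sxx - sx * sx) * (n * syy - sy * sy)
        r2 = cov * cov / var
    r2[~(var > 0)] = np.nan  # zero-variance pair -> undefined
    return r2


def pairwise_r2(panel: GenotypePanel, max_dist_kb: float = 500.0) -> pd.DataFrame:
    """All same-chromosome dosage-r² pairs within ``max_dist_kb``.

    Returns a frame with columns snp_i, snp_j, dist_bp, r2. Pairs involving
    a zero-variance SNP are skipped.
    """
    g = panel.genotypes.astype(float)
    called = panel.genotypes != MISSING
    chroms = panel.chromosomes
    positions = panel.positions
    max_bp = int(max_dist_kb * 1000)
    out_i, out_j, out_d, out_r = [], [], [], []
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        pos = positions[cols]
        for a in range(cols.size - 1):
            hi = np.searchsorted(pos, pos[a] + max_bp, side="right")
            if hi <= a + 1:
                continue
            js = cols[a + 1 : hi]
            r2 = _pair_r2(g, called, cols[a], js)
            ok = ~np.isnan(r2)
            if not ok.any():
                continue
            out_i += [panel.snps[cols[a]].id] * int(ok.sum())
            out_j += [panel.snps[j].id for j in js[ok]]
            out_d.append(pos[a + 1 : hi][ok] - pos[a])
            out_r.append(r2[ok])
    return pd.DataFrame(
        {
            "snp_i": out_i,
            "snp_j": out_j,
            "dist_bp": np.concatenate(out_d) if out_d else np.array([], int),
            "r2": np.concatenate(out_r) if out_r else np.array([]),
        }
    )


def decay_curve(pairs: pd.DataFrame, bin_width_kb: float = 10.0) -> pd.DataFrame:
    """Bin LD pairs by distance; per-bin mean r² and pair count.

    Bin k covers [k·w, (k+1)·w) bp; ``mid_kb`` is the bin midpoint. Bins with
    no pairs have NaN mean.
    """
    if bin_width_kb <= 0:
        raise ValueError("bin_width_kb must be positive")
    if pairs.empty:
        raise ValueError("empty pair list")
    w = bin_width_kb * 1000
    idx = (pairs["dist_bp"] // w).astype(int)
    n_bins = int(idx.max()) + 1
    grouped = pairs.groupby(idx)["r2"]
    mean = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    mean[grouped.mean().index] = grouped.mean().values
    count[grouped.count().index] = grouped.count().values
    return pd.DataFrame(
        {
            "bin_lo_bp": np.arange(n_bins) * w,
            "bin_hi_bp": (np.arange(n_bins) + 1) * w,
            "mid_kb": (np.arange(n_bins) + 0.5) * bin_width_kb,
            "mean_r2": mean,
            "n_pairs": count,
        }
    )


def r2_threshold_distance(curve: pd.DataFrame, threshold: float = 0.3) -> float:
    """Distance (kb) at which the smoothed decay curve falls to ``threshold``.

    Bin means are first forced monotone non-increasing by isotonic
    regression (pair-count weighted), then the first crossing is located by
    linear interpolation between the flanking bin midpoints. Returns 0 if
    the curve never reaches the threshold, and the maximum binned distance
    (with a warning) if it never falls below it.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    use = curve[curve["n_pairs"] > 0]
    if use.empty:
        raise ValueError("decay curve has no populated bins")
    x = use["mid_kb"].to_numpy(float)
    y = IsotonicRegression(increasing=False).fit_transform(
        x, use["mean_r2"].to_numpy(float), sample_weight=use["n_pairs"].to_numpy(float)
    )
    if y.max() < threshold:
        return 0.0
    below = np.flatnonzero(y < threshold)
    if below.size == 0:
        warnings.warn(
            "mean r2 never decays below threshold within the binned range",
            stacklevel=2,
        )
        return float(x[-1])
    k = below[0]
    if k == 0:
        return float(x[0])
    return float(x[k - 1] + (y[k - 1] - threshold) / (y[k - 1] - y[k]) * (x[k] - x[k - 1]))


def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.5,
    window_snps: int = 50,
    step_snps: int = 5,
) -> list[str]:
    """Greedy LD pruning; returns the retained SNP ids.

    Windows of ``window_snps`` SNPs slide by ``step_snps`` along each
    chromosome; within a window, for every pair with r² ≥ ``r2_max`` the
    lower-MAF member is removed (tie: the later position). The retained set
    has no intra-window pair at or above the cutoff.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    g = panel.genotypes.astype(float)
    called = panel.genotypes != MISSING
    maf = panel.minor_allele_frequency()
    maf = np.minimum(maf, 1 - maf)
    chroms = panel.chromosomes
    alive = np.ones(panel.n_snps, dtype=bool)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        for start in range(0, max(cols.size - 1, 1), step_snps):
            win = cols[start : start + window_snps]
            live = [c for c in win if alive[c]]
            for ai in range(len(live)):
                a = live[ai]
                if not alive[a]:
                    continue
                others = np.array(
                    [b for b in live[ai + 1 :] if alive[b]], dtype=int
                )
                if others.size == 0:
                    continue
                r2 = _pair_r2(g, called, a, others)
                for b, r in zip(others, r2):
                    if not alive[a]:
                        break
                    if np.isnan(r) or r < r2_max:
                        continue
                    # drop the less informative member
                    if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                        alive[a] = False
                    else:
                        alive[b] = False
            if start + window_snps >= cols.size:
                break
    return [s.id for s, keep in zip(panel.snps, alive) if keep]


def detect_roh(
    panel: GenotypePanel,
    window_snps: int = 50,
    max_het_per_window: int = 1,
    max_missing_per_window: int = 5,
    min_length_kb: float = 200.0,
    min_snps: int = 25,
    hit_fraction: float = 0.05,
) -> list[RohSegment]:
    """Window-vote ROH detection, per individual and chromosome.

    A ``window_snps``-wide window sliding one SNP at a time is
    homozygous-eligible if it holds at most ``max_het_per_window``
    heterozygous and ``max_missing_per_window`` missing calls. A SNP is
    in-ROH when the fraction of eligible windows covering it is at least
    ``hit_fraction``; maximal runs of in-ROH SNPs become segments if they
    span at least ``min_length_kb`` and contain at least ``min_snps`` SNPs.
    Chromosomes with fewer than ``window_snps`` SNPs yield no calls.
    """
    segments: list[RohSegment] = []
    chroms = panel.chromosomes
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        m = cols.size
        if m < window_snps:
            continue
        pos = panel.positions[cols]
        n_win = m - window_snps + 1
        starts = np.arange(m)
        win_lo = np.maximum(0, starts - window_snps + 1)
        win_hi = np.minimum(starts, n_win - 1)
        total = win_hi - win_lo + 1
        for ind_idx, ind in enumerate(panel.individuals):
            g = panel.genotypes[ind_idx, cols]
            het = (g == 1).astype(int)
            miss = (g == MISSING).astype(int)
            het_c = np.concatenate([[0], np.cumsum(het)])
            miss_c = np.concatenate([[0], np.cumsum(miss)])
            w = np.arange(n_win)
            eligible = (
                (het_c[w + window_snps] - het_c[w] <= max_het_per_window)
                & (miss_c[w + window_snps] - miss_c[w] <= max_missing_per_window)
            ).astype(int)
            elig_c = np.concatenate([[0], np.cumsum(eligible)])
            hits = elig_c[win_hi + 1] - elig_c[win_lo]
            in_roh = hits / total >= hit_fraction
            # maximal runs of in-ROH SNPs
            edges = np.diff(np.concatenate([[0], in_roh.astype(int), [0]]))
            for lo, hi in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
                span = int(pos[hi - 1] - pos[lo] + 1)
                n_in = hi - lo
                if span >= min_length_kb * 1000 and n_in >= min_snps:
                    segments.append(
                        RohSegment(
                            individual=ind.id,
                            chrom=str(chrom),
                            start_bp=int(pos[lo]),
                            end_bp=int(pos[hi - 1]),
                            n_snps=n_in,
                            n_het=int(het[lo:hi].sum()),
                            n_missing=int(miss[lo:hi].sum()),
                        )
                    )
    return segments


def accumulative_roh(
    segments: list[RohSegment], individuals: list[str] | None = None
) -> pd.Series:
    """Total ROH length (bp) per individual.

    ``individuals`` supplies the full index (individuals with no segment
    get 0); defaults to those appearing in ``segments``.
    """
    totals: dict[str, int] = {i: 0 for i in (individuals or [])}
    for seg in segments:
        totals[seg.individual] = totals.get(seg.individual, 0) + seg.length_bp
    return pd.Series(totals, dtype=float).sort_index()


def roh_table(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual": s.individual,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "length_bp": s.length_bp,
                "n_snps": s.n_snps,
                "n_het": s.n_het,
                "n_missing": s.n_missing,
            }
            for s in segments
        ]
    )
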
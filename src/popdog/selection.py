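"""Windowed d_i selection scan.

For breed i the per-SNP statistic is

    d_i = Σ_{j≠i} ( F_ST^{ij} − E[F_ST^{ij}] ) / sd[F_ST^{ij}]

where E and sd are each pair's genome-wide moments of the raw (untruncated)
per-SNP F_ST over all scan SNPs. Large d_i marks loci where breed i's allele
frequencies diverge from every other breed at once — the footprint of
breed-specific selection. The scan averages d_i in 200-kb non-overlapping
windows tiled from position 1 on each autosome, discards windows with fewer
than 6 SNPs, calls windows above the 99.5th percentile of the breed's own
empirical window distribution, and merges grid-adjacent called windows into
candidate selection regions.

A two-group contrast (focal group vs background, e.g. plateau vs non-plateau
breeds) treats the groups as two populations, for which d_i reduces to the
single-pair standardization (F_ST − E)/sd.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differentiation import AlleleFrequencyTable, allele_frequencies, per_snp_fst
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

WINDOW_BP = 200_000
MIN_SNPS_PER_WINDOW = 6
PERCENTILE = 99.5


@dataclass
class PairMoments:
    """Genome-wide mean and SD of raw per-SNP F_ST for each breed pair."""

    pairs: list[tuple[str, str]]
    e_fst: dict[tuple[str, str], float]
    sd_fst: dict[tuple[str, str], float]
    excluded: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class DiTrack:
    """Per-SNP d_i values for one breed; NaN where undefined."""

    breed: str
    snp_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class ScanWindow:
    chrom: str
    start_bp: int  # 1-based inclusive, fixed 200-kb grid
    end_bp: int
    n_snps: int
    mean_di: float


@dataclass(frozen=True)
class SelectionRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_windows: int
    peak_di: float


def pairwise_fst_tracks(
    panel: GenotypePanel, breeds: list[str] | None = None
) -> tuple[AlleleFrequencyTable, dict[tuple[str, str], np.ndarray]]:
    """Raw per-SNP F_ST track for every unordered breed pair."""
    table = allele_frequencies(panel, breeds)
    breeds = table.populations
    tracks: dict[tuple[str, str], np.ndarray] = {}
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            sub = AlleleFrequencyTable(
                populations=[breeds[i], breeds[j]],
                snp_ids=table.snp_ids,
                chroms=table.chroms,
                positions=table.positions,
                freqs=table.freqs[[i, j]],
                sizes=table.sizes[[i, j]],
            )
            tracks[(breeds[i], breeds[j])] = per_snp_fst(sub).fst_raw
    return table, tracks


def pair_moments(tracks: dict[tuple[str, str], np.ndarray]) -> PairMoments:
    """Mean and population SD (divisor N) of each pair's defined F_ST values.

    Pairs with zero SD (constant track) are excluded with a warning.
    """
    e, sd, pairs, excluded = {}, {}, [], []
    for pair, track in tracks.items():
        vals = track[~np.isnan(track)]
        if vals.size < 2:
            excluded.append(pair)
            continue
        mu, sigma = float(vals.mean()), float(vals.std(ddof=0))
        if sigma <= 1e-12 * max(1.0, abs(mu)):
            warnings.warn(f"pair {pair}: constant F_ST track, excluded", stacklevel=2)
            excluded.append(pair)
            continue
        pairs.append(pair)
        e[pair], sd[pair] = mu, sigma
    return PairMoments(pairs=pairs, e_fst=e, sd_fst=sd, excluded=excluded)


def _pair_key(i: str, j: str, moments: PairMoments) -> tuple[str, str] | None:
    if (i, j) in moments.e_fst:
        return (i, j)
    if (j, i) in moments.e_fst:
        return (j, i)
    return None


def di_per_snp(
    tracks: dict[tuple[str, str], np.ndarray],
    moments: PairMoments,
    breeds: list[str],
    table: AlleleFrequencyTable,
) -> dict[str, DiTrack]:
    """d_i track per breed; a SNP is NaN for breed i if any constituent
    pairwise F_ST is undefined there."""
    out: dict[str, DiTrack] = {}
    for breed in breeds:
        partners = [b for b in breeds if b != breed]
        if not partners:
            raise ValueError(f"breed {breed}: no partner breeds")
        terms = []
        for other in partners:
            key = _pair_key(breed, other, moments)
            if key is None:
                continue  # pair excluded (zero SD); skip its term
            terms.append((tracks[key] - moments.e_fst[key]) / moments.sd_fst[key])
        if not terms:
            raise ValueError(f"breed {breed}: no usable pair moments")
        stacked = np.vstack(terms)
        values = stacked.sum(axis=0)  # NaN propagates: any undefined pair -> NaN
        n_dropped = int(np.isnan(values).sum())
        if n_dropped:
            logger.info("breed %s: %d SNPs undefined in d_i track", breed, n_dropped)
        out[breed] = DiTrack(
            breed=breed,
            snp_ids=table.snp_ids,
            chroms=table.chroms,
            positions=table.positions,
            values=values,
        )
    return out


def window_scan(
    track: DiTrack,
    window_bp: int = WINDOW_BP,
    min_snps: int = MIN_SNPS_PER_WINDOW,
) -> list[ScanWindow]:
    """Mean d_i in non-overlapping windows on a fixed grid from position 1.

    Window k on a chromosome covers [k·w + 1, (k+1)·w]; windows with fewer
    than ``min_snps`` SNPs carrying a defined d_i are discarded.
    """
    ok = ~np.isnan(track.values)
    if not ok.any():
        raise ValueError("empty d_i track")
    windows: list[ScanWindow] = []
    for chrom in pd.unique(track.chroms):
        on = (track.chroms == chrom) & ok
        if not on.any():
            continue
        pos = track.positions[on]
        vals = track.values[on]
        win_idx = (pos - 1) // window_bp
        for k in np.unique(win_idx):
            sel = win_idx == k
            n = int(sel.sum())
            if n < min_snps:
                continue
            windows.append(
                ScanWindow(
                    chrom=str(chrom),
                    start_bp=int(k) * window_bp + 1,
                    end_bp=(int(k) + 1) * window_bp,
                    n_snps=n,
                    mean_di=float(vals[sel].mean()),
                )
            )
    return windows


def call_outliers(
    windows: list[ScanWindow], percentile: float = PERCENTILE
) -> tuple[list[ScanWindow], float]:
    """Windows at or above the empirical ``percentile`` of mean d_i.

    The threshold is the linear-interpolation quantile of the retained
    windows' means; ties at the threshold are included. Returns (called
    windows, threshold).
    """
    if not windows:
        raise ValueError("no windows to call")
    if len(windows) < 20:
        warnings.warn(
            f"only {len(windows)} windows; percentile threshold unstable",
            stacklevel=2,
        )
    means = np.array([w.mean_di for w in windows])
    threshold = float(np.quantile(means, percentile / 100.0))
    called = [w for w in windows if w.mean_di >= threshold]
    return called, threshold


def merge_regions(called: list[ScanWindow]) -> list[SelectionRegion]:
    """Merge grid-adjacent called windows on the same chromosome."""
    regions: list[SelectionRegion] = []
    by_chrom: dict[str, list[ScanWindow]] = {}
    for w in called:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in by_chrom:
        ws = sorted(by_chrom[chrom], key=lambda w: w.start_bp)
        run = [ws[0]]
        for w in ws[1:]:
            if w.start_bp == run[-1].end_bp + 1:
                run.append(w)
            else:
                regions.append(_region(chrom, run))
                run = [w]
        regions.append(_region(chrom, run))
    return sorted(regions, key=lambda r: (r.chrom, r.start_bp))


def _region(chrom: str, run: list[ScanWindow]) -> SelectionRegion:
    return SelectionRegion(
        chrom=chrom,
        start_bp=run[0].start_bp,
        end_bp=run[-1].end_bp,
        n_windows=len(run),
        peak_di=max(w.mean_di for w in run),
    )


@dataclass
class ScanResult:
    breed: str
    windows: list[ScanWindow]
    called: list[ScanWindow]
    regions: list[SelectionRegion]
    threshold: float

    def window_table(self) -> pd.DataFrame:
        called = {(w.chrom, w.start_bp) for w in self.called}
        return pd.DataFrame(
            [
                {
                    "chrom": w.chrom,
                    "start_bp": w.start_bp,
                    "end_bp": w.end_bp,
                    "n_snps": w.n_snps,
                    "mean_di": w.mean_di,
                    "called": (w.chrom, w.start_bp) in called,
                }
                for w in self.windows
            ]
        )

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.regions])


def breed_scan(
    panel: GenotypePanel,
    breeds: list[str] | None = None,
    window_bp: int = WINDOW_BP,
    min_snps: int = MIN_SNPS_PER_WINDOW,
    percentile: float = PERCENTILE,
) -> dict[str, ScanResult]:
    """Full per-breed d_i scan on an autosomal panel."""
    panel = panel.autosomal()
    table, tracks = pairwise_fst_tracks(panel, breeds)
    moments = pair_moments(tracks)
    di = di_per_snp(tracks, moments, table.populations, table)
    results = {}
    for breed, track in di.items():
        windows = window_scan(track, window_bp, min_snps)
        called, threshold = call_outliers(windows, percentile)
        results[breed] = ScanResult(
            breed=breed,
            windows=windows,
            called=called,
            regions=merge_regions(called),
            threshold=threshold,
        )
    return results


def group_contrast_scan(
    panel: GenotypePanel,
    group_assignment: dict[str, str] | None = None,
    window_bp: int = WINDOW_BP,
    min_snps: int = MIN_SNPS_PER_WINDOW,
    percentile: float = PERCENTILE,
    focal: list[str] | None = None,
    background: list[str] | None = None,
) -> ScanResult:
    """Focal-vs-background contrast scan.

    ``group_assignment`` maps population codes to "focal" or "background"
    (alternatively pass ``focal``/``background`` lists); the two groups are
    pooled into two super-populations and scanned with the single-pair
    standardization. Moments are re-estimated from the two-group F_ST track
    itself.
    """
    if group_assignment is None:
        if not focal or not background:
            raise ValueError("both groups must be non-empty")
        overlap = set(focal) & set(background)
        if overlap:
            raise ValueError(f"populations in both groups: {sorted(overlap)}")
        group_assignment = {p: "focal" for p in focal}
        group_assignment.update({p: "background" for p in background})
    groups = set(group_assignment.values())
    if groups != {"focal", "background"}:
        raise ValueError("assignment values must be 'focal' and 'background'")

    panel = panel.subset(populations=list(group_assignment)).autosomal()
    relabeled = GenotypePanel(
        [
            type(ind)(ind.id, group_assignment[ind.population], ind.sex)
            for ind in panel.individuals
        ],
        panel.snps,
        panel.genotypes,
    )
    results = breed_scan(
        relabeled,
        breeds=["focal", "background"],
        window_bp=window_bp,
        min_snps=min_snps,
        percentile=percentile,
    )
    return results["focal"]
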
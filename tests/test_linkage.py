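"""LD statistics, pruning, and ROH detection against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from popdog import (
    MISSING,
    SimConfig,
    accumulative_roh,
    decay_curve,
    detect_roh,
    filter_snps,
    ld_prune,
    pairwise_r2,
    r2_threshold_distance,
    simulate_panel,
)

from conftest import make_panel


class TestPairwiseR2:
    def test_duplicated_snp_r2_one(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        pairs = pairwise_r2(make_panel(g))
        assert len(pairs) == 1
        assert pairs.r2.iloc[0] == pytest.approx(1.0)

    def test_allele_recoding_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        r_orig = pairwise_r2(make_panel(g)).r2.iloc[0]
        g2 = g.copy()
        g2[:, 1] = 2 - g2[:, 1]  # swap which allele is counted at SNP 2
        r_flip = pairwise_r2(make_panel(g2)).r2.iloc[0]
        assert r_orig == pytest.approx(r_flip, abs=1e-12)

    def test_zero_variance_pair_skipped(self):
        g = np.array([[0, 0], [0, 1], [0, 2]], dtype=np.int8)
        assert pairwise_r2(make_panel(g)).empty

    def test_max_distance_respected(self):
        g = np.array([[0, 0, 0], [1, 2, 1], [2, 1, 2]], dtype=np.int8)
        panel = make_panel(g, positions=[1000, 200_000, 600_000])
        pairs = pairwise_r2(panel, max_dist_kb=500)
        assert (pairs.dist_bp <= 500_000).all()
        assert len(pairs) == 2  # (1,2) and (2,3); (1,3) is 599 kb apart

    def test_independent_snps_small_sample_bias(self):
        """E[r²] for unlinked SNPs is ~1/(n−1), the sampling floor."""
        rng = np.random.default_rng(8)
        n = 50
        p = rng.uniform(0.2, 0.8, size=150)
        g = rng.binomial(2, p, size=(n, 150)).astype(np.int8)
        panel = make_panel(g, positions=list(range(1, 151)))
        pairs = pairwise_r2(panel, max_dist_kb=500)
        assert pairs.r2.mean() == pytest.approx(1 / (n - 1), abs=0.005)


class TestDecayCurve:
    def test_single_bin_mean(self):
        pairs = pd.DataFrame(
            {"snp_i": list("aab"), "snp_j": list("bcc"),
             "dist_bp": [1000, 2000, 3000], "r2": [0.1, 0.2, 0.6]}
        )
        curve = decay_curve(pairs, bin_width_kb=10)
        assert len(curve) == 1
        assert curve.mean_r2.iloc[0] == pytest.approx(0.3)
        assert curve.n_pairs.iloc[0] == 3

    def test_two_bins_hand_computed(self):
        pairs = pd.DataFrame(
            {"snp_i": list("aabb"), "snp_j": list("bccd"),
             "dist_bp": [5_000, 8_000, 25_000, 12_000], "r2": [0.8, 0.6, 0.2, 0.4]}
        )
        curve = decay_curve(pairs, bin_width_kb=10)
        assert curve.mean_r2.iloc[0] == pytest.approx(0.7)   # 5 kb, 8 kb
        assert curve.mean_r2.iloc[1] == pytest.approx(0.4)   # 12 kb
        assert curve.mean_r2.iloc[2] == pytest.approx(0.2)   # 25 kb

    def test_empty_bin_has_nan_mean(self):
        pairs = pd.DataFrame(
            {"snp_i": ["a", "a"], "snp_j": ["b", "c"],
             "dist_bp": [1_000, 25_000], "r2": [0.5, 0.1]}
        )
        curve = decay_curve(pairs, bin_width_kb=10)
        assert np.isnan(curve.mean_r2.iloc[1])
        assert curve.n_pairs.iloc[1] == 0

    def test_bad_width(self):
        with pytest.raises(ValueError):
            decay_curve(pd.DataFrame({"dist_bp": [1], "r2": [0.1]}), 0)


class TestR2ThresholdDistance:
    @staticmethod
    def curve_from(mids_kb, means, counts=None):
        n = len(mids_kb)
        return pd.DataFrame(
            {"mid_kb": mids_kb, "mean_r2": means,
             "n_pairs": counts if counts is not None else [10] * n}
        )

    def test_never_above_threshold_returns_zero(self):
        curve = self.curve_from([5, 15, 25], [0.2, 0.2, 0.2])
        assert r2_threshold_distance(curve, 0.3) == 0.0

    def test_linear_interpolation(self):
        curve = self.curve_from([10, 20], [0.4, 0.2])
        assert r2_threshold_distance(curve, 0.3) == pytest.approx(15.0)

    def test_never_below_returns_max_with_warning(self):
        curve = self.curve_from([10, 20], [0.9, 0.8])
        with pytest.warns(UserWarning):
            assert r2_threshold_distance(curve, 0.3) == 20.0

    def test_nonmonotone_input_smoothed(self):
        curve = self.curve_from([10, 20, 30, 40], [0.5, 0.1, 0.45, 0.1])
        d = r2_threshold_distance(curve, 0.3)
        assert 10 < d < 40


def test_ld_extent_decreases_with_founders():
    """r²₀.₃ is larger for 2 founders than 100 (more LD, slower decay)."""
    extents = {}
    for nf in (2, 100):
        cfg = SimConfig(n_pops=1, n_per_pop=20, n_chrom=2,
                        chrom_length_bp=10_000_000, fst_param=0.0,
                        founders_per_pop=nf, seed=11)
        panel, _ = simulate_panel(cfg)
        panel, _ = filter_snps(panel, maf_min=0.05, call_rate_min=0.9)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curve = decay_curve(pairwise_r2(panel), bin_width_kb=10)
            extents[nf] = r2_threshold_distance(curve, 0.3)
    assert extents[2] > extents[100]


class TestLdPrune:
    def test_duplicated_pair_keeps_one(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        kept = ld_prune(make_panel(g), r2_max=0.5, window_snps=10, step_snps=5)
        assert len(kept) == 1

    def test_independent_snps_identity(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        panel = make_panel(g)
        pairs = pairwise_r2(panel)
        assume_ok = pairs.r2.max() < 0.5
        kept = ld_prune(panel, r2_max=0.5, window_snps=10, step_snps=5)
        if assume_ok:
            assert kept == panel.snp_ids

    def test_matches_greedy_oracle_on_fixture(self):
        """5-SNP panel vs an independent scalar re-run of the greedy rule."""
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=(40, 1))
        g = np.column_stack(
            [base[:, 0],
             base[:, 0],                                   # duplicate of snp1
             np.where(rng.random(40) < 0.3, 2 - base[:, 0], base[:, 0]),
             rng.integers(0, 3, size=40),
             rng.integers(0, 3, size=40)]
        ).astype(np.int8)
        panel = make_panel(g)
        maf = np.minimum(panel.minor_allele_frequency(),
                         1 - panel.minor_allele_frequency())
        alive = [True] * 5
        for a in range(5):
            for b in range(a + 1, 5):
                if not (alive[a] and alive[b]):
                    continue
                r = np.corrcoef(g[:, a].astype(float), g[:, b].astype(float))[0, 1]
                if r * r >= 0.5 - 1e-12:
                    if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                        alive[a] = False
                    else:
                        alive[b] = False
        expected = [s for s, al in zip(panel.snp_ids, alive) if al]
        kept = ld_prune(panel, r2_max=0.5, window_snps=5, step_snps=5)
        assert kept == expected

    def test_bad_window(self):
        with pytest.raises(ValueError):
            ld_prune(make_panel([[0, 1], [1, 0]]), window_snps=1)


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------

def roh_oracle(genotypes, positions, window, max_het, max_miss,
               min_length_bp, min_snps, hit_fraction):
    """Exhaustive scalar re-implementation of the window vote, one sample."""
    m = len(genotypes)
    if m < window:
        return []
    eligible = []
    for s in range(m - window + 1):
        win = genotypes[s : s + window]
        eligible.append(
            sum(1 for x in win if x == 1) <= max_het
            and sum(1 for x in win if x == MISSING) <= max_miss
        )
    in_roh = []
    for snp in range(m):
        covering = [
            s for s in range(len(eligible)) if s <= snp <= s + window - 1
        ]
        frac = sum(eligible[s] for s in covering) / len(covering)
        in_roh.append(frac >= hit_fraction)
    segments, start = [], None
    for snp in range(m + 1):
        flag = in_roh[snp] if snp < m else False
        if flag and start is None:
            start = snp
        elif not flag and start is not None:
            span = positions[snp - 1] - positions[start] + 1
            if span >= min_length_bp and snp - start >= min_snps:
                segments.append((positions[start], positions[snp - 1]))
            start = None
    return segments


class TestDetectRoh:
    def test_all_het_no_segments(self):
        g = np.ones((1, 80), dtype=np.int8)
        panel = make_panel(g, positions=list(range(10_000, 810_000, 10_000)))
        assert detect_roh(panel) == []

    def test_pure_homozygous_tract(self):
        # 60 homozygous SNPs spanning ~1 Mb -> one segment, first to last SNP
        pos = list(range(10_000, 10_000 + 60 * 17_000, 17_000))
        g = np.zeros((1, 60), dtype=np.int8)
        segs = detect_roh(make_panel(g, positions=pos))
        assert len(segs) == 1
        assert segs[0].start_bp == pos[0]
        assert segs[0].end_bp == pos[-1]
        assert segs[0].n_snps == 60

    def test_short_chromosome_skipped(self):
        g = np.zeros((1, 30), dtype=np.int8)
        panel = make_panel(g, positions=list(range(10_000, 310_000, 10_000)))
        assert detect_roh(panel, window_snps=50) == []

    @pytest.mark.parametrize("het_gap, hit_fraction", [
        (10, 0.5), (10, 0.05), (60, 0.5), (60, 0.05),
    ])
    def test_het_interruptions_match_oracle(self, het_gap, hit_fraction):
        """Two het calls in a homozygous tract, close vs far apart."""
        m = 150
        pos = list(range(5_000, 5_000 + m * 10_000, 10_000))
        g = np.zeros(m, dtype=np.int8)
        g[60] = 1
        g[60 + het_gap] = 1
        panel = make_panel(g.reshape(1, -1), positions=pos)
        segs = detect_roh(panel, hit_fraction=hit_fraction, min_snps=10)
        expected = roh_oracle(list(g), pos, 50, 1, 5, 200_000, 10, hit_fraction)
        assert [(s.start_bp, s.end_bp) for s in segs] == expected

    def test_two_far_hets_leave_single_segment(self):
        """Hets farther apart than a window never co-occur: no window is
        ineligible, the tract stays whole."""
        m = 150
        pos = list(range(5_000, 5_000 + m * 10_000, 10_000))
        g = np.zeros(m, dtype=np.int8)
        g[40], g[100] = 1, 1  # 60 > 50 apart
        segs = detect_roh(make_panel(g.reshape(1, -1), positions=pos),
                          hit_fraction=0.5, min_snps=10)
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp) == (pos[0], pos[-1])

    def test_emitted_segments_respect_thresholds(self, two_pop_panel):
        panel, _ = two_pop_panel
        segs = detect_roh(panel, min_length_kb=200, min_snps=25)
        for s in segs:
            assert s.length_bp >= 200_000
            assert s.n_snps >= 25

    def test_min_length_monotonicity(self, two_pop_panel):
        panel, _ = two_pop_panel
        strict = detect_roh(panel, min_length_kb=400)
        loose = detect_roh(panel, min_length_kb=100)
        loose_keys = {(s.individual, s.chrom, s.start_bp) for s in loose}
        for s in strict:
            assert (s.individual, s.chrom, s.start_bp) in loose_keys


class TestAccumulativeRoh:
    def test_no_segments_zero(self):
        acc = accumulative_roh([], individuals=["a"])
        assert acc["a"] == 0

    def test_disjoint_segments_sum(self):
        from popdog import RohSegment

        segs = [
            RohSegment("a", "1", 1, 300_000, 30, 0, 0),
            RohSegment("a", "2", 1, 300_000, 30, 0, 0),
        ]
        assert accumulative_roh(segs)["a"] == 600_000

    def test_founder_count_monotonicity(self):
        medians = {}
        for nf in (2, 100):
            cfg = SimConfig(n_pops=1, n_per_pop=15, n_chrom=2,
                            chrom_length_bp=20_000_000, fst_param=0.0,
                            founders_per_pop=nf, recomb_rate=5e-8, seed=11)
            panel, _ = simulate_panel(cfg)
            acc = accumulative_roh(detect_roh(panel), panel.individual_ids)
            medians[nf] = acc.median()
        assert medians[2] > medians[100]
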
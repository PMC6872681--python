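"""Mean-square F_ST estimator and ABBA-BABA D against brute-force oracles."""

import numpy as np
import pytest

from popdog import (
    MISSING,
    AdmixEvent,
    SimConfig,
    allele_frequencies,
    d_statistic,
    mean_fst,
    pairwise_fst_matrix,
    per_snp_fst,
    simulate_panel,
)
from popdog.differentiation import AlleleFrequencyTable

from conftest import make_panel


def freq_table(freqs, sizes):
    """Direct frequency-table construction for estimator tests."""
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    sizes = np.atleast_2d(np.asarray(sizes, dtype=float))
    s, m = freqs.shape
    return AlleleFrequencyTable(
        populations=[f"p{k}" for k in range(s)],
        snp_ids=[f"snp{j}" for j in range(m)],
        chroms=np.array(["1"] * m, dtype=object),
        positions=np.arange(1, m + 1) * 1000,
        freqs=freqs,
        sizes=sizes,
    )


def fst_oracle(p, n, msg_denominator="n-1"):
    """Scalar re-derivation of the mean-square F_ST for one SNP."""
    p, n = np.asarray(p, float), np.asarray(n, float)
    keep = n >= 2
    p, n = p[keep], n[keep]
    s = len(p)
    p_bar = np.sum(n * p) / np.sum(n)
    denom = np.sum(n - 1) if msg_denominator == "n-1" else np.sum(n)
    msg = np.sum(n * p * (1 - p)) / denom
    msp = np.sum(n * (p - p_bar) ** 2) / (s - 1)
    n_c = (np.sum(n) - np.sum(n**2) / np.sum(n)) / (s - 1)
    bottom = msp + (n_c - 1) * msg
    if bottom == 0:
        return np.nan
    return (msp - msg) / bottom


class TestAlleleFrequencies:
    def test_direct_count(self):
        panel = make_panel(np.array([[0], [0], [1], [1], [2]], dtype=np.int8))
        table = allele_frequencies(panel)
        assert table.freqs[0, 0] == pytest.approx(0.4)
        assert table.sizes[0, 0] == 10

    def test_all_missing_zero_size(self):
        g = np.full((3, 1), MISSING, dtype=np.int8)
        g = np.hstack([g, np.ones((3, 1), dtype=np.int8)])
        table = allele_frequencies(make_panel(g))
        assert table.sizes[0, 0] == 0
        assert np.isnan(table.freqs[0, 0])

    def test_no_missing_full_size(self, two_pop_panel):
        panel, _ = two_pop_panel
        complete = panel.genotypes != MISSING
        table = allele_frequencies(panel)
        for k, pop in enumerate(table.populations):
            rows = panel.population_mask(pop)
            np.testing.assert_array_equal(
                table.sizes[k], 2 * complete[rows].sum(axis=0)
            )


class TestPerSnpFst:
    def test_equal_frequencies_negative_limit(self):
        # p1 = p2 = 0.5, 10 individuals each (20 copies): raw = -1/(n_c - 1)
        comp = per_snp_fst(freq_table([[0.5], [0.5]], [[20], [20]]))
        assert comp.n_c[0] == pytest.approx(20.0)
        assert comp.fst_raw[0] == pytest.approx(-1 / 19)
        assert comp.fst_reported[0] == 0.0

    def test_fixed_difference_is_one(self):
        comp = per_snp_fst(freq_table([[1.0], [0.0]], [[20], [20]]))
        assert comp.msg[0] == 0.0
        assert comp.fst_raw[0] == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        comp = per_snp_fst(freq_table([[0.0], [0.0]], [[20], [20]]))
        assert np.isnan(comp.fst_raw[0])
        assert not comp.defined[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            s = rng.integers(2, 6)
            p = rng.uniform(0, 1, size=s)
            n = rng.integers(4, 80, size=s).astype(float)
            comp = per_snp_fst(freq_table(p[:, None], n[:, None]))
            expected = fst_oracle(p, n)
            if np.isnan(expected):
                assert np.isnan(comp.fst_raw[0])
            else:
                assert comp.fst_raw[0] == pytest.approx(expected, abs=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, size=(3, 20))
        n = np.full((3, 20), 30.0)
        a = per_snp_fst(freq_table(p, n))
        b = per_snp_fst(freq_table(1 - p, n))
        np.testing.assert_allclose(a.fst_raw, b.fst_raw, atol=1e-12)
        np.testing.assert_allclose(a.msg, b.msg, atol=1e-12)
        np.testing.assert_allclose(a.msp, b.msp, atol=1e-12)

    def test_raw_one_iff_msg_zero_msp_positive(self):
        rng = np.random.default_rng(6)
        p = rng.choice([0.0, 1.0, 0.3], size=(2, 50))
        comp = per_snp_fst(freq_table(p, np.full((2, 50), 40.0)))
        for j in range(50):
            if not comp.defined[j]:
                continue
            is_one = comp.fst_raw[j] == pytest.approx(1.0, abs=1e-12)
            assert is_one == (comp.msg[j] == 0 and comp.msp[j] > 0)

    def test_msg_denominator_switch(self):
        p, n = [[0.8], [0.2]], [[20], [20]]
        a = per_snp_fst(freq_table(p, n), msg_denominator="n-1").fst_raw[0]
        b = per_snp_fst(freq_table(p, n), msg_denominator="n").fst_raw[0]
        assert a != b
        assert b == pytest.approx(fst_oracle([0.8, 0.2], [20, 20], "n"), abs=1e-12)


class TestPairwiseMatrix:
    def test_symmetric_zero_diagonal(self, multi_pop_panel):
        panel, _ = multi_pop_panel
        m = pairwise_fst_matrix(panel)
        assert m.shape == (5, 5)
        np.testing.assert_array_equal(m.values, m.values.T)
        assert np.diag(m.values).sum() == 0

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 300)
        g = rng.binomial(2, p, size=(40, 300)).astype(np.int8)
        panel = make_panel(g, populations=["a"] * 20 + ["b"] * 20,
                           positions=list(range(1000, 301_000, 1000)))
        assert pairwise_fst_matrix(panel).loc["a", "b"] < 0.02

    def test_permutation_equivariant(self, multi_pop_panel):
        panel, _ = multi_pop_panel
        m = pairwise_fst_matrix(panel)
        pops = panel.populations
        reordered = panel.subset(populations=pops)  # same panel
        order = pops[::-1]
        sub = panel.genotypes  # reorder individuals by population
        idx = [i for p in order for i in np.flatnonzero(panel.population_mask(p))]
        panel2 = make_panel(
            panel.genotypes[idx],
            populations=[panel.individuals[i].population for i in idx],
            chroms=panel.chromosomes,
            positions=panel.positions,
        )
        m2 = pairwise_fst_matrix(panel2)
        for a in pops:
            for b in pops:
                assert m.loc[a, b] == pytest.approx(m2.loc[a, b], abs=1e-12)

    def test_recovers_simulated_divergence(self, two_pop_panel):
        panel, _ = two_pop_panel
        comp_mean = pairwise_fst_matrix(panel).iloc[0, 1]
        # brute-force oracle over per-SNP values on the same data
        table = allele_frequencies(panel)
        oracle_vals = [
            fst_oracle(table.freqs[:, j], table.sizes[:, j])
            for j in range(panel.n_snps)
        ]
        oracle_vals = np.array(oracle_vals)
        oracle_mean = np.nanmean(np.maximum(oracle_vals, 0))
        assert comp_mean == pytest.approx(oracle_mean, abs=1e-12)
        assert abs(comp_mean - 0.1) < 0.03


class TestDStatistic:
    def test_equal_p1_p2_gives_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=(4, 600))
        p[1] = p[0]
        table = freq_table(p, np.full((4, 600), 40.0))
        res = d_statistic(table)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_pure_abba_site(self):
        table = freq_table([[0.0], [1.0], [1.0], [0.0]], [[20]] * 4)
        assert d_statistic(table).d == pytest.approx(1.0)

    def test_sign_flips_with_p1_p2_swap(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, size=(4, 900))
        table = freq_table(p, np.full((4, 900), 40.0))
        d12 = d_statistic(table, quartet=("p0", "p1", "p2", "p3"))
        d21 = d_statistic(table, quartet=("p1", "p0", "p2", "p3"))
        assert d12.d == pytest.approx(-d21.d, abs=1e-12)

    def test_zero_denominator_errors(self):
        table = freq_table([[0.0], [0.0], [0.0], [0.0]], [[20]] * 4)
        with pytest.raises(ValueError, match="undefined"):
            d_statistic(table)

    def test_jackknife_blocks_counted(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, size=(4, 1000))
        res = d_statistic(freq_table(p, np.full((4, 1000), 40.0)), block_snps=300)
        assert res.n_blocks == 3
        assert np.isfinite(res.z)

    def test_planted_admixture_detected(self):
        cfg = SimConfig(
            n_pops=4, n_per_pop=20, n_chrom=2, chrom_length_bp=60_000_000,
            fst_param=[0.1, 0.1, 0.1, 0.3], founders_per_pop=60,
            pop_names=["p1", "p2", "p3", "out"],
            admix_events=[AdmixEvent("p3", "p2", 0.25)], seed=5,
        )
        panel, _ = simulate_panel(cfg)
        table = allele_frequencies(panel, ["p1", "p2", "p3", "out"])
        res = d_statistic(table)
        assert res.d > 0
        assert res.z > 3
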
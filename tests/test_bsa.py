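"""G statistic, tricube smoothing, replicate merging, SNP filters, the
log-normal null with Hampel filtering, and QTL interval calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import mitemap as mm
from mitemap.io import SNP_COLUMNS


def make_table(chrom, pos, ad_res, ad_sens, gq=99):
    """Minimal SNP table; ad_* are (ref, alt) pairs per site."""
    ad_res = np.atleast_2d(ad_res)
    ad_sens = np.atleast_2d(ad_sens)
    n = len(pos)
    return pd.DataFrame({
        "CHROM": chrom if not np.isscalar(chrom) else [chrom] * n,
        "POS": pos,
        "REF": ["A"] * n, "ALT": ["T"] * n,
        "AD_REF_RES": ad_res[:, 0], "AD_ALT_RES": ad_res[:, 1],
        "DP_RES": ad_res.sum(axis=1), "GQ_RES": gq,
        "AD_REF_SENS": ad_sens[:, 0], "AD_ALT_SENS": ad_sens[:, 1],
        "DP_SENS": ad_sens.sum(axis=1), "GQ_SENS": gq,
    })[SNP_COLUMNS]


class TestGStatistic:
    def test_equal_frequencies_give_zero(self):
        assert mm.g_statistic(np.array([[5, 5], [5, 5]])) == 0.0

    def test_proportional_table_exactly_zero(self):
        # marginal products reproduce the cells exactly in float arithmetic
        for table in ([[2, 4], [3, 6]], [[10, 5], [4, 2]], [[1, 1], [7, 7]]):
            assert mm.g_statistic(np.array(table)) == 0.0

    def test_hand_computed_example(self):
        assert mm.g_statistic(np.array([[10, 2], [3, 9]])) == pytest.approx(8.794692, abs=1e-6)

    def test_matches_independent_log_likelihood_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(1, 40, size=(2, 2))
            oracle = chi2_contingency(t, correction=False, lambda_="log-likelihood").statistic
            assert mm.g_statistic(t) == pytest.approx(oracle, abs=1e-9)

    def test_swap_invariance_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        t = rng.integers(0, 30, size=(500, 2, 2)) + 1
        g = mm.g_statistic(t)
        swapped = t[:, ::-1, ::-1]  # swap pools together with alleles
        assert np.allclose(g, mm.g_statistic(swapped))
        assert np.all(g >= 0)

    def test_zero_margin_is_degenerate(self):
        assert np.isnan(mm.g_statistic(np.array([[7, 0], [7, 0]])))


class TestSmoothing:
    def test_constant_signal_unchanged(self):
        pos = np.sort(np.random.default_rng(0).integers(1, 10**7, 50))
        out = mm.smooth_gprime(pos, np.full(50, 3.7), 10_000_000)
        assert np.allclose(out, 3.7)

    def test_single_site_passthrough(self):
        assert mm.smooth_gprime(np.array([100]), np.array([4.2]), 10**7)[0] == 4.2

    def test_three_site_tricube_oracle(self):
        # explicit weight calculation: neighbors at 1 Mb with D = 5 Mb
        w = (1 - (1_000_000 / 5_000_000) ** 3) ** 3
        expected_mid = 10.0 / (1.0 + 2.0 * w)
        out = mm.smooth_gprime(np.array([0, 1_000_000, 2_000_000]),
                               np.array([0.0, 10.0, 0.0]), 10_000_000)
        assert out[1] == pytest.approx(expected_mid, abs=1e-9)
        assert expected_mid == pytest.approx(3.3871, abs=1e-4)

    def test_linear_and_shift_invariant(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.integers(1, 5 * 10**7, 200))
        g = rng.gamma(2.0, 1.0, 200)
        a, b = 2.5, 1.3
        lhs = mm.smooth_gprime(pos, a * g + b, 10**7)
        rhs = a * mm.smooth_gprime(pos, g, 10**7) + b
        assert np.allclose(lhs, rhs)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            mm.smooth_gprime(np.array([5, 1]), np.array([1.0, 2.0]), 10**6)


class TestMergeReplicates:
    def test_self_merge_doubles_depths(self):
        t = make_table("chr1", [10, 20], [[3, 5], [2, 6]], [[4, 4], [1, 7]])
        merged = mm.merge_replicates([t, t.copy()])
        assert (merged["DP_RES"] == 2 * t["DP_RES"]).all()
        assert (merged["AD_ALT_SENS"] == 2 * t["AD_ALT_SENS"]).all()

    def test_merge_with_empty_is_identity(self):
        t = make_table("chr1", [10, 20], [[3, 5], [2, 6]], [[4, 4], [1, 7]])
        merged = mm.merge_replicates([t, t.iloc[0:0]])
        assert merged[SNP_COLUMNS].equals(t[SNP_COLUMNS])

    def test_disjoint_sites_union(self):
        a = make_table("chr1", [10], [[3, 5]], [[4, 4]])
        b = make_table("chr1", [20], [[2, 6]], [[1, 7]])
        merged = mm.merge_replicates([a, b])
        assert list(merged["POS"]) == [10, 20]

    def test_conflicting_alleles_dropped(self):
        a = make_table("chr1", [10, 20], [[3, 5], [2, 6]], [[4, 4], [1, 7]])
        b = make_table("chr1", [10, 20], [[3, 5], [2, 6]], [[4, 4], [1, 7]])
        b.loc[0, "ALT"] = "G"
        merged = mm.merge_replicates([a, b])
        assert list(merged["POS"]) == [20]
        assert merged.attrs["n_conflicts"] == 1


class TestFilterSnps:
    def test_depth_and_frequency_rules(self):
        p = mm.ScanParams()
        # total depth 5 < 6 removed; balanced 24x retained; ref freq 0.1 removed
        t = make_table("chr1", [10, 20, 30],
                       [[1, 2], [6, 6], [1, 11]],
                       [[1, 1], [6, 6], [1, 11]])
        kept = mm.filter_snps(t, p)
        assert list(kept["POS"]) == [20]

    def test_gq_and_depth_difference(self):
        p = mm.ScanParams()
        t = make_table("chr1", [10], [[6, 6]], [[6, 6]], gq=19)
        assert len(mm.filter_snps(t, p)) == 0
        t2 = make_table("chr1", [10], [[10, 10]], [[2, 2]])
        assert len(mm.filter_snps(t2, p)) == 0  # depth difference 16 > 8

    def test_doubled_params(self):
        d = mm.ScanParams().doubled()
        assert (d.min_total_depth, d.max_total_depth) == (12, 72)
        assert (d.max_depth_difference, d.min_sample_depth) == (16, 6)
        assert d.ref_freq_cutoff == 0.2  # non-depth settings unchanged


def _bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestNullFit:
    def test_identical_values_degenerate_no_rejections(self):
        p, q = mm.null_fit_pvalues(np.full(200, 2.0))
        assert np.all(p == 0.5)
        assert not np.any(q < 0.01)

    def test_iid_lognormal_null_controls_fdr(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0.0, 0.4, 10_000)
        p, q = mm.null_fit_pvalues(x, hampel_g=5.2)
        frac = (q < 0.01).mean()
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / 10_000)

    def test_implanted_block_detected_and_rest_uniformish(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(0.0, 0.3, 4000)
        x[1000:1200] *= 6.0  # 5% high-G' block
        p, q = mm.null_fit_pvalues(x)
        assert (q[1000:1200] < 0.01).mean() > 0.9
        background = np.concatenate([p[:1000], p[1200:]])
        assert abs((background < 0.5).mean() - 0.5) < 0.1

    def test_bh_qvalues_match_brute_force_step_up(self):
        rng = np.random.default_rng(5)
        for n in (1, 10, 1000):
            x = rng.lognormal(0.0, 0.5, max(n, 1))
            p, q = mm.null_fit_pvalues(x)
            assert np.allclose(q, _bh_oracle(p))
        # monotone in p
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallQtl:
    def _track(self, chrom, pos, q, gprime=None):
        return pd.DataFrame({
            "CHROM": chrom, "POS": pos, "G": 1.0,
            "Gprime": gprime if gprime is not None else 1.0,
            "p": q, "q": q,
        })

    def test_no_significant_sites_empty(self):
        track = self._track("chr1", [1, 2, 3], [0.5, 0.9, 0.2])
        assert len(mm.call_qtl(track)) == 0

    def test_single_block_peak_is_leftmost_argmax(self):
        track = self._track("chr1", [10, 20, 30, 40],
                            [0.001, 0.002, 0.001, 0.5],
                            gprime=[5.0, 9.0, 9.0, 1.0])
        iv = mm.call_qtl(track)
        assert len(iv) == 1
        row = iv.iloc[0]
        assert (row["start"], row["end"], row["peak_pos"]) == (10, 30, 20)

    def test_runs_closer_than_window_are_joined(self):
        pos = [1_000_000, 2_000_000, 9_000_000, 10_000_000, 25_000_000, 40_000_000]
        q = [0.001, 0.001, 0.5, 0.001, 0.5, 0.001]
        iv = mm.call_qtl(self._track("chr1", pos, q), 0.01, 10_000_000)
        # 2 Mb -> 10 Mb gap (8 Mb) is joined; 10 Mb -> 40 Mb gap (30 Mb) is not
        assert len(iv) == 2
        assert (iv.iloc[0]["start"], iv.iloc[0]["end"]) == (1_000_000, 10_000_000)
        assert iv.iloc[1]["start"] == 40_000_000


class TestScanEndToEnd:
    def test_scan_track_columns_and_determinism(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 500, divergence=1.0, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), 50, one_chrom_genome, seed=1)
        pop.damage = np.random.default_rng(2).normal(5, 1, 50)
        pop.progeny = np.zeros(50, dtype=np.int64)
        pop.excluded = np.zeros(50, dtype=bool)
        bulks = mm.make_bulks(pop, 20, seed=3)
        table = mm.simulate_pool_seq(pop, bulks, mm.PoolSeqParams(pool_size=20, mean_depth=8.0, seed=4))
        t1 = mm.scan(table, mm.ScanParams())
        t2 = mm.scan(table, mm.ScanParams())
        assert t1.equals(t2)
        assert list(t1.columns) == ["CHROM", "POS", "G", "Gprime", "p", "q"]
        assert (t1["Gprime"] >= 0).all()
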
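"""Generator invariants: seeded determinism, Mendelian segregation,
IBD implanting, phenotype calibration, bulk construction, pool sequencing."""

import numpy as np
import pytest

import mitemap as mm


def _spec(chrom, pos, h=0.70, mode="recessive", **kw):
    return mm.QtlSpec(loci=(mm.QtlLocus(chrom, pos, "B49", mode, h),), **kw)


class TestSimulateParents:
    def test_seeded_regeneration_is_bit_identical(self, small_genome):
        a = mm.simulate_parents(small_genome, 100, divergence=0.3, seed=5)
        b = mm.simulate_parents(small_genome, 100, divergence=0.3, seed=5)
        for chrom in small_genome.names:
            assert np.array_equal(a.positions[chrom], b.positions[chrom])
            for line in a.line_ids:
                assert np.array_equal(a.genotypes[line][chrom], b.genotypes[line][chrom])
                assert np.array_equal(a.depth[line][chrom], b.depth[line][chrom])
            assert a.site_annotations[chrom].equals(b.site_annotations[chrom])

    def test_zero_leak_whole_chromosome_segment_makes_members_identical(self, small_genome):
        seg = mm.IbdSegment("chr1", 1, 50_000_000, frozenset({"B49", "B75"}))
        panel = mm.simulate_parents(
            small_genome, 200, ibd=mm.IbdSpec((seg,), 0.0), divergence=0.5, seed=1
        )
        assert np.array_equal(panel.genotypes["B49"]["chr1"], panel.genotypes["B75"]["chr1"])
        # the non-member line is not dragged along
        assert not np.array_equal(panel.genotypes["B96"]["chr1"], panel.genotypes["B49"]["chr1"])

    def test_zero_divergence_makes_all_lines_identical(self, small_genome):
        panel = mm.simulate_parents(small_genome, 100, divergence=0.0, seed=2)
        for chrom in small_genome.names:
            for line in panel.line_ids:
                assert not panel.genotypes[line][chrom].any()

    def test_pairwise_divergence_matches_rate(self, small_genome):
        panel = mm.simulate_parents(small_genome, 2000, divergence=0.2, seed=3)
        diff = (panel.genotypes["B49"]["chr1"] != panel.genotypes["B73"]["chr1"]).mean()
        assert abs(diff - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 2000)

    def test_overlapping_segments_with_inconsistent_members_rejected(self):
        segs = (
            mm.IbdSegment("chr1", 1, 10_000_000, frozenset({"B49", "B75"})),
            mm.IbdSegment("chr1", 5_000_000, 15_000_000, frozenset({"B49", "B96"})),
        )
        with pytest.raises(ValueError, match="inconsistent member sets"):
            mm.IbdSpec(segs, 0.0)

    def test_leak_rate_bounds(self):
        with pytest.raises(ValueError):
            mm.IbdSpec((), 0.02)


class TestSimulateF2:
    def test_rejects_empty_population(self, small_genome):
        panel = mm.simulate_parents(small_genome, 60, seed=0)
        with pytest.raises(ValueError):
            mm.simulate_f2(panel, ("B49", "B73"), 0, small_genome)

    def test_map_length_zero_gives_whole_chromosome_classes(self):
        model = mm.GenomeModel(chromosomes=(("chr1", 10_000_000),), genetic_map={"chr1": 0.0})
        panel = mm.simulate_parents(model, 60, divergence=1.0, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), 300, model, seed=1)
        g = pop.genotypes["chr1"]
        # no recombination: each individual is constant 0, 1, or 2 across sites
        assert (g == g[:, :1]).all()
        counts = np.bincount(g[:, 0], minlength=3) / 300
        sd = np.sqrt(np.array([0.25 * 0.75, 0.5 * 0.5, 0.25 * 0.75]) / 300)
        assert np.all(np.abs(counts - [0.25, 0.5, 0.25]) < 3 * sd)

    def test_single_site_genotypes_near_1_2_1(self, one_chrom_genome):
        # binomial sampling oracle: 3-SD band around (0.25, 0.5, 0.25)
        panel = mm.simulate_parents(one_chrom_genome, 60, divergence=1.0, seed=0)
        n = 10_000
        pop = mm.simulate_f2(panel, ("B49", "B73"), n, one_chrom_genome, seed=4)
        g = pop.genotypes["chr1"][:, 30]
        freq = np.bincount(g, minlength=3) / n
        sd = np.sqrt(np.array([0.25 * 0.75, 0.5 * 0.5, 0.25 * 0.75]) / n)
        assert np.all(np.abs(freq - [0.25, 0.5, 0.25]) < 3 * sd)
        # Mendelian check: allele frequency within 3 SD of 0.5 at every site
        af = pop.genotypes["chr1"].mean(axis=0) / 2
        assert np.all(np.abs(af - 0.5) < 3 * np.sqrt(0.25 / (2 * n)))

    def test_seeded_determinism(self, small_genome):
        panel = mm.simulate_parents(small_genome, 60, seed=0)
        a = mm.simulate_f2(panel, ("B49", "B73"), 20, small_genome, seed=9)
        b = mm.simulate_f2(panel, ("B49", "B73"), 20, small_genome, seed=9)
        for chrom in small_genome.names:
            assert np.array_equal(a.genotypes[chrom], b.genotypes[chrom])

    def test_genotype_at_matches_site_genotypes(self, small_genome):
        panel = mm.simulate_parents(small_genome, 60, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), 30, small_genome, seed=2)
        pos = panel.positions["chr1"][10]
        assert np.array_equal(pop.genotype_at("chr1", pos), pop.genotypes["chr1"][:, 10])


class TestSimulatePhenotypes:
    def test_noise_free_recessive_is_deterministic(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 60, divergence=1.0, seed=0)
        pos = int(panel.positions["chr1"][25])
        pop = mm.simulate_f2(panel, ("B49", "B73"), 200, one_chrom_genome, seed=1)
        mm.simulate_phenotypes(pop, _spec("chr1", pos, noise_sd=0.0), seed=2)
        g = pop.genotypes["chr1"][:, 25]
        # heterozygote effect equals susceptible homozygote effect, exactly
        assert np.all(pop.damage[g == 1] == pop.damage[g == 0][0])
        assert np.all(pop.damage[g == 2] < pop.damage[g == 0][0])
        res = mm.marker_effect_analysis(np.array(["SS", "Het", "RR"])[g], pop.damage)
        assert res.r2_homozygous == pytest.approx(1.0)

    def test_variance_explained_target_recovered(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 60, divergence=1.0, seed=0)
        pos = int(panel.positions["chr1"][25])
        r2 = []
        for s in range(60):
            pop = mm.simulate_f2(panel, ("B49", "B73"), 200, one_chrom_genome, seed=100 + s)
            mm.simulate_phenotypes(pop, _spec("chr1", pos, h=0.70), seed=200 + s)
            g = pop.genotypes["chr1"][:, 25]
            res = mm.marker_effect_analysis(np.array(["SS", "Het", "RR"])[g], pop.damage)
            r2.append(res.r2_homozygous)
        assert abs(np.mean(r2) - 0.70) < 0.03

    def test_damage_clamped_to_scale(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 60, divergence=1.0, seed=0)
        pos = int(panel.positions["chr1"][0])
        pop = mm.simulate_f2(panel, ("B49", "B73"), 500, one_chrom_genome, seed=1)
        mm.simulate_phenotypes(pop, _spec("chr1", pos, noise_sd=2.0), seed=2)
        assert pop.damage.min() >= 1.0 and pop.damage.max() <= 7.0

    def test_variance_explained_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            mm.QtlLocus("chr1", 100, "B49", "recessive", 1.0)

    def test_qtl_position_must_be_a_site(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 60, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), 10, one_chrom_genome, seed=1)
        with pytest.raises(ValueError, match="not a simulated site"):
            mm.simulate_phenotypes(pop, _spec("chr1", 12345), seed=2)

    def test_progeny_link_hits_target_r2(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 60, divergence=1.0, seed=0)
        pos = int(panel.positions["chr1"][25])
        r2 = []
        for s in range(40):
            pop = mm.simulate_f2(panel, ("B49", "B73"), 100, one_chrom_genome, seed=300 + s)
            mm.simulate_phenotypes(pop, _spec("chr1", pos), seed=400 + s)
            r2.append(mm.damage_productivity_fit(pop.damage, pop.progeny)[0])
        assert abs(np.mean(r2) - 0.83) < 0.05


class TestMakeBulks:
    def _pop_with_scores(self, one_chrom_genome, scores):
        panel = mm.simulate_parents(one_chrom_genome, 60, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), len(scores), one_chrom_genome, seed=1)
        pop.damage = np.asarray(scores, dtype=float)
        pop.progeny = np.zeros(len(scores), dtype=np.int64)
        pop.excluded = np.zeros(len(scores), dtype=bool)
        return pop

    def test_monotone_scores_select_exact_extremes(self, one_chrom_genome):
        pop = self._pop_with_scores(one_chrom_genome, np.arange(1, 201))
        res, sens = mm.make_bulks(pop, 50)
        assert np.array_equal(res, np.arange(50))
        assert np.array_equal(sens, np.arange(150, 200))

    def test_all_ties_is_a_seeded_random_partition(self, one_chrom_genome):
        pop = self._pop_with_scores(one_chrom_genome, np.ones(100))
        res, sens = mm.make_bulks(pop, 50, seed=7)
        assert len(np.intersect1d(res, sens)) == 0
        assert len(res) == len(sens) == 50
        res2, sens2 = mm.make_bulks(pop, 50, seed=7)
        assert np.array_equal(res, res2) and np.array_equal(sens, sens2)

    def test_excluded_individuals_never_enter_bulks(self, one_chrom_genome):
        pop = self._pop_with_scores(one_chrom_genome, np.arange(1, 121))
        pop.excluded[:10] = True
        res, sens = mm.make_bulks(pop, 50)
        assert not set(res) & set(range(10))

    def test_oversized_bulks_rejected(self, one_chrom_genome):
        pop = self._pop_with_scores(one_chrom_genome, np.arange(1, 61))
        with pytest.raises(ValueError):
            mm.make_bulks(pop, 50)


class TestSimulatePoolSeq:
    def _fixed_pop(self, one_chrom_genome, genotype_value, n=20):
        panel = mm.simulate_parents(one_chrom_genome, 60, divergence=1.0, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), n, one_chrom_genome, seed=1)
        pop.genotypes["chr1"][:] = genotype_value
        return pop

    def test_pool_fixed_for_reference_allele_gives_ad_ref_equal_dp(self, one_chrom_genome):
        pop = self._fixed_pop(one_chrom_genome, 0)  # all susceptible-homozygous
        table = mm.simulate_pool_seq(
            pop, (np.arange(10), np.arange(10, 20)),
            mm.PoolSeqParams(pool_size=10, mean_depth=6.0, read_error=0.0, seed=3),
        )
        assert (table["AD_REF_RES"] == table["DP_RES"]).all()
        assert (table["AD_ALT_RES"] == 0).all()

    def test_mean_depth_matches_poisson_oracle(self, one_chrom_genome):
        panel = mm.simulate_parents(one_chrom_genome, 5000, divergence=1.0, seed=0)
        pop = mm.simulate_f2(panel, ("B49", "B73"), 20, one_chrom_genome, seed=1)
        table = mm.simulate_pool_seq(
            pop, (np.arange(10), np.arange(10, 20)),
            mm.PoolSeqParams(pool_size=10, mean_depth=4.0, seed=5),
        )
        dp = np.concatenate([table["DP_RES"], table["DP_SENS"]])
        assert 3.9 <= dp.mean() <= 4.1

    def test_gq_rule_and_determinism(self, one_chrom_genome):
        pop = self._fixed_pop(one_chrom_genome, 1)
        params = mm.PoolSeqParams(pool_size=10, mean_depth=4.0, seed=11)
        t1 = mm.simulate_pool_seq(pop, (np.arange(10), np.arange(10, 20)), params)
        t2 = mm.simulate_pool_seq(pop, (np.arange(10), np.arange(10, 20)), params)
        assert t1.equals(t2)
        assert (t1["GQ_RES"] == np.minimum(99, 10 * t1["DP_RES"])).all()

    def test_empty_bulks_rejected(self, one_chrom_genome):
        pop = self._fixed_pop(one_chrom_genome, 0)
        with pytest.raises(ValueError):
            mm.simulate_pool_seq(pop, (np.array([], dtype=int), np.arange(5)),
                                 mm.PoolSeqParams(pool_size=5))

    def test_read_error_bounds(self):
        with pytest.raises(ValueError):
            mm.PoolSeqParams(read_error=0.1)
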
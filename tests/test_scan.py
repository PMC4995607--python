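"""d_i standardization, empirical p, the strict top-fraction rule, region
merging arithmetic and end-to-end scan properties."""

import numpy as np
import pytest

import altisweep as aw
from oracles import di_bruteforce, empirical_p_bruteforce


class TestDi:
    def test_locus_at_pair_means_scores_zero(self):
        theta = np.array([[0.1, 0.2], [0.3, 0.4], [0.2, 0.3]])
        table = aw.PairwiseFstTable("f", ["r1", "r2"], list("abc"), theta,
                                    np.zeros_like(theta), np.ones_like(theta))
        mom = aw.fst_moments(table)
        di, _ = aw.di_statistic(table, mom)
        # middle locus sits exactly at both pair means
        assert di[2] == pytest.approx(0.0, abs=1e-12)

    def test_unit_z_score_single_pair(self):
        theta = np.array([[0.1], [0.2], [0.3]])
        table = aw.PairwiseFstTable("f", ["r"], list("abc"), theta,
                                    np.zeros_like(theta), np.ones_like(theta))
        mom = aw.fst_moments(table)
        di, _ = aw.di_statistic(table, mom)
        sd = np.std([0.1, 0.2, 0.3], ddof=1)
        assert di[2] == pytest.approx((0.3 - 0.2) / sd, abs=1e-12)

    def test_matches_bruteforce_with_undefined_entries(self):
        rng = np.random.default_rng(31)
        theta = rng.uniform(-0.05, 0.5, size=(30, 3))
        theta[rng.random(theta.shape) < 0.1] = np.nan
        table = aw.PairwiseFstTable("f", ["r1", "r2", "r3"],
                                    [f"l{j}" for j in range(30)], theta,
                                    np.zeros_like(theta), np.ones_like(theta))
        mom = aw.fst_moments(table)
        di, _ = aw.di_statistic(table, mom)
        np.testing.assert_allclose(di, di_bruteforce(theta), atol=1e-12)

    def test_zero_sd_pair_contributes_zero_with_warning(self, caplog):
        theta = np.column_stack([np.array([0.1, 0.2, 0.3]), np.full(3, 0.2)])
        table = aw.PairwiseFstTable("f", ["r1", "r2"], list("abc"), theta,
                                    np.zeros_like(theta), np.ones_like(theta))
        mom = aw.fst_moments(table)
        with caplog.at_level("WARNING"):
            di, z = aw.di_statistic(table, mom)
        assert np.all(z[:, 1] == 0)
        assert any("zero sd" in r.message for r in caplog.records)

    def test_column_centring_invariant(self, scan_panel):
        """Each pair's standardized terms have mean 0 and sample sd 1 over
        defined loci, so d_i itself averages ~0."""
        matrix, _ = scan_panel
        table = aw.pairwise_fst_table(matrix, "hi1", ["lo1", "lo2", "lo3", "lo4"])
        mom = aw.fst_moments(table)
        di, z = aw.di_statistic(table, mom)
        mask = table.defined_mask
        for k in range(z.shape[1]):
            col = z[mask[:, k], k]
            assert col.mean() == pytest.approx(0.0, abs=1e-9)
            assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestEmpiricalP:
    def test_strict_maximum_gets_one_over_n(self):
        di = np.array([1.0, 2.0, 5.0, 3.0])
        pe = aw.empirical_p(di)
        assert pe[2] == pytest.approx(1 / 4)
        assert pe[0] == pytest.approx(1.0)

    def test_total_tie_gives_one_everywhere(self):
        pe = aw.empirical_p(np.full(10, 0.5))
        np.testing.assert_allclose(pe, 1.0)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        di = np.round(rng.normal(size=1000), 2)  # rounding forces ties
        np.testing.assert_allclose(aw.empirical_p(di),
                                   empirical_p_bruteforce(di), atol=1e-12)

    def test_monotone_nonincreasing_in_di(self):
        rng = np.random.default_rng(9)
        di = rng.normal(size=200)
        pe = aw.empirical_p(di)
        order = np.argsort(di)
        assert np.all(np.diff(pe[order]) <= 1e-15)

    def test_nonfinite_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pe = aw.empirical_p(np.array([1.0, np.nan, 2.0]))
        assert np.isnan(pe[1]) and pe[2] == pytest.approx(0.5)


class TestTopFraction:
    @pytest.mark.parametrize("n,expect", [(43_835, 219), (1_000, 4)])
    def test_strict_rule_counts(self, n, expect):
        """With N distinct values the strict P_E < 0.005 rule keeps the top k
        where k is the largest integer with k/N < 0.005."""
        rng = np.random.default_rng(1)
        di = rng.permutation(np.arange(n, dtype=float))
        sig = aw.significant_loci(aw.empirical_p(di))
        assert int(sig.sum()) == expect

    def test_all_tied_selects_none(self):
        sig = aw.significant_loci(aw.empirical_p(np.zeros(100)))
        assert not sig.any()

    def test_significant_set_is_upper_set_of_di(self):
        rng = np.random.default_rng(2)
        di = rng.normal(size=2000)
        sig = aw.significant_loci(aw.empirical_p(di))
        if sig.any():
            assert di[sig].min() > di[~sig].max()


class TestMergeRegions:
    def test_chr7_three_snp_region_width(self):
        regions = aw.merge_regions([
            ("a", "7", 57_764_872), ("b", "7", 57_816_492), ("c", "7", 57_915_106)])
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (57_764_872, 57_915_106)
        assert r.width_bp == 150_234      # 150.2 kb
        assert r.n_snps == 3

    def test_chr7_two_snp_region_width(self):
        regions = aw.merge_regions([("a", "7", 57_764_872), ("b", "7", 57_816_492)])
        assert regions[0].width_bp == 51_620   # 51.6 kb

    def test_gap_boundary_inclusive(self):
        one = aw.merge_regions([("a", "1", 1_000), ("b", "1", 501_000)])
        two = aw.merge_regions([("a", "1", 1_000), ("b", "1", 501_001)])
        assert len(one) == 1 and len(two) == 2

    def test_singleton_forms_width_zero_region(self):
        r = aw.merge_regions([("a", "3", 42)])[0]
        assert r.start_bp == r.end_bp == 42 and r.n_snps == 1

    def test_regions_partition_loci_and_merge_is_fixpoint(self):
        rng = np.random.default_rng(4)
        loci = [(f"l{j}", str(rng.integers(1, 4)), int(rng.integers(1, 10_000_000)))
                for j in range(200)]
        regions = aw.merge_regions(loci)
        members = [lid for r in regions for lid in r.locus_ids]
        assert sorted(members) == sorted(l[0] for l in loci)
        # separation: consecutive regions on one chromosome are > gap apart
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            for r1, r2 in zip(rs, rs[1:]):
                assert r2.start_bp - r1.end_bp > 500_000
        # re-merging region bounds is a fixpoint
        again = aw.merge_regions([(r.locus_ids[0], r.chrom, r.start_bp) for r in regions])
        assert len(again) == len(regions)


class TestRunScan:
    def test_injected_sweeps_recovered(self, scan_panel):
        matrix, sweep_idx = scan_panel
        sweep_ids = {f"snp_{i:06d}" for i in sweep_idx}
        for focal in ("hi1", "hi2"):
            res, regions = aw.run_scan(matrix, focal, ["lo1", "lo2", "lo3", "lo4"])
            sig_ids = set(np.array(res.locus_ids)[res.significant])
            assert sweep_ids <= sig_ids
            assert regions

    def test_empty_reference_list_rejected(self, scan_panel):
        with pytest.raises(ValueError):
            aw.run_scan(scan_panel[0], "hi1", [])

    def test_scan_invariant_to_sample_and_locus_order(self, scan_panel):
        matrix, _ = scan_panel
        rng = np.random.default_rng(0)
        shuffled = matrix.subset(sample_idx=rng.permutation(matrix.n_samples),
                                 locus_idx=rng.permutation(matrix.n_loci))
        shuffled = aw.sort_loci(shuffled)
        r1, _ = aw.run_scan(matrix, "hi1", ["lo1", "lo2"])
        r2, _ = aw.run_scan(shuffled, "hi1", ["lo1", "lo2"])
        assert r1.locus_ids == r2.locus_ids
        np.testing.assert_allclose(r1.di, r2.di)

    def test_scan_maf_filter_uses_pooled_union(self):
        """A locus rare in the pooled focal+reference sample is dropped even
        if common in an unused population."""
        samples = ([aw.SampleInfo(f"a{i}", "A", "high") for i in range(10)]
                   + [aw.SampleInfo(f"b{i}", "B") for i in range(10)]
                   + [aw.SampleInfo(f"c{i}", "C") for i in range(10)])
        dosage = np.zeros((30, 2), dtype=np.int8)
        dosage[:, 1] = 1
        dosage[20:, 0] = 2   # alt common only in unused population C
        m = aw.GenotypeMatrix(samples=samples,
                              loci=[aw.LocusInfo("x", "1", 100, "A", "G"),
                                    aw.LocusInfo("y", "1", 200, "A", "G")],
                              dosage=dosage)
        kept = aw.scan_maf_filter(m, "A", ["B"])
        assert [l.id for l in kept.loci] == ["y"]

    def test_null_panel_calibration(self):
        """Without sweeps the significant count equals the strict top-0.5%
        arithmetic of the realized (possibly tied) d_i distribution."""
        cfg = aw.SimulationConfig(
            n_loci=2000,
            populations=(aw.PopulationSpec("hi1", "high", 25, 0.05),
                         aw.PopulationSpec("lo1", "low", 25, 0.05),
                         aw.PopulationSpec("lo2", "low", 25, 0.05),
                         aw.PopulationSpec("lo3", "low", 25, 0.05)),
            seed=55)
        m, _ = aw.simulate_panel(cfg)
        res, _ = aw.run_scan(m, "hi1", ["lo1", "lo2", "lo3"])
        n = len(res.di)
        expect = int((empirical_p_bruteforce(np.asarray(res.di)) < 0.005).sum())
        assert int(res.significant.sum()) == expect
        assert expect <= int(0.005 * n)
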
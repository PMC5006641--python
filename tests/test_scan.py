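"""Window scan: filtering, expectation, ratio statistic, and the two nulls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_variants
from regionburden.io import GenomicInterval
from regionburden.scan import (
    RareVariantFilterConfig,
    RegionalBurdenScan,
    WindowScanConfig,
    annotate_regulatory_overlap,
    carrier_summary,
    control_order_statistic_p,
    count_rare_in_windows,
    enumerate_windows,
    expected_common_density,
    expected_common_density_closed_form,
    filter_rare_variants,
    format_order_p,
    poisson_local_enrichment,
    poisson_tail,
    window_statistic,
)
from regionburden.synthetic import PopulationModel, random_common_sites, simulate_rare_variant_cohort


class TestRareVariantFilter:
    def _panel(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "pos": [300], "ref": ["A"], "alt": ["T"], "maf": [0.2]}
        )

    def test_recurrence_is_exclusive(self):
        """A variant in exactly max_samples samples is excluded ('less than
        five'); one in max_samples - 1 is kept."""
        rows = [("chr1", 100, "A", "T", f"s{i}") for i in range(5)]
        rows += [("chr1", 200, "G", "C", f"s{i}") for i in range(4)]
        out = filter_rare_variants(make_variants(rows))
        assert set(out["pos"]) == {200}

    def test_bad_flag_excluded(self):
        rows = [("chr1", 100, "A", "T", "s1", 1, "strandBias", "unknown")]
        assert len(filter_rare_variants(make_variants(rows))) == 0

    def test_allele_bias_kept(self):
        rows = [("chr1", 100, "A", "T", "s1", 1, "allele_bias", "unknown")]
        assert len(filter_rare_variants(make_variants(rows))) == 1

    def test_manual_enumeration(self):
        """6 variants: 2 too recurrent, 1 in panel, 1 badly flagged -> 2 left."""
        cfg = RareVariantFilterConfig(max_samples=3)
        rows = []
        rows += [("chr1", 100, "A", "T", f"s{i}") for i in range(3)]   # recurrent
        rows += [("chr1", 150, "C", "G", f"s{i}") for i in range(4)]   # recurrent
        rows += [("chr1", 300, "A", "T", "s1")]                        # in panel
        rows += [("chr1", 400, "G", "A", "s2", 1, "other", "unknown")] # bad flag
        rows += [("chr1", 500, "T", "C", "s1")]                        # keep
        rows += [("chr1", 600, "C", "A", "s9")]                        # keep
        out = filter_rare_variants(make_variants(rows), self._panel(), cfg)
        assert set(out["pos"]) == {500, 600}

    def test_empty_input(self):
        from regionburden.io import empty_variant_table
        assert len(filter_rare_variants(empty_variant_table())) == 0


class TestWindows:
    def test_count_closed_form(self):
        region = GenomicInterval("chr3", 1, 2_000_000)
        starts, ends = enumerate_windows(region, window_size=40_000, step=100)
        assert len(starts) == 19_601
        assert starts[0] == 1 and ends[0] == 40_000
        assert ends[-1] <= region.end
        assert ((ends - starts) == 39_999).all()
        assert (np.diff(starts) == 100).all()

    def test_single_window_when_equal(self):
        region = GenomicInterval("chr1", 11, 1010)
        starts, ends = enumerate_windows(region, window_size=1000, step=10)
        assert len(starts) == 1 and starts[0] == 11 and ends[0] == 1010

    def test_region_too_short(self):
        with pytest.raises(ValueError):
            enumerate_windows(GenomicInterval("chr1", 1, 999), window_size=1000, step=10)


class TestExpectedCommonDensity:
    def test_single_site_carrier_mean(self):
        """One site at maf 0.5, cohort 33: expectation within 3 MC-SE of
        33 * (2*0.25 + 0.25) = 24.75."""
        region = GenomicInterval("chr1", 1, 1000)
        panel = pd.DataFrame({"chrom": ["chr1"], "pos": [500], "ref": ["A"], "alt": ["T"], "maf": [0.5]})
        cfg = WindowScanConfig(window_size=1000, step=1000, n_sim=400, cohort_size=33)
        mean, sd = expected_common_density(panel, region, cfg, seed=0)
        q = 1 - 0.5**2
        true_mean = 33 * q
        true_sd = np.sqrt(33 * q * (1 - q))
        assert abs(mean[0] - true_mean) < 3 * true_sd / np.sqrt(cfg.n_sim)
        assert true_mean == pytest.approx(24.75)

    def test_converges_to_closed_form(self, small_region, small_population):
        cfg = WindowScanConfig(window_size=40_000, step=10_000, n_sim=600, cohort_size=33)
        panel = small_population.panel()
        mean, sd = expected_common_density(panel, small_region, cfg, seed=1)
        closed = expected_common_density_closed_form(panel, small_region, cfg)
        mc_se = sd / np.sqrt(cfg.n_sim)
        assert (np.abs(mean - closed) < 3 * np.maximum(mc_se, 1e-9) + 1e-9).all()

    def test_no_sites_gives_zero_with_warning(self):
        region = GenomicInterval("chr1", 1, 2000)
        panel = pd.DataFrame({"chrom": ["chr2"], "pos": [500], "ref": ["A"], "alt": ["T"], "maf": [0.5]})
        cfg = WindowScanConfig(window_size=1000, step=1000, n_sim=10)
        with pytest.warns(UserWarning, match="no common panel sites"):
            mean, sd = expected_common_density(panel, region, cfg, seed=0)
        assert (mean == 0).all()

    def test_sites_mode_counts_segregating_sites(self):
        region = GenomicInterval("chr1", 1, 1000)
        panel = pd.DataFrame({"chrom": ["chr1"], "pos": [500], "ref": ["A"], "alt": ["T"], "maf": [0.5]})
        cfg = WindowScanConfig(window_size=1000, step=1000, n_sim=400, cohort_size=33,
                               count_mode="sites")
        mean, _ = expected_common_density(panel, region, cfg, seed=2)
        # one site, virtually always polymorphic in 33 people at maf 0.5
        assert 0.99 <= mean[0] <= 1.0


class TestWindowStatistic:
    def test_values(self):
        obs = np.array([0.0, 5.0, 3.0])
        exp = np.array([2.0, 2.0, 1.5])
        assert window_statistic(obs, exp).tolist() == [0.0, 2.5, 2.0]

    def test_zero_expected_sentinel(self):
        with pytest.warns(UserWarning, match="zero expectation"):
            ratio = window_statistic(np.array([1.0]), np.array([0.0]))
        assert np.isinf(ratio[0])

    def test_zero_observed_zero_expected(self):
        assert window_statistic(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            window_statistic(np.zeros(3), np.zeros(2))


class TestPoissonModel:
    def test_tail_examples(self):
        assert poisson_tail(np.array([0]), 2.26)[0] == 1.0
        lam = 113 * 40_000 / 2_000_000
        # term-by-term summation oracle for P(X >= 8)
        from math import factorial
        oracle = sum(np.exp(-lam) * lam**k / factorial(k) for k in range(8, 80))
        assert poisson_tail(np.array([8]), lam)[0] == pytest.approx(oracle, rel=1e-10)

    def test_monotone_in_observed(self):
        p = poisson_tail(np.arange(0, 30), 2.26)
        assert (np.diff(p) < 0).all()

    def test_window_table(self):
        region = GenomicInterval("chr1", 1, 10_000)
        rows = [("chr1", p, "A", "T", "s1") for p in (100, 200, 5000, 9000)]
        cfg = WindowScanConfig(window_size=1000, step=1000)
        out = poisson_local_enrichment(make_variants(rows), region, cfg)
        assert len(out) == 10
        assert out["observed"].sum() == 4
        lam = 4 / 10_000 * 1000
        expected_p = stats.poisson.sf(out["observed"] - 1, lam)
        assert np.allclose(out["poisson_p"], expected_p)

    def test_requires_variants(self):
        from regionburden.io import empty_variant_table
        with pytest.raises(ValueError):
            poisson_local_enrichment(empty_variant_table(), GenomicInterval("chr1", 1, 10_000))


class TestOrderStatistic:
    def _setup(self):
        region = GenomicInterval("chr1", 1, 10_000)
        windows = enumerate_windows(region, window_size=10_000, step=10_000)
        # 10 control individuals, each carrying i variants (distinct positions)
        rows = []
        pos = itertools.count(10)
        for i in range(10):
            for _ in range(i + 1):
                rows.append(("chr1", next(pos), "A", "T", f"c{i}"))
        control = make_variants(rows)
        return region, windows, control

    def test_p_one_when_observed_below_all(self):
        region, windows, control = self._setup()
        cfg = WindowScanConfig(window_size=10_000, step=10_000, n_control_subsets=30, cohort_size=4)
        p = control_order_statistic_p(np.array([0.0]), control, np.array([1.0]), windows,
                                      config=cfg, seed=0)
        assert p[0] == 1.0

    def test_p_zero_when_observed_above_all(self):
        region, windows, control = self._setup()
        cfg = WindowScanConfig(window_size=10_000, step=10_000, n_control_subsets=30, cohort_size=4)
        p = control_order_statistic_p(np.array([1e9]), control, np.array([1.0]), windows,
                                      config=cfg, seed=0)
        assert p[0] == 0.0
        assert format_order_p(p[0], 100) == "< 0.01"

    def test_matches_exhaustive_subset_distribution(self):
        """Monte-Carlo order p within 3 SE of the exact subset enumeration."""
        region, windows, control = self._setup()
        cohort_size, n_subsets = 4, 400
        cfg = WindowScanConfig(window_size=10_000, step=10_000,
                               n_control_subsets=n_subsets, cohort_size=cohort_size)
        observed = np.array([22.0])  # compare against total variants of a subset
        expected = np.array([1.0])
        p = control_order_statistic_p(observed, control, expected, windows, config=cfg, seed=1)
        # exact: each control sample i carries i+1 distinct variants, all rare
        sizes = np.arange(1, 11)
        exact = np.mean([
            sum(combo) >= observed[0]
            for combo in itertools.combinations(sizes, cohort_size)
        ])
        se = np.sqrt(exact * (1 - exact) / n_subsets)
        assert abs(p[0] - exact) < 3 * se

    def test_control_pool_too_small(self):
        region, windows, control = self._setup()
        cfg = WindowScanConfig(window_size=10_000, step=10_000, cohort_size=50)
        with pytest.raises(ValueError, match="cohort_size"):
            control_order_statistic_p(np.array([1.0]), control, np.array([1.0]), windows, config=cfg)

    def test_null_order_p_not_anticonservative(self):
        """Case cohort drawn from the control model: order p-values over
        non-overlapping windows are stochastically >= uniform (one-sided KS)."""
        region = GenomicInterval("chr3", 1, 2_000_000)
        sites = random_common_sites(region, 100, seed=20)
        model = PopulationModel(region=region, common_sites=sites, rare_site_rate=1.05e-5)
        case = simulate_rare_variant_cohort(model, 10, seed=21)
        control = simulate_rare_variant_cohort(model, 40, seed=22)
        panel = model.panel()
        cfg = WindowScanConfig(window_size=40_000, step=40_000, n_sim=100,
                               cohort_size=10, n_control_subsets=40)
        scan = RegionalBurdenScan(case, region, panel, control, config=cfg)
        res = scan.fit(seed=23)
        pvals = res.frame["order_p"].to_numpy()
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestOverlapAnnotation:
    def test_boundaries_inclusive(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        rows = [("chr1", p, "A", "T", "s1") for p in (99, 100, 150, 200, 201)]
        out, summary = annotate_regulatory_overlap(make_variants(rows), {"dnase": track})
        assert out["in_dnase"].tolist() == [False, True, True, True, False]
        assert summary == {"dnase": 3, "any": 3}

    def test_agrees_with_linear_scan(self):
        rng = np.random.default_rng(5)
        intervals = []
        cursor = 1
        for _ in range(30):
            cursor += int(rng.integers(10, 200))
            length = int(rng.integers(1, 150))
            intervals.append(("chr1", cursor, cursor + length - 1))
            cursor += length
        track = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        positions = rng.integers(1, cursor + 100, size=200)
        rows = [("chr1", int(p), "A", "T", f"s{i}") for i, p in enumerate(positions)]
        out, _ = annotate_regulatory_overlap(make_variants(rows), {"t": track})
        # brute-force scan over all intervals per variant
        for flag, p in zip(out["in_t"], out["pos"]):
            manual = any(s <= p <= e for _, s, e in intervals)
            assert flag == manual


class TestCarrierSummary:
    def test_percentages(self):
        rows = []
        for i in range(16):
            status = "somatic" if i < 7 else "germline"
            rows.append(("chr3", 182_200_000 + i, "A", "T", f"p{i:02d}", 1, "pass", status))
        region = GenomicInterval.parse("chr3:182,189,714-182,229,714")
        summary = carrier_summary(make_variants(rows), region, n_cohort=33)
        assert summary["n_carriers"] == 16
        assert summary["pct_carriers"] == 48.5
        assert summary["n_somatic_carriers"] == 7
        assert summary["pct_somatic_carriers"] == 21.2


class TestScanModel:
    def test_fit_deterministic_under_seed(self, small_region, small_population):
        case = simulate_rare_variant_cohort(small_population, 10, seed=31)
        control = simulate_rare_variant_cohort(small_population, 30, seed=32)
        panel = small_population.panel()
        cfg = WindowScanConfig(window_size=40_000, step=20_000, n_sim=50,
                               cohort_size=10, n_control_subsets=20)
        frames = []
        for _ in range(2):
            model = RegionalBurdenScan(case, small_region, panel, control, config=cfg)
            frames.append(model.fit(seed=99).frame)
        pd.testing.assert_frame_equal(frames[0], frames[1])

    def test_enriched_window_overlaps_argmax(self):
        """The argmax-ratio window overlaps a strongly enriched window."""
        region = GenomicInterval("chr3", 1_000_001, 3_000_000)
        enriched = GenomicInterval("chr3", 1_800_001, 1_840_000)
        # ~1 common SNP per kb, the reference-panel density over such regions
        sites = random_common_sites(region, 2000, seed=41)
        model = PopulationModel(region=region, common_sites=sites,
                                rare_site_rate=1.05e-5,
                                enrichment_windows=[(enriched, 5.0)])
        panel = model.panel()
        cfg = WindowScanConfig(window_size=40_000, step=1000, n_sim=50, cohort_size=33)
        for seed in (1, 2, 3):
            case = simulate_rare_variant_cohort(model, 33, seed=seed)
            scan = RegionalBurdenScan(case, region, panel, config=cfg)
            res = scan.fit(seed=seed + 100)
            best = res.top_windows(1).iloc[0]
            assert best["start"] <= enriched.end and best["end"] >= enriched.start

    def test_summary_mentions_no_correction(self, small_region, small_population):
        case = simulate_rare_variant_cohort(small_population, 5, seed=51)
        cfg = WindowScanConfig(window_size=40_000, step=40_000, n_sim=20, cohort_size=5)
        res = RegionalBurdenScan(case, small_region, small_population.panel(), config=cfg).fit(seed=0)
        assert "multiple-testing" in res.summary()
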
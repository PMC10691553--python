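"""Fold changes, rank tests, hotspots, regression, heritability, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import permutation_ranksum_p
from telocus.annotation_io import ChromSpec, GeneModel, TEInsertion
from telocus.compartments import LocusTEProfile, profile_locus
from telocus.enrichment_stats import (
    PosteriorSamples,
    adjust_pvalues,
    call_hotspots,
    cyp_function_contrast,
    fold_change,
    fragment_length_summary,
    heritability,
    kruskal_wallis,
    locus_table,
    rank_sum_test,
    species_enrichment_table,
    te_genome_regression,
)


class TestFoldChange:
    def test_printed_locus_means_round_to_printed_multiples(self):
        # DNA-class means: 4026 vs 1974 bp coverage, 10.05 vs 1.57 count
        assert fold_change(4026, 1974)[1] == 2.0
        assert fold_change(10.05, 1.57)[1] == 6.4

    def test_identity(self):
        raw, rounded = fold_change(123.4, 123.4)
        assert raw == 1.0 and rounded == 1.0

    def test_zero_background_is_undefined(self):
        raw, rounded = fold_change(5.0, 0.0)
        assert math.isnan(raw) and math.isnan(rounded)

    def test_rounding_is_half_even(self):
        assert fold_change(1.25, 1.0)[1] == 1.2
        assert fold_change(1.35, 1.0)[1] == 1.4


class TestRankSum:
    def test_exact_small_sample(self):
        # a=[1,2] vs b=[3,4]: 6 equally likely rank assignments, 2 as extreme
        _w, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _w, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_close_to_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.9, 1.0, 30)
        _w, p = rank_sum_test(a, b)
        p_perm = permutation_ranksum_p(a, b, 100_000, rng)
        assert p == pytest.approx(p_perm, abs=1e-3)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_rep = 2_000
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if rank_sum_test(a, b)[1] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    def test_hand_computed_value(self):
        # rank sums 6, 15, 24 over N=9 -> H = 12/90 * (12+75+192) - 30 = 7.2
        h, _p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_close_to_permutation_oracle(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0.4, 1, 15), rng.normal(0.8, 1, 15)]
        h, p = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 20_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            hp, _ = kruskal_wallis(parts)
            if hp >= h - 1e-12:
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.02)


def _profile(gene_id, cov, cnt, genic=0):
    return LocusTEProfile(gene_id=gene_id, coverage_bp=cov, count=cnt, genic_te_bp=genic)


class TestHotspots:
    def test_threshold_rule_is_strict(self):
        genes = [GeneModel(f"g{i}", "chr1", "+", [(i * 100_000, i * 100_000 + 1_000)], "CYP")
                 for i in range(3)]
        profiles = [_profile("g0", 36_000, 81), _profile("g1", 35_000, 81),
                    _profile("g2", 36_000, 80)]
        calls = {c.gene_id: c for c in call_hotspots(genes, profiles)}
        assert calls["g0"].is_hotspot
        assert not calls["g1"].is_hotspot  # coverage not above threshold
        assert not calls["g2"].is_hotspot  # count not above threshold

    def test_z_score_population_sd(self):
        # gene sizes {10,10,10,40}: mean 17.5, population SD 12.99 -> Z = 1.73
        genes = [GeneModel(f"g{i}", "chr1", "+", [(i * 1_000, i * 1_000 + size)], "UGT")
                 for i, size in enumerate([10, 10, 10, 40])]
        profiles = [_profile(g.gene_id, 0, 0) for g in genes]
        calls = {c.gene_id: c for c in call_hotspots(genes, profiles)}
        assert calls["g3"].gene_size_z == pytest.approx(1.73, abs=5e-3)

    def test_te_driven_size_inflation_flagged(self):
        # 19 genes near 10 kb plus one 60-kb gene whose excess is TE sequence
        sizes = [9_500 + 50 * i for i in range(19)] + [60_000]
        genes = [GeneModel(f"g{i:02d}", "chr1", "+", [(i * 100_000, i * 100_000 + s)], "CYP")
                 for i, s in enumerate(sizes)]
        profiles = [
            _profile(g.gene_id, 0, 0, genic=49_800 if g.gene_id == "g19" else 0)
            for g in genes
        ]
        calls = {c.gene_id: c for c in call_hotspots(genes, profiles)}
        assert calls["g19"].gene_size_z > 3
        assert calls["g19"].gene_size_z_te_removed < 3

    def test_degenerate_categories_get_nan(self, fixtures):
        fx = fixtures["zero_sd_category"]  # three UGT genes of identical size
        profiles = [_profile(g.gene_id, 0, 0) for g in fx.genes]
        calls = call_hotspots(fx.genes, profiles)
        assert all(math.isnan(c.gene_size_z) for c in calls)

    def test_invariant_to_gene_input_order(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", "+",
                           [(i * 10_000, i * 10_000 + int(rng.integers(500, 5_000)))], "GST")
                 for i in range(8)]
        profiles = [_profile(g.gene_id, int(rng.integers(0, 50_000)),
                             int(rng.integers(0, 120))) for g in genes]
        a = call_hotspots(genes, profiles)
        order = rng.permutation(len(genes))
        b = call_hotspots([genes[i] for i in order], [profiles[i] for i in order])
        assert a == b


class TestSpeciesEnrichment:
    @staticmethod
    def _table(rng, species, fold=1.0, n_focal=30, n_bg=70):
        rows = []
        for i in range(n_focal + n_bg):
            focal = i < n_focal
            scale = fold if focal else 1.0
            rows.append(
                {"species": species, "gene_id": f"{species}_g{i}",
                 "category": "CYP" if focal else "other", "cyp_function": "unassigned",
                 "gene_size": 1_000,
                 "coverage_bp": rng.poisson(8) * scale * 500,
                 "count": rng.poisson(8 * scale), "genic_te_bp": 0}
            )
        return pd.DataFrame(rows)

    def test_single_species_table_has_one_row_per_metric(self, rng):
        table, _cross = species_enrichment_table({"spA": self._table(rng, "spA")})
        assert len(table) == 2
        assert set(table["metric"]) == {"coverage_bp", "count"}

    def test_planted_threefold_recovered(self, rng):
        tables = {"spA": self._table(rng, "spA", fold=3.0, n_focal=300, n_bg=300)}
        table, _ = species_enrichment_table(tables)
        cov = table[table["metric"] == "coverage_bp"].iloc[0]
        assert 2.5 <= cov["fold_change_raw"] <= 3.5

    def test_cross_species_analysis_present(self, rng):
        tables = {sp: self._table(rng, sp) for sp in ("spA", "spB", "spC")}
        _table, cross = species_enrichment_table(tables)
        assert set(cross) == {"coverage_bp", "count"}
        h, p = cross["coverage_bp"]
        assert h >= 0 and 0 <= p <= 1


class TestFragmentLengths:
    def test_simple_means_and_fraction(self):
        mean, frac, _h = fragment_length_summary([500, 500])
        assert (mean, frac) == (500, 1.0)
        mean, frac, _h = fragment_length_summary([250, 1750])
        assert (mean, frac) == (1000, 0.5)

    def test_histogram_matches_naive_binning(self, rng):
        lengths = rng.integers(1, 5_000, size=400)
        _m, _f, hist = fragment_length_summary(lengths)
        naive = np.zeros(len(hist))
        for ln in lengths:
            naive[ln // 250] += 1
        assert (hist["count"].to_numpy() == naive).all()


class TestRegression:
    def test_collinear_points_have_unit_r2(self):
        x = [1, 2, 3, 4, 5]
        slope, _f, _p, r2 = te_genome_regression(x, [2 * xi + 1 for xi in x])
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_hand_computed_normal_equations(self):
        x = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        y = np.array([8.0, 12.0, 18.0, 25.0, 33.0])
        slope_hand = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        slope, f, p, r2 = te_genome_regression(x, y)
        assert slope == pytest.approx(slope_hand)
        assert f > 0 and 0 <= p <= 1 and 0 <= r2 <= 1

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            te_genome_regression([1, 1, 1], [1, 2, 3])

    def test_null_pvalues_uniform(self, rng):
        from scipy.stats import kstest

        x = rng.normal(size=20)
        pvals = []
        for _ in range(200):
            y = rng.normal(size=20)
            pvals.append(te_genome_regression(x, y)[2])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestHeritability:
    def test_equal_components_give_half(self):
        s = PosteriorSamples(np.ones(100), np.ones(100))
        mean, (lo, hi) = heritability(s)
        assert mean == 0.5 and lo == 0.5 and hi == 0.5

    def test_uniform_grid_hpd_covers_95_percent_span(self):
        r = np.linspace(0, 1, 1_001)
        s = PosteriorSamples(r, 1 - r)  # ratios reproduce the grid
        mean, (lo, hi) = heritability(s)
        assert mean == pytest.approx(0.5)
        assert hi - lo == pytest.approx(0.95, abs=2e-3)

    def test_no_species_variance_gives_one(self):
        s = PosteriorSamples(np.full(10, 2.0), np.zeros(10))
        mean, (lo, hi) = heritability(s)
        assert mean == 1.0 and (lo, hi) == (1.0, 1.0)

    def test_zero_total_samples_dropped_with_warning(self):
        s = PosteriorSamples(np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 3.0]))
        with pytest.warns(UserWarning, match="dropped"):
            mean, _ = heritability(s)
        assert mean == pytest.approx((0.5 + 0.25) / 2)


def _cyp_df(rng, n=30, fold=1.0):
    rows = []
    for i in range(2 * n):
        fn = "insecticide" if i < n else "natural"
        scale = fold if fn == "insecticide" else 1.0
        rows.append(
            {"species": "sp", "gene_id": f"g{i}", "category": "CYP",
             "cyp_function": fn, "gene_size": 1_000,
             "coverage_bp": float(rng.poisson(20)) * 300 * scale,
             "count": rng.poisson(6), "genic_te_bp": 0}
        )
    return pd.DataFrame(rows)


class TestCypContrast:
    def test_uniform_labels_skip_contrast(self, rng, caplog):
        df = _cyp_df(rng)
        df["cyp_function"] = "insecticide"
        with caplog.at_level("WARNING"):
            res = cyp_function_contrast(df)
        assert res == {}

    def test_planted_twofold_recovered(self, rng):
        res = cyp_function_contrast(_cyp_df(rng, n=30, fold=2.0))
        r = res["insecticide_vs_natural"]
        assert 1.6 <= r.fold_change_raw <= 2.4

    def test_null_labels_rarely_significant(self, rng):
        rejections = 0
        for _ in range(100):
            res = cyp_function_contrast(_cyp_df(rng, n=30, fold=1.0))
            if res["insecticide_vs_natural"].p_value < 0.05:
                rejections += 1
        assert rejections <= 6  # non-significant in >= 94% of replicates


class TestMultipleTesting:
    def test_benjamini_hochberg_monotone_and_bounded(self, rng):
        p = rng.uniform(size=25)
        adj = adjust_pvalues(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
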
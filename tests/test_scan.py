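import numpy as np
import pytest
from scipy import stats

from ailqtl import (AssociationModelSpec, GenotypeMatrix, MarkerMap,
                    PhenotypeSeries, association_test, effect_summary,
                    effect_summary_from_means, lod_from_p, scan_timeseries,
                    scan_week, top_snp)
from ailqtl.simulate import SimConfig, simulate_dataset


def brute_force_anova(groups):
    """Independent oracle: one-way fixed-effects F from explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(all_vals) - len(groups)
    F = (ssb / df1) / (ssw / df2)
    return F, stats.f.sf(F, df1, df2), ssb / (ssb + ssw)


class TestLodFromP:
    def test_meff_bonferroni_alpha_gives_printed_cutoff(self):
        assert round(lod_from_p(0.05 / 849), 1) == 4.2

    @pytest.mark.parametrize("p,expected", [(1.0, 0.0), (1e-7, 7.0)])
    def test_reference_points(self, p, expected):
        assert lod_from_p(p) == pytest.approx(expected)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            lod_from_p(0.0)


class TestAssociationTest:
    def _row_and_y(self, groups):
        calls = np.concatenate([[g] * len(v) for g, v in enumerate(groups)])
        y = np.concatenate(groups)
        return calls.astype(np.int8), y.astype(float)

    def test_identical_class_means_give_p_one(self):
        row, y = self._row_and_y([[5.0] * 6, [5.0] * 6, [5.0] * 6])
        p, r2, _ = association_test(row, y)
        assert p == 1.0 and r2 == 0.0

    def test_matches_brute_force_sums_of_squares(self):
        groups = [[1.0, 2, 3, 4, 2], [2.0, 3, 4, 5, 3], [3.0, 4, 5, 6, 4]]
        row, y = self._row_and_y(groups)
        p, r2, _ = association_test(row, y)
        _, p_ref, r2_ref = brute_force_anova(groups)
        assert p == pytest.approx(p_ref, rel=1e-10)
        assert r2 == pytest.approx(r2_ref, rel=1e-10)

    def test_invariant_to_animal_order(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, 30).astype(np.int8)
        y = rng.normal(30, 4, 30)
        p1, _, _ = association_test(row, y)
        perm = rng.permutation(30)
        p2, _, _ = association_test(row[perm], y[perm])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_fewer_than_two_classes_flagged_untested(self):
        row = np.array([2] * 10 + [1] * 2, dtype=np.int8)  # het below min_class_n
        y = np.arange(12, dtype=float) + 20
        p, r2, by_class = association_test(row, y)
        assert p is None and r2 is None
        assert by_class["S1S1"]["n"] == 10

    def test_missing_pairs_dropped(self):
        row = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, -1], dtype=np.int8)
        y = np.r_[np.arange(10, dtype=float) + 10, 99.0]
        p, _, by_class = association_test(row, y, AssociationModelSpec(min_class_n=2))
        assert by_class["S2S2"]["n"] + by_class["H"]["n"] == 10

    def test_two_class_anova_r2_equals_regression_r2(self):
        # with only two classes the factor model is an affine recoding of the
        # dosage regression, so the R^2 must agree
        rng = np.random.default_rng(2)
        row = np.array([0] * 15 + [2] * 15, dtype=np.int8)
        y = rng.normal(30, 3, 30) + 2.0 * (row == 2)
        _, r2_anova, _ = association_test(row, y)
        _, r2_reg, _ = association_test(
            row, y, AssociationModelSpec(model="additive_regression"))
        assert r2_anova == pytest.approx(r2_reg, rel=1e-9)


class TestScanTimeseries:
    def test_shape_one_result_per_week(self, small_sim):
        _, geno, pheno, _ = small_sim
        results = scan_timeseries(geno, pheno)
        assert len(results) == len(pheno.weeks)
        assert all(len(r.table) == geno.n_markers for r in results)

    def test_all_missing_week_skipped(self, tiny_geno):
        weights = np.full((6, 2), np.nan)
        weights[:, 0] = [20, 21, 22, 23, 24, 25.0]
        pheno = PhenotypeSeries([f"a{i}" for i in range(1, 7)], [3, 4], weights)
        with pytest.warns(UserWarning, match="week 4"):
            results = scan_timeseries(tiny_geno, pheno,
                                      AssociationModelSpec(min_class_n=1))
        assert [r.week for r in results] == [3]

    def test_no_overlapping_animals_rejected(self, tiny_geno, weekly_pheno):
        pheno = PhenotypeSeries([f"z{i}" for i in range(8)],
                                weekly_pheno.weeks, weekly_pheno.weights)
        with pytest.raises(ValueError, match="overlap"):
            scan_timeseries(tiny_geno, pheno)

    def test_simulated_qtl_max_lod_near_truth(self, small_sim):
        _, geno, pheno, truth = small_sim
        results = scan_timeseries(geno, pheno)
        marker, week, lod = top_snp(results)
        table = results[0].table
        pos = int(table.loc[table["marker_id"] == marker, "position_bp"].iloc[0])
        chrom = table.loc[table["marker_id"] == marker, "chromosome"].iloc[0]
        qc, qp = truth.qtl_positions[0]
        assert chrom == qc and abs(pos - qp) < 15_000_000


class TestTopSnp:
    def _results(self, lods_by_week, positions):
        import pandas as pd
        from ailqtl.scan import WeeklyScanResult
        out = []
        for week, lods in lods_by_week.items():
            t = pd.DataFrame({
                "marker_id": [f"m{i}" for i in range(len(lods))],
                "chromosome": "chr1", "position_bp": positions,
                "tested": True, "n_used": 100,
                "p_value": [10.0 ** -l for l in lods], "lod": lods,
                "r_squared": 0.1})
            out.append(WeeklyScanResult(week=week, table=t))
        return out

    def test_tie_breaks_to_smaller_position(self):
        res = self._results({3: [3.0, 5.1, 5.1]}, [10, 20, 30])
        assert top_snp(res)[0] == "m1"

    def test_global_max_over_weeks(self):
        res = self._results({3: [1.0, 2.0], 4: [6.0, 1.0]}, [10, 20])
        marker, week, lod = top_snp(res)
        assert (marker, week, lod) == ("m0", 4, 6.0)

    def test_empty_region_rejected(self):
        res = self._results({3: [1.0]}, [10])
        with pytest.raises(ValueError):
            top_snp(res, region="chr9")


class TestEffectSummary:
    def test_printed_chr15_class_means_reproduce_effects(self):
        es = effect_summary_from_means(44.41, 41.17, 39.01)
        assert es.diff_S1_S2_g == pytest.approx(5.40, abs=0.005)
        assert round(es.pct_S1_over_S2, 1) == 13.8
        assert es.diff_S1_H_g == pytest.approx(3.24, abs=0.005)
        assert round(es.pct_S1_over_H, 1) == 7.9

    def test_printed_chr16_class_means_reproduce_percentages(self):
        es = effect_summary_from_means(40.45, 38.15, 36.19)
        assert round(es.pct_S1_over_S2, 1) == 11.8
        assert round(es.pct_S1_over_H, 1) == 6.0

    def test_equal_means_zero_differences(self):
        es = effect_summary_from_means(30.0, 30.0, 30.0)
        assert es.diff_S1_S2_g == 0 and es.pct_S1_over_H == 0

    def test_absent_class_leaves_fields_none(self):
        row = np.array([0] * 8 + [2] * 8, dtype=np.int8)
        y = np.r_[np.full(8, 30.0), np.full(8, 35.0)]
        es = effect_summary(row, y)
        assert es.mean_H is None and es.diff_S1_H_g is None
        assert es.diff_S1_S2_g == pytest.approx(5.0)


class TestNullCalibrationProperty:
    def test_null_pvalues_approximately_uniform(self):
        """No-QTL scan p-values follow U(0,1): pooled KS < 0.05 (seeded)."""
        from ailqtl.evaluation import null_config
        cfg = null_config(seed=42, n_animals=400)
        geno, _, _ = simulate_dataset(cfg)
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(5):
            y = 42 + rng.normal(0, 4, geno.n_animals)
            t = scan_week(geno, y, week=20).table
            pvals.append(t.loc[t["tested"], "p_value"].to_numpy())
        pvals = np.concatenate(pvals)
        assert len(pvals) == 1000
        assert stats.kstest(pvals, "uniform").statistic < 0.05
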
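import math

import numpy as np
import pytest

from exocnv.assoc import (
    CHI2_1_MEDIAN,
    AssociationResult,
    compute_lambda,
    fit_logistic,
    gc_significance_table,
    qq_table,
    scan,
)


def table_to_xy(a, b, c, d):
    """Binary predictor from a 2x2 table: cases a exposed / b unexposed,
    controls c exposed / d unexposed."""
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return x, y


class TestFitLogistic:
    def test_known_two_by_two_table(self):
        # cases 60 exposed / 40 unexposed, controls 40 / 60:
        # beta = ln(60*60/(40*40)) = ln 2.25, Woolf SE = sqrt(sum 1/cell)
        x, y = table_to_xy(60, 40, 40, 60)
        fit = fit_logistic(x, y)
        assert fit.beta == pytest.approx(math.log(2.25), abs=1e-6)
        assert fit.se == pytest.approx(math.sqrt(1 / 60 + 1 / 40 + 1 / 40 + 1 / 60),
                                       abs=1e-6)
        assert fit.p_value == pytest.approx(0.0050, abs=5e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form_mle_on_random_tables(self, seed):
        r = np.random.default_rng(seed)
        a, b, c, d = r.integers(8, 80, size=4)
        x, y = table_to_xy(a, b, c, d)
        fit = fit_logistic(x, y)
        assert fit.beta == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
        assert fit.se == pytest.approx(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d),
                                       abs=1e-6)

    def test_matches_statsmodels_on_continuous_predictor(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0, method="newton",
                                                  tol=1e-12)
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_zero_variance_predictor_not_estimable(self):
        y = np.array([0, 1] * 10, dtype=float)
        fit = fit_logistic(np.full(20, 3.0), y)
        assert not fit.estimable and math.isnan(fit.p_value)

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        fit = fit_logistic(x, y)
        assert not fit.estimable

    def test_separation_check_is_scale_free(self):
        # a predictor with tiny variance must not be mistaken for separation
        rng = np.random.default_rng(4)
        x = 0.05 + 1e-4 * rng.normal(size=400)
        y = rng.integers(0, 2, size=400).astype(float)
        fit = fit_logistic(x, y)
        assert fit.estimable
        assert 0 < fit.p_value <= 1

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.arange(5.0), np.ones(5))

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=150)
        y = (rng.random(150) < 0.5).astype(float)
        f1, f2 = fit_logistic(x, y), fit_logistic(10 * x, y)
        assert f2.beta == pytest.approx(f1.beta / 10, rel=1e-8)
        assert f2.p_value == pytest.approx(f1.p_value, rel=1e-8)


class TestComputeLambda:
    def test_definition_at_the_chi2_median(self):
        stats = np.full(50, CHI2_1_MEDIAN)
        assert compute_lambda(stats) == pytest.approx(1.0, abs=1e-9)

    def test_homogeneous_scaling(self, rng):
        stats = rng.chisquare(1, size=1000)
        assert compute_lambda(2 * stats) == pytest.approx(2 * compute_lambda(stats),
                                                          rel=1e-12)

    def test_too_few_statistics(self):
        with pytest.raises(ValueError, match="at least 10"):
            compute_lambda(np.ones(9))

    def test_null_chi_square_draws_give_unit_lambda(self):
        rng = np.random.default_rng(987)
        stats = rng.normal(size=100_000) ** 2
        assert 0.95 < compute_lambda(stats) < 1.05


class TestQQTable:
    def test_single_point(self):
        table = qq_table([0.5])
        assert table[0, 0] == pytest.approx(-math.log10(0.5))
        assert table[0, 1] == pytest.approx(-math.log10(0.5))

    def test_all_ones_give_zero_observed(self):
        table = qq_table([1.0, 1.0, 1.0])
        assert np.all(table[:, 1] == 0.0)

    def test_zero_p_clamped_to_finite(self):
        table = qq_table([0.0, 0.5])
        assert np.all(np.isfinite(table))

    def test_expected_column_formula(self):
        n = 7
        table = qq_table(np.linspace(0.1, 0.9, n))
        ranks = np.arange(1, n + 1)
        assert table[:, 0] == pytest.approx(-np.log10((ranks - 0.5) / n))

    def test_uniform_p_hug_the_diagonal(self, rng):
        table = qq_table(rng.random(5000))
        bulk = table[table[:, 0] <= 2.0]
        assert np.abs(bulk[:, 1] - bulk[:, 0]).mean() < 0.05

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            qq_table([1.5])


class TestScan:
    def _pcs(self, rows):
        return [(rid, np.asarray(v, dtype=float)) for rid, v in rows]

    def test_ranks_follow_p_values(self, rng):
        y = np.array([0, 1] * 20, dtype=float)
        strong = 1.5 * y + rng.normal(size=40)  # strongly associated, overlapping
        weak = rng.normal(size=40)
        results, report = scan(self._pcs([("weak", weak), ("strong", strong)]),
                               y, H=0, min_regions_for_lambda=2)
        by_id = {r.region_id: r for r in results}
        assert by_id["strong"].rank == 1 and by_id["weak"].rank == 2
        assert report.n_regions == 2

    def test_rank_invariant_under_input_order(self, rng):
        y = np.array([0, 1] * 25, dtype=float)
        rows = [(f"r{i}", rng.normal(size=50)) for i in range(12)]
        fwd, _ = scan(self._pcs(rows), y, 0, min_regions_for_lambda=2)
        rev, _ = scan(self._pcs(rows[::-1]), y, 0, min_regions_for_lambda=2)
        assert {r.region_id: r.rank for r in fwd} == {r.region_id: r.rank for r in rev}

    def test_non_estimable_regions_excluded(self, rng):
        y = np.array([0, 1] * 15, dtype=float)
        rows = [("const", np.ones(30)), ("ok", rng.normal(size=30)),
                ("ok2", rng.normal(size=30))]
        results, report = scan(self._pcs(rows), y, 0, min_regions_for_lambda=2)
        by_id = {r.region_id: r for r in results}
        assert by_id["const"].rank is None
        assert report.n_regions == 2
        assert sorted(r.rank for r in results if r.rank) == [1, 2]

    def test_empty_region_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            scan([], np.array([0.0, 1.0]), 0)

    def test_all_non_estimable_errors(self):
        y = np.array([0, 1] * 5, dtype=float)
        with pytest.raises(ValueError, match="non-estimable"):
            scan(self._pcs([("a", np.ones(10)), ("b", np.zeros(10))]), y, 0)

    def test_wald_chi2_consistent_with_beta_se(self, rng):
        y = np.array([0, 1] * 30, dtype=float)
        results, _ = scan(self._pcs([(f"r{i}", rng.normal(size=60))
                                     for i in range(10)]), y, 0)
        for r in results:
            assert r.wald_chi2 == pytest.approx((r.beta / r.se) ** 2, abs=1e-9)


class TestGCSignificanceTable:
    def _results(self, gcs, ps):
        return [AssociationResult(f"r{i}", 0, 0.0, 1.0, 0.0, p, None, gc)
                for i, (gc, p) in enumerate(zip(gcs, ps))]

    def test_flat_p_gives_equal_bin_fractions(self):
        res = self._results([0.22, 0.27, 0.52, 0.57], [1e-6] * 4)
        _, bins = gc_significance_table(res, p_threshold=1e-4)
        assert np.all(bins[:, 2] == 1.0)

    def test_missing_gc_rows_dropped(self):
        res = self._results([0.3, None, 0.6], [0.5, 0.5, 0.5])
        points, _ = gc_significance_table(res)
        assert points.shape[0] == 2

    def test_empty_input(self):
        points, bins = gc_significance_table([])
        assert points.size == 0 and bins.size == 0

    def test_enrichment_localized_to_one_bin(self):
        gcs = [0.32] * 10 + [0.62] * 10
        ps = [1e-6] * 10 + [0.5] * 10
        _, bins = gc_significance_table(self._results(gcs, ps), p_threshold=1e-4)
        frac = {round(low, 2): f for low, _, f in bins}
        assert frac[0.30] == 1.0
        assert frac[0.60] == 0.0
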
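import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestmap import (
    CovariateStack,
    GridSpec,
    RegionMask,
    compute_weights,
    confidence_band,
    crossvalidate,
    fit_apr_covariate,
    harmonize,
    infer_raw_global,
    rank_statistic,
    state_covariate_means,
)


def stack_of(spec, **grids):
    return CovariateStack(spec=spec, grids={k: np.asarray(v, float) for k, v in grids.items()})


class TestHarmonize:
    def test_identity_on_matching_specs(self, small_spec):
        grid = np.random.default_rng(0).normal(size=small_spec.shape)
        assert np.array_equal(harmonize(grid, small_spec, small_spec), grid)

    def test_extensive_coarsening_conserves_sum(self):
        src = GridSpec(n_rows=8, n_cols=12, lon_min=0, lon_max=12, lat_min=0, lat_max=8)
        dst = GridSpec(n_rows=4, n_cols=6, lon_min=0, lon_max=12, lat_min=0, lat_max=8)
        grid = np.random.default_rng(1).uniform(0, 5, src.shape)
        out = harmonize(grid, src, dst, kind="extensive")
        assert out.sum() == pytest.approx(grid.sum(), rel=1e-9)

    @pytest.mark.parametrize("kind", ["continuous", "categorical"])
    def test_constant_field_stays_constant(self, kind):
        src = GridSpec(n_rows=6, n_cols=9, lon_min=0, lon_max=9, lat_min=0, lat_max=6)
        dst = GridSpec(n_rows=4, n_cols=4, lon_min=0, lon_max=9, lat_min=0, lat_max=6)
        out = harmonize(np.full(src.shape, 3.3), src, dst, kind=kind)
        assert np.allclose(out, 3.3)

    def test_disjoint_extents_rejected(self):
        src = GridSpec(n_rows=4, n_cols=4, lon_min=0, lon_max=4, lat_min=0, lat_max=4)
        dst = GridSpec(n_rows=4, n_cols=4, lon_min=10, lon_max=14, lat_min=0, lat_max=4)
        with pytest.raises(ValueError, match="disjoint"):
            harmonize(np.ones(src.shape), src, dst)


class TestStateMeans:
    def test_uniform_field(self, small_spec, two_region_mask):
        stack = stack_of(small_spec, x=np.full(small_spec.shape, 2.5))
        means = state_covariate_means(stack, two_region_mask)
        assert np.allclose(means["mean"], 2.5)

    def test_matches_bruteforce(self, small_spec, two_region_mask):
        grid = np.random.default_rng(2).normal(size=small_spec.shape)
        grid[0, 0] = np.nan
        means = state_covariate_means(stack_of(small_spec, x=grid), two_region_mask)
        for rid in (0, 1):
            sel = grid[two_region_mask.labels == rid]
            brute = np.nanmean(sel)
            got = means[(means["state"] == rid)]["mean"].iloc[0]
            assert got == pytest.approx(brute)


class TestCovariateFit:
    def test_exact_linear_relation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_apr_covariate(2 * x + 1, x)
        assert fit.alpha == pytest.approx(2.0)
        assert fit.beta == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_constant_response_zero_correlation(self):
        x = np.array([0.0, 1.0, 2.0])
        fit = fit_apr_covariate(np.full(3, 5.0), x)
        assert fit.alpha == pytest.approx(0.0)
        assert fit.r == 0.0

    def test_three_point_closed_form(self):
        fit = fit_apr_covariate(np.array([1.0, 3.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert fit.alpha == pytest.approx(0.5)
        assert fit.beta == pytest.approx(1.0)
        assert fit.r == pytest.approx(0.5)

    def test_too_few_points_skipped(self):
        assert fit_apr_covariate(np.array([1.0, 2.0]), np.array([1.0, 2.0])) is None

    def test_n_frac_counts_complete_states(self):
        apr = np.array([1.0, 2.0, np.nan, 4.0])
        fit = fit_apr_covariate(apr, np.arange(4.0), total_states=48)
        assert fit.n == 3
        assert fit.n_frac == pytest.approx(3 / 48)


class TestConfidenceBand:
    def test_zero_residuals_zero_band(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_apr_covariate(2 * x + 1, x)
        assert confidence_band(fit, np.array([0.0, 10.0])) == pytest.approx([0.0, 0.0])

    def test_minimal_at_mean(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 12)
        y = 1.5 * x + rng.normal(0, 1, 12)
        fit = fit_apr_covariate(y, x)
        grid = np.linspace(-5, 15, 101)
        widths = confidence_band(fit, grid)
        assert grid[np.argmin(widths)] == pytest.approx(fit.x_bar, abs=0.2)

    def test_matches_textbook_formula_four_points(self):
        from scipy import stats

        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        fit = fit_apr_covariate(y, x)
        # independent evaluation of the mean-response band
        n = 4
        xbar = x.mean()
        slope = np.sum((x - xbar) * (y - y.mean())) / np.sum((x - xbar) ** 2)
        inter = y.mean() - slope * xbar
        s2 = np.sum((y - slope * x - inter) ** 2) / (n - 2)
        x0 = 2.7
        expect = stats.t.ppf(0.975, n - 2) * np.sqrt(
            s2 * (1 / n + (x0 - xbar) ** 2 / np.sum((x - xbar) ** 2))
        )
        assert confidence_band(fit, np.array([x0]))[0] == pytest.approx(expect, rel=1e-9)


class TestWeights:
    @staticmethod
    def fit_with(r, name, n=48):
        from pestmap.inference import CovariateFit

        return CovariateFit(
            ai="a", crop="Corn", covariate=name, alpha=1.0, beta=0.0, r=r, n=n,
            n_frac=n / 48, x_bar=0.0, sxx=1.0, resid_var=0.0, slope_se=0.0,
        )

    def test_single_covariate_unit_weight(self):
        ws = compute_weights([self.fit_with(0.4, "x")])
        assert ws.weights == {"x": 1.0}

    def test_normalization_arithmetic(self):
        rs = [0.8, 0.4, 0.2, 0.1, 0.1]
        fits = [self.fit_with(r, f"x{i}") for i, r in enumerate(rs)]
        ws = compute_weights(fits, k=5)
        assert list(ws.weights.values()) == pytest.approx([0.5, 0.25, 0.125, 0.0625, 0.0625])

    def test_equal_n_reduces_to_r_normalization(self):
        rs = [0.9, -0.6, 0.3]
        for n in (10, 48):
            ws = compute_weights([self.fit_with(r, f"x{i}", n=n) for i, r in enumerate(rs)])
            assert list(ws.weights.values()) == pytest.approx(
                [0.9 / 1.8, 0.6 / 1.8, 0.3 / 1.8]
            )

    def test_all_zero_correlation_equal_weights(self):
        log = []
        ws = compute_weights([self.fit_with(0.0, f"x{i}") for i in range(3)], log=log)
        assert list(ws.weights.values()) == pytest.approx([1 / 3] * 3)
        assert "equal weights" in log[0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=12))
    def test_weights_always_normalized(self, rs):
        fits = [self.fit_with(r, f"x{i:02d}") for i, r in enumerate(rs)]
        ws = compute_weights(fits, k=5)
        assert sum(ws.weights.values()) == pytest.approx(1.0)
        assert len(ws.weights) == min(5, len(fits))
        assert all(w >= 0 for w in ws.weights.values())


class TestInferRawGlobal:
    def test_single_covariate_zero_residual_collapses_bounds(self, small_spec):
        x_states = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_apr_covariate(2 * x_states + 1, x_states, covariate="x")
        ws = compute_weights([fit])
        grid = np.random.default_rng(0).uniform(0, 3, small_spec.shape)
        out = infer_raw_global({"x": fit}, ws, stack_of(small_spec, x=grid), np.ones(small_spec.shape, bool))
        assert np.allclose(out.high, 2 * grid + 1, atol=1e-9)
        assert np.allclose(out.high, out.low, atol=1e-9)

    def test_two_covariate_hand_arithmetic_one_cell(self, small_spec):
        rng = np.random.default_rng(8)
        x1s = np.linspace(0, 3, 6)
        y1 = 2 * x1s + 1 + rng.normal(0, 0.2, 6)
        x2s = np.linspace(1, 4, 6)
        y2 = -1 * x2s + 6 + rng.normal(0, 0.2, 6)
        f1 = fit_apr_covariate(y1, x1s, covariate="x1")
        f2 = fit_apr_covariate(y2, x2s, covariate="x2")
        ws = compute_weights([f1, f2])
        g1 = np.full(small_spec.shape, 1.5)
        g2 = np.full(small_spec.shape, 2.0)
        out = infer_raw_global(
            {"x1": f1, "x2": f2}, ws, stack_of(small_spec, x1=g1, x2=g2),
            np.ones(small_spec.shape, bool),
        )
        w1, w2 = ws.weights["x1"], ws.weights["x2"]
        ci1 = confidence_band(f1, np.array([1.5]))[0]
        ci2 = confidence_band(f2, np.array([2.0]))[0]
        expect_h = w1 * (f1.predict(1.5) + ci1) + w2 * (f2.predict(2.0) + ci2)
        expect_l = w1 * (f1.predict(1.5) - ci1) + w2 * (f2.predict(2.0) - ci2)
        assert out.high[0, 0] == pytest.approx(max(expect_h, 0.0), rel=1e-9)
        assert out.low[0, 0] == pytest.approx(max(expect_l, 0.0), rel=1e-9)

    def test_band_identity_before_flooring(self, small_spec):
        rng = np.random.default_rng(9)
        xs = np.linspace(0, 3, 8)
        f1 = fit_apr_covariate(5 + 2 * xs + rng.normal(0, 0.1, 8), xs, covariate="x1")
        ws = compute_weights([f1])
        grid = rng.uniform(0, 3, small_spec.shape)
        out = infer_raw_global({"x1": f1}, ws, stack_of(small_spec, x1=grid), np.ones(small_spec.shape, bool))
        # H - L = 2 * sum_k W_k CI_k >= 0 (no flooring active: surface >> 0)
        expect = 2 * confidence_band(f1, grid)
        assert np.allclose(out.high - out.low, expect, atol=1e-9)

    def test_off_crop_cells_are_nodata(self, small_spec):
        xs = np.linspace(0, 3, 6)
        fit = fit_apr_covariate(2 * xs + 1, xs, covariate="x")
        ws = compute_weights([fit])
        present = np.zeros(small_spec.shape, bool)
        present[0, 0] = True
        out = infer_raw_global(
            {"x": fit}, ws, stack_of(small_spec, x=np.ones(small_spec.shape)), present
        )
        assert np.isfinite(out.high[0, 0])
        assert np.isnan(out.high[1, 1])

    def test_missing_covariate_renormalized_cellwise(self, small_spec):
        xs = np.linspace(0, 3, 8)
        f1 = fit_apr_covariate(2 * xs + 1, xs, covariate="x1")
        f2 = fit_apr_covariate(3 * xs + 2, xs, covariate="x2")
        ws = compute_weights([f1, f2])
        g1 = np.full(small_spec.shape, 1.0)
        g2 = np.full(small_spec.shape, 1.0)
        g2[0, 0] = np.nan
        log = []
        out = infer_raw_global(
            {"x1": f1, "x2": f2}, ws, stack_of(small_spec, x1=g1, x2=g2),
            np.ones(small_spec.shape, bool), log=log,
        )
        # cell (0,0) uses only x1: value = 2*1+1 = 3
        assert out.high[0, 0] == pytest.approx(3.0)
        assert log and "renormalized" in log[0]


class TestRankStatistic:
    @pytest.mark.parametrize(
        "r,nrmse,expected",
        [(0.701, 10.33, 40.2), (0.775, 9.10, 31.6), (0.842, 8.83, 24.6), (-0.177, 17.66, 100.0)],
    )
    def test_reported_inference_quality_ranks(self, r, nrmse, expected):
        assert round(rank_statistic(r, nrmse), 1) == expected


class TestCrossValidation:
    def test_perfect_linear_surface_any_split(self, exact_world):
        bundle = exact_world
        ai, crop = bundle.config.ais[0], bundle.config.crops[0]
        cov = bundle.true_coefficients.query("ai == @ai and crop == @crop")["covariate"].iloc[0]
        stack = CovariateStack(
            spec=bundle.grid_spec, grids={cov: bundle.covariates.grids[cov]}
        )
        for frac in (0.07, 0.2, 0.5):
            cv = crossvalidate(
                bundle.true_apr[(ai, crop)], stack, calib_frac=frac, n_bins=120, seed=3
            )
            assert cv.r == pytest.approx(1.0, abs=1e-9)
            assert cv.nrmse == pytest.approx(0.0, abs=1e-9)
            assert cv.rank == pytest.approx(0.0, abs=1e-9)

    def test_weighted_combination_not_worse_than_worst_single(self, noisy_world):
        bundle = noisy_world
        ai, crop = bundle.config.ais[0], bundle.config.crops[0]
        truth = bundle.true_apr[(ai, crop)] + np.random.default_rng(1).normal(
            0, 0.05 * np.nanmean(bundle.true_apr[(ai, crop)]), bundle.grid_spec.shape
        )
        cv_all = crossvalidate(truth, bundle.covariates, calib_frac=0.3, n_bins=150, seed=2)
        singles = []
        for name in list(bundle.covariates.grids)[:8]:
            sub = CovariateStack(
                spec=bundle.grid_spec, grids={name: bundle.covariates.grids[name]}
            )
            singles.append(crossvalidate(truth, sub, calib_frac=0.3, n_bins=150, seed=2).nrmse)
        assert cv_all.nrmse <= max(singles) + 1e-9

    def test_empty_validation_set_rejected(self, exact_world):
        bundle = exact_world
        key = (bundle.config.ais[0], bundle.config.crops[0])
        with pytest.raises(ValueError, match="validation"):
            crossvalidate(bundle.true_apr[key], bundle.covariates, calib_frac=1.0, n_bins=50)

    def test_seeded_reproducibility(self, exact_world):
        bundle = exact_world
        key = (bundle.config.ais[0], bundle.config.crops[0])
        a = crossvalidate(bundle.true_apr[key], bundle.covariates, n_bins=100, seed=5)
        b = crossvalidate(bundle.true_apr[key], bundle.covariates, n_bins=100, seed=5)
        assert (a.r, a.nrmse, a.rank) == (b.r, b.nrmse, b.rank)
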
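"""Trend regression, net change, uncertainty, and the endpoint baseline."""

import numpy as np
import pytest
from scipy import stats

from lcluc import (
    LandChangeTrendModel,
    Transition,
    block_fractions,
    endpoint_change,
    generate_series,
    linear_fraction_cube,
    merge_classes,
    net_change,
    ols_trend,
    trend_surface,
)

from conftest import make_scenario

YEARS = tuple(range(2001, 2014))


class TestOlsTrend:
    def test_constant_series_not_significant(self):
        fit = ols_trend([0.3] * 13, YEARS)
        assert fit.slope == 0.0
        assert np.isnan(fit.p_value)
        nc = net_change(fit)
        assert not nc.significant and nc.masked_net_area == 0.0

    def test_noiseless_line_exact(self):
        y = 0.10 + 0.02 * np.arange(13)
        fit = ols_trend(y, YEARS)
        assert fit.slope == pytest.approx(0.02, abs=1e-12)
        assert fit.p_value == 0.0
        assert net_change(fit).significant

    def test_matches_independent_ols_oracle(self, rng):
        # 1,000 random series vs scipy.stats.linregress (normal equations +
        # two-sided t test), agreement to 1e-10
        t = np.arange(13, dtype=float)
        for _ in range(1000):
            y = rng.normal(0.3, 0.05, size=13) + rng.normal(0, 0.01) * t
            fit = ols_trend(y, YEARS)
            ref = stats.linregress(t, y)
            assert fit.slope == pytest.approx(ref.slope, abs=1e-10)
            assert fit.intercept == pytest.approx(ref.intercept, abs=1e-10)
            assert fit.se_slope == pytest.approx(ref.stderr, abs=1e-10)
            assert fit.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            ols_trend([0.1, 0.2], (2001, 2002))
        with pytest.raises(ValueError, match="non-finite"):
            ols_trend([0.1, np.nan, 0.3], (2001, 2002, 2003))
        with pytest.raises(ValueError, match="increasing"):
            ols_trend([0.1, 0.2, 0.3], (2003, 2002, 2001))


class TestNetChange:
    def test_arithmetic(self):
        fit = ols_trend(0.10 + 0.02 * np.arange(13), YEARS)
        nc = net_change(fit, interval=13, alpha=0.1, cell_area=6.25)
        assert nc.net_fraction == pytest.approx(0.26)
        assert nc.net_area == pytest.approx(1.625)

    def test_sd_area_scaling(self):
        from lcluc.trend import TrendFit

        fit = TrendFit(slope=0.02, intercept=0.1, se_slope=0.005, p_value=0.01, n_years=13)
        assert net_change(fit).sd_area == pytest.approx(0.40625)  # 0.005 x 13 x 6.25

    def test_nonsignificant_masked_to_zero(self):
        from lcluc.trend import TrendFit

        fit = TrendFit(slope=0.02, intercept=0.1, se_slope=0.02, p_value=0.2, n_years=13)
        nc = net_change(fit)
        assert not nc.significant
        assert nc.masked_net_area == 0.0
        assert nc.net_area == pytest.approx(1.625)  # raw fit retained

    def test_validation(self):
        fit = ols_trend([0.1, 0.2, 0.3], (1, 2, 3))
        with pytest.raises(ValueError, match="interval"):
            net_change(fit, interval=0)
        with pytest.raises(ValueError, match="cell_area"):
            net_change(fit, cell_area=-1)


class TestTrendSurface:
    def test_null_scenario_all_nonsignificant(self):
        series, _ = generate_series(make_scenario(grid=(50, 50)))
        trend = trend_surface(block_fractions(series))
        for name in trend.class_names:
            assert not trend.significant[name].any()

    def test_type_i_error_under_categorical_noise(self):
        # zero designed slopes + confusion-flip noise: cell fractions are iid
        # multinomial proportions across years, close enough to Gaussian at
        # 100 px/cell for the t test to hold its nominal size
        grid = (120, 120)
        cfg = make_scenario(
            grid=grid,
            background={"GRAS": 0.3, "AGRI": 0.3, "URBN": 0.2, "BARE": 0.2},
            seed=31,
        )
        series, _ = generate_series(cfg)
        from lcluc import apply_noise

        noisy = apply_noise(series, 0.1, seed=32)
        trend = trend_surface(block_fractions(noisy), alpha=0.1)
        sig = np.array([trend.significant[c] for c in trend.class_names])
        defined = np.isfinite(np.array([trend.p_value[c] for c in trend.class_names]))
        rate = sig.sum() / defined.sum()
        assert defined.sum() >= 2000
        assert 0.08 <= rate <= 0.12

    def test_designed_slope_recovery_over_seeds(self):
        # +0.01/yr cropland gain under categorical noise: region-mean slope
        # across seeds within 2 Monte-Carlo SE of the design
        est = []
        for seed in range(50):
            cfg = make_scenario(
                grid=(50, 50),
                transitions=[Transition("all", "GRAS", "AGRI", 0.01, "random")],
                noise_rate=0.05,
                seed=seed,
            )
            series, truth = generate_series(cfg)
            from lcluc import apply_noise

            noisy = apply_noise(series, cfg.noise_rate, seed=seed + 1000)
            trend = trend_surface(block_fractions(noisy), classes=("AGRI",))
            est.append(trend.slope["AGRI"].mean())
        est = np.array(est)
        # noise inflows from 14 other classes add a small constant level, not
        # a trend; the designed slope is attenuated by (1 - noise_rate)
        design = 0.01 * 0.95
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - design) < 2 * mc_se + 1e-4

    def test_cross_class_slope_cancellation(self):
        cfg = make_scenario(
            grid=(60, 60),
            transitions=[Transition("all", "GRAS", "AGRI", 0.008, "random")],
            seed=11,
        )
        series, _ = generate_series(cfg)
        from lcluc import apply_noise

        noisy = apply_noise(series, 0.1, seed=12)
        trend = trend_surface(block_fractions(merge_classes(noisy)))
        total = np.zeros(trend.cell_shape)
        for name in trend.class_names:
            total += trend.slope[name]
        np.testing.assert_allclose(total, 0.0, atol=1e-9)

    def test_missing_year_voids_cell(self, legend):
        from lcluc import LandCoverSeries

        labels = np.full((13, 20, 10), legend.code("GRAS"), dtype=np.int64)
        labels[6, :10, :] = legend.nodata_code
        series = LandCoverSeries(years=YEARS, labels=labels, legend=legend)
        trend = trend_surface(block_fractions(series), classes=("GRAS",))
        assert np.isnan(trend.slope["GRAS"][0, 0])
        assert np.isfinite(trend.slope["GRAS"][1, 0])

    def test_class_validation(self, gras_to_agri_series):
        series, _ = gras_to_agri_series
        cube = block_fractions(series)
        with pytest.raises(ValueError, match="not in cube"):
            trend_surface(cube, classes=("NOPE",))


class TestEndpointChange:
    def test_noiseless_line_discrepancy_with_regression(self):
        # 13 annual maps span 12 inter-year steps: endpoint difference gives
        # slope x 12, the regression net change uses the x13 convention
        cube, _ = linear_fraction_cube(1, slope=0.02, noise_sd=0.0, seed=0)
        ep = endpoint_change(cube)
        assert ep[0, 0, 0] == pytest.approx(0.24, abs=1e-12)
        trend = trend_surface(cube, interval=13)
        assert trend.net_fraction("AGRI")[0, 0] == pytest.approx(0.26, abs=1e-12)

    def test_identical_endpoints_give_zero(self, gras_to_agri_series):
        series, _ = gras_to_agri_series
        labels = series.labels.copy()
        labels[-1] = labels[0]
        cube = block_fractions(series.with_labels(labels))
        assert np.nanmax(np.abs(endpoint_change(cube))) == 0.0

    def test_single_year_rejected(self, legend):
        from lcluc import LandCoverSeries

        labels = np.full((1, 10, 10), legend.code("GRAS"), dtype=np.int64)
        cube = block_fractions(LandCoverSeries(years=(2001,), labels=labels, legend=legend))
        with pytest.raises(ValueError, match="at least 2"):
            endpoint_change(cube)

    def test_regression_beats_endpoint_under_final_year_shock(self):
        # a +0.10 anomaly confined to the last year: the regression estimate
        # dilutes it by (t_last - mean t)/Sxx x interval, endpoint eats it whole
        cube, designed = linear_fraction_cube(1000, slope=0.01, noise_sd=0.03, seed=21)
        cube.fractions[:, :, -1, 0] += 0.10
        cube.fractions[:, :, -1, 1] -= 0.10
        trend = trend_surface(cube, interval=13)
        reg_err = np.abs(trend.net_fraction("AGRI") - designed)
        ep_err = np.abs(endpoint_change(cube)[..., 0] - designed)
        assert reg_err.mean() < ep_err.mean()


class TestSdCoverage:
    def test_one_sd_interval_has_t11_coverage(self):
        # with Gaussian noise, (slope_hat - slope)/se ~ t(11); +-1 SD of the
        # net change should cover the design for P(|t11|<1) ~ 66% of cells
        cube, designed = linear_fraction_cube(5000, slope=0.01, noise_sd=0.03, seed=5)
        trend = trend_surface(cube, interval=13)
        err = np.abs(trend.net_fraction("AGRI") - designed)
        sd = trend.sd_area["AGRI"] / trend.cell_area  # back to fraction units
        coverage = (err <= sd).mean()
        expected = 2 * stats.t.cdf(1, df=11) - 1
        assert coverage == pytest.approx(expected, abs=0.03)


class TestModelResults:
    def test_from_series_full_pipeline(self, gras_to_agri_series):
        series, truth = gras_to_agri_series
        res = LandChangeTrendModel.from_series(series).fit()
        assert res.trend.class_names == series.legend.analysis_set
        df = res.summary_frame()
        agri_net = float(df.loc[df["class"] == "AGRI", "net_km2"].iloc[0])
        assert agri_net == pytest.approx(truth.region_net_area[("all", "AGRI")], rel=0.05)
        assert "AGRI" in res.summary()

    def test_interval_defaults_to_span_length(self, gras_to_agri_series):
        series, _ = gras_to_agri_series
        model = LandChangeTrendModel.from_series(series)
        assert model.interval == 13.0
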
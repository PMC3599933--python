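import numpy as np
import pandas as pd
import pytest

from dlnmeta import (
    BasisSpec,
    PipelineConfig,
    RegionSeries,
    SimConfig,
    crosspred,
    fit_first_stage,
    fit_moving_average_model,
    min_mortality_temperature,
    predict_reduced,
    pooled_reduced_fit,
    reduce_fit,
    reduction_matrix,
    run_two_stage,
    simulate_regions,
)
from dlnmeta.reduction import SummaryCurve
from dlnmeta.twostage import _confounder_design, build_specs


def small_sim(seed=0, m=2, N=900, dispersion=1.0, eta_sd=0.0, eta_seed=99):
    var_spec = BasisSpec("bspline", degree=2, internal_knots=(8.0, 15.0),
                         boundary_knots=(-6.0, 28.0), intercept=False, center=17.0)
    lag_spec = BasisSpec("natural_cubic", internal_knots=(1.0, 3.0),
                         boundary_knots=(0.0, 7.0), intercept=True)
    dim = var_spec.dimension() * lag_spec.dimension()
    eta = np.zeros(dim)
    if eta_sd > 0:
        eta = np.random.default_rng(eta_seed).normal(0, eta_sd, dim)
    return SimConfig(m=m, N=N, var_spec=var_spec, lag_spec=lag_spec, eta_true=eta,
                     L=7, dispersion=dispersion, seed=seed)


class TestRegionSeries:
    def test_validation(self):
        dates = pd.date_range("2000-01-01", periods=5)
        with pytest.raises(ValueError, match="vectors"):
            RegionSeries("r", dates, np.zeros(4, dtype=int), np.zeros(5))
        with pytest.raises(ValueError, match="consecutive"):
            RegionSeries("r", dates[[0, 1, 2, 4]], np.zeros(4, dtype=int), np.zeros(4))
        with pytest.raises(ValueError, match="non-negative"):
            RegionSeries("r", dates, np.array([1, -1, 0, 0, 0]), np.zeros(5))


class TestConfounderDesign:
    def test_time_spline_df_10_per_year_14_years(self):
        n = 5113  # 14 years of daily data
        dates = pd.date_range("1993-01-01", periods=n)
        s = RegionSeries("r", dates, np.ones(n, dtype=int), np.zeros(n))
        x, names = _confounder_design(s, PipelineConfig(df_per_year=10, day_of_week=True))
        n_time = sum(1 for nm in names if nm.startswith("time_s"))
        assert n_time == 140
        assert x.shape[1] == 1 + 140 + 6  # intercept + trend + day-of-week

    def test_day_of_week_monday_baseline(self):
        dates = pd.date_range("2024-01-01", periods=14)  # starts a Monday
        s = RegionSeries("r", dates, np.ones(14, dtype=int), np.zeros(14))
        x, names = _confounder_design(s, PipelineConfig(df_per_year=0, day_of_week=True))
        dow_cols = x[:, [i for i, nm in enumerate(names) if nm.startswith("dow_")]]
        assert np.all(dow_cols[0] == 0)  # Monday row maps to the baseline
        assert dow_cols.sum(axis=1).max() == 1


class TestFirstStage:
    def test_main_model_has_20_coefficients(self):
        cfg_sim = SimConfig(m=1, N=1200, seed=3, dispersion=1.2)
        regions, _ = simulate_regions(cfg_sim)
        cfg = PipelineConfig(df_per_year=7)
        fit = fit_first_stage(regions[0], cfg)
        assert fit.eta.size == 20
        assert fit.vcov.shape == (20, 20)
        assert fit.dispersion > 0
        assert fit.n_used == 1200 - 21

    def test_eta_recovery_no_confounding(self):
        # simulate with a known surface and no seasonal terms; the fitted
        # cross-basis coefficients must sit within 3 SEs of truth
        sim = small_sim(seed=5, m=1, N=3000, eta_sd=0.04)
        sim = SimConfig(**{**sim.__dict__, "season_amplitude": 0.0})
        regions, truth = simulate_regions(sim)
        cfg = PipelineConfig(L=7, df_per_year=0, day_of_week=False,
                             var_boundary=sim.var_spec.boundary_knots,
                             var_knots=sim.var_spec.internal_knots,
                             lag_knots=sim.lag_spec.internal_knots, lag_nknots=2)
        fit = fit_first_stage(regions[0], cfg, sim.var_spec, sim.lag_spec)
        se = np.sqrt(np.diag(fit.vcov))
        z = (fit.eta - truth.eta_regions["region01"]) / se
        assert np.all(np.abs(z) < 3.5)

    def test_all_missing_exposure_raises(self):
        dates = pd.date_range("2000-01-01", periods=100)
        s = RegionSeries("bad", dates, np.ones(100, dtype=int), np.full(100, np.nan))
        with pytest.raises(ValueError, match="bad"):
            fit_first_stage(s, PipelineConfig(L=7, df_per_year=0))


@pytest.fixture(scope="module")
def fitted():
    cfg_sim = small_sim(seed=2, m=1, N=1500, eta_sd=0.04, eta_seed=4)
    regions, _ = simulate_regions(cfg_sim)
    cfg = PipelineConfig(L=7, df_per_year=4, day_of_week=True, var_boundary=(-6.0, 28.0))
    return fit_first_stage(regions[0], cfg, cfg_sim.var_spec, cfg_sim.lag_spec)


class TestCrossPred:

    def test_zero_at_reference(self, fitted):
        cp = crosspred(fitted, np.array([17.0]), np.arange(8), cen=17.0)
        assert np.allclose(cp.matfit, 0.0, atol=1e-12)
        assert np.allclose(cp.matse, 0.0, atol=1e-12)

    def test_cumfit_equals_overall_reduction(self, fitted):
        grid = np.linspace(-5, 27, 40)
        cp = crosspred(fitted, grid, np.arange(8), cen=17.0)
        rf = reduce_fit(fitted, "overall", center=17.0)
        cur = predict_reduced(rf, grid, cen=17.0)
        assert np.allclose(cur.fit, cp.cumfit, atol=1e-10)
        assert np.allclose(cur.se, cp.cumse, atol=1e-10)

    def test_surface_shape_recovery(self):
        # truth: immediate effect for high exposure, delayed for low; the
        # fitted surface must reproduce that qualitative pattern
        var_spec = BasisSpec("bspline", degree=2, internal_knots=(8.0, 15.0),
                             boundary_knots=(-6.0, 28.0))
        lag_spec = BasisSpec("natural_cubic", internal_knots=(1.0, 3.0),
                             boundary_knots=(0.0, 7.0), intercept=True)
        # build eta from a closed-form surface f(x, l) by least squares
        from dlnmeta import build_crossbasis, make_basis

        xg = np.linspace(-6, 28, 60)
        lg = np.arange(8.0)
        z = make_basis(xg, var_spec).values
        c = make_basis(lg, lag_spec).values
        heat = np.maximum(xg - 20, 0) / 8.0
        cold = np.maximum(8 - xg, 0) / 14.0
        f = (heat[:, None] * np.exp(-lg / 1.0)[None, :] * 0.4
             + cold[:, None] * (np.exp(-((lg - 4) ** 2) / 6.0))[None, :] * 0.25)
        a = np.kron(c, z)
        eta = np.linalg.lstsq(a, f.T.ravel(), rcond=None)[0]
        sim = SimConfig(m=1, N=4000, var_spec=var_spec, lag_spec=lag_spec,
                        eta_true=eta, L=7, seed=21, baseline_log_mean=np.log(80))
        regions, _ = simulate_regions(sim)
        cfg = PipelineConfig(L=7, df_per_year=4, var_boundary=(-6.0, 28.0))
        fit = fit_first_stage(regions[0], cfg, var_spec, lag_spec)
        cp = crosspred(fit, np.array([0.0, 24.0]), lg, cen=17.0)
        heat_row, cold_row = cp.matfit[1], cp.matfit[0]
        assert heat_row[0] > heat_row[5]  # heat effect concentrated at lag 0
        assert cold_row[4] > cold_row[0]  # cold effect delayed


class TestRunTwoStage:
    def test_requires_two_regions(self):
        cfg_sim = small_sim(seed=1, m=1)
        regions, _ = simulate_regions(cfg_sim)
        with pytest.raises(ValueError):
            run_two_stage(regions, PipelineConfig(L=7))

    def test_two_identical_regions_degenerate_pooling(self):
        cfg_sim = small_sim(seed=8, m=1, N=1200, eta_sd=0.03, eta_seed=6)
        regions, _ = simulate_regions(cfg_sim)
        twin = RegionSeries("twin", regions[0].dates, regions[0].deaths.copy(),
                            regions[0].temperature.copy(), latitude=51.0)
        cfg = PipelineConfig(L=7, df_per_year=4, lag_nknots=2, summary_values=(0.0, 24.0),
                             meta_method="fixed")
        res = run_two_stage([regions[0], twin], cfg)
        assert res.heterogeneity["overall"].Q == pytest.approx(0.0, abs=1e-6)
        # pooled curve equals each region's own curve
        rf = res.reduced["overall"]["region01"]
        own = predict_reduced(rf, res.grid_x, cen=17.0)
        assert np.allclose(res.pooled["overall"].fit, own.fit, atol=1e-8)

    def test_pooled_rr_at_reference_is_one(self):
        cfg_sim = small_sim(seed=9, m=3, N=900)
        regions, _ = simulate_regions(cfg_sim)
        cfg = PipelineConfig(L=7, df_per_year=4, lag_nknots=2, center=17.0,
                             meta_method="fixed", summary_values=())
        res = run_two_stage(regions, cfg)
        i = np.argmin(np.abs(res.grid_x - 17.0))
        cur = res.pooled["overall"]
        assert abs(res.grid_x[i] - 17.0) < 1e-9
        assert cur.fit[i] == pytest.approx(0.0, abs=1e-12)
        assert cur.se[i] == pytest.approx(0.0, abs=1e-12)

    def test_meta_regression_wald_and_prediction(self):
        cfg_sim = small_sim(seed=10, m=6, N=900, eta_sd=0.03, eta_seed=13)
        regions, _ = simulate_regions(cfg_sim)
        cfg = PipelineConfig(L=7, df_per_year=4, lag_nknots=2, meta_method="ml",
                             meta_variables=("latitude",), summary_values=())
        res = run_two_stage(regions, cfg)
        assert "overall" in res.wald
        assert 0.0 <= res.wald["overall"]["p"] <= 1.0
        lat = [s.latitude for s in regions]
        rf = pooled_reduced_fit(res, "overall", u_new=[1.0, np.quantile(lat, 0.25)])
        cur = predict_reduced(rf, res.grid_x, cen=17.0)
        assert np.all(np.isfinite(cur.fit))


class TestMinMortalityTemperature:
    def test_symmetric_u_shape(self):
        grid = np.round(np.arange(100, 301) * 0.1, 10)
        fit = (grid - 20.0) ** 2 * 0.01
        curve = SummaryCurve(grid=grid, fit=fit, se=np.zeros_like(fit))
        assert min_mortality_temperature(curve) == pytest.approx(20.0, abs=0.1)

    def test_monotone_curve_returns_boundary_with_warning(self):
        grid = np.linspace(0, 30, 301)
        curve = SummaryCurve(grid=grid, fit=0.02 * grid, se=np.zeros_like(grid))
        with pytest.warns(UserWarning):
            assert min_mortality_temperature(curve) == pytest.approx(0.0)

    def test_tie_broken_toward_reference(self):
        grid = np.array([0.0, 10.0, 20.0])
        curve = SummaryCurve(grid=grid, fit=np.array([0.0, 1.0, 0.0]), se=np.zeros(3))
        assert min_mortality_temperature(curve, reference=18.0) == 20.0


class TestMovingAverage:
    def test_reduction_matrix_is_scaled_identity(self, main_var_spec):
        rm = reduction_matrix("overall", None, main_var_spec, BasisSpec("constant"), 3)
        assert np.allclose(rm.M, 4.0 * np.eye(4))

    def test_moving_average_model_has_4_parameters(self):
        cfg_sim = SimConfig(m=1, N=1000, seed=14, dispersion=1.1)
        regions, _ = simulate_regions(cfg_sim)
        cfg = PipelineConfig(df_per_year=5)
        fit = fit_moving_average_model(regions[0], window=3, config=cfg)
        assert fit.eta.size == 4  # v_x * v_l = 4 x 1
        rf = reduce_fit(fit, "overall", center=17.0)
        assert np.allclose(rf.theta, 4.0 * fit.eta)

    def test_dispersion_inflates_ses_not_point_estimates(self):
        fits = []
        for disp in (1.0, 3.0):
            sim = small_sim(seed=16, m=1, N=2500, eta_sd=0.03, eta_seed=15, dispersion=disp)
            regions, _ = simulate_regions(sim)
            cfg = PipelineConfig(L=7, df_per_year=0, day_of_week=False,
                                 var_boundary=(-6.0, 28.0))
            fits.append(fit_first_stage(regions[0], cfg, sim.var_spec, sim.lag_spec))
        se0 = np.sqrt(np.diag(fits[0].vcov))
        se1 = np.sqrt(np.diag(fits[1].vcov))
        assert fits[1].dispersion > fits[0].dispersion
        assert np.median(se1 / se0) > 1.3
        # same seed, same exposure -> point estimates stay close (within joint SE)
        z = np.abs(fits[1].eta - fits[0].eta) / np.sqrt(se0**2 + se1**2)
        assert np.all(z < 4)
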
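"""Accelerated-failure-time models: likelihood, fitting, LOO, derived quantities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tgisurv import AFTParams, CohortConfig, SamplerConfig, generate_cohort
from tgisurv.aft import (
    EvaluationError,
    acceleration_factor,
    fit_aft,
    forward_select,
    location_parameter,
    log_likelihood,
    median_survival,
    psis_loo,
    simulate_population_curve,
    survivor_function,
)
from conftest import make_records

LIGHT = SamplerConfig(chains=2, warmup=800, iters=300, thin=4, seed=0)


def frame(n, **cols):
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="patient_id"))


class TestLocationParameter:
    def test_weibull_intercept_only(self):
        p = AFTParams(dist="weibull", theta0=3.80, sigma_ln=None, alpha=2.33)
        lam = location_parameter(p, frame(1))
        assert lam[0] == pytest.approx(44.70, abs=0.05)

    def test_lognormal_intercept_reproduces_km_median(self):
        p = AFTParams(dist="lognormal", theta0=1.25, sigma_ln=0.544)
        mu = location_parameter(p, frame(1))
        assert mu[0] == pytest.approx(3.4903, abs=1e-3)
        assert np.exp(mu[0]) == pytest.approx(32.8, abs=0.1)  # ~33-week cohort median

    def test_zero_coefficients_ignore_covariates(self):
        p = AFTParams(dist="lognormal", theta0=1.25, coeffs={"TS0": 0.0}, sigma_ln=0.5)
        mu = location_parameter(p, frame(3, TS0=[10.0, 100.0, 350.0]))
        assert np.allclose(mu, mu[0])

    def test_negative_lognormal_location_flagged(self):
        p = AFTParams(dist="lognormal", theta0=1.25, coeffs={"X": -10.0}, sigma_ln=0.5)
        with pytest.raises(EvaluationError, match="patients"):
            location_parameter(p, frame(2, X=[0.0, 5.0]))


class TestLogLikelihood:
    def test_weibull_censored_at_scale_contributes_minus_one(self):
        p = AFTParams(dist="weibull", theta0=np.log(40.0), sigma_ln=None, alpha=2.0)
        rec = make_records([40.0], [0])
        assert log_likelihood(p, frame(1), rec)[0] == pytest.approx(-1.0)

    def test_censoring_near_zero_contributes_nothing(self):
        p = AFTParams(dist="lognormal", theta0=1.25, sigma_ln=0.5)
        rec = make_records([1e-9], [0])
        assert log_likelihood(p, frame(1), rec)[0] == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_event_density_matches_cdf_derivative(self):
        p = AFTParams(dist="lognormal", theta0=1.25, sigma_ln=0.544)
        t, h = 25.0, 1e-4
        dens = np.exp(log_likelihood(p, frame(1), make_records([t], [1]))[0])
        mu = np.exp(1.25)
        cdf = lambda u: stats.norm.cdf((np.log(u) - mu) / 0.544)
        assert dens == pytest.approx((cdf(t + h) - cdf(t - h)) / (2 * h), rel=1e-5)


class TestAccelerationFactor:
    # printed effect sizes from the studied cohort
    @pytest.mark.parametrize(
        "coef, delta, expected",
        [
            (1.07, 1.0, 2.92),     # early shrinkage, per unit fraction
            (-0.001, 10.0, 0.990), # baseline tumour size, per cm
            (0.0079, 10.0, 1.08),  # albumin, per 10 G/l
            (0.762, 1.0, 2.14),    # body surface area, per m2 (Weibull fit)
            (0.0, 5.0, 1.0),
        ],
    )
    def test_reproduces_printed_ratios(self, coef, delta, expected):
        p = AFTParams(dist="lognormal", theta0=1.25, coeffs={"x": coef}, sigma_ln=0.5)
        assert acceleration_factor(p, "x", delta) == pytest.approx(expected, abs=0.005)

    def test_reciprocal_property(self):
        p = AFTParams(dist="weibull", theta0=3.8, coeffs={"x": 0.3}, sigma_ln=None, alpha=2.0)
        assert acceleration_factor(p, "x", 2.0) * acceleration_factor(p, "x", -2.0) == pytest.approx(1.0)

    def test_unknown_variable_rejected(self):
        p = AFTParams(dist="lognormal", theta0=1.0, sigma_ln=0.5)
        with pytest.raises(EvaluationError):
            acceleration_factor(p, "nope", 1.0)


class TestMedianSurvival:
    def test_exponential_special_case(self):
        p = AFTParams(dist="weibull", theta0=np.log(20.0), sigma_ln=None, alpha=1.0)
        assert median_survival(p, frame(1))[0] == pytest.approx(20.0 * np.log(2.0))

    def test_weibull_cohort_values(self):
        p = AFTParams(dist="weibull", theta0=3.80, sigma_ln=None, alpha=2.33)
        assert median_survival(p, frame(1))[0] == pytest.approx(38.2, abs=0.1)

    def test_lognormal_typical(self):
        p = AFTParams(dist="lognormal", theta0=1.25, sigma_ln=0.544)
        assert median_survival(p, frame(1))[0] == pytest.approx(32.8, abs=0.1)


class TestFitAft:
    def test_no_censoring_matches_least_squares(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(0, 1, n)
        logt = 3.0 + 0.4 * x + 0.5 * rng.standard_normal(n)
        rec = make_records(np.exp(logt), np.ones(n))
        cov = frame(n, X=x)
        fit = fit_aft(rec, cov, "lognormal", ["X"], LIGHT)
        s = fit.summary()
        # OLS of log T on centered x
        xc = x - np.median(x)
        beta_ols = np.polyfit(xc, logt, 1)
        assert s.loc["theta_X", "mean"] == pytest.approx(beta_ols[0], abs=3 * s.loc["theta_X", "sd"])
        assert np.exp(s.loc["theta0", "mean"]) == pytest.approx(beta_ols[1], abs=0.05)

    def test_exponential_data_recovers_unit_shape(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(30.0, size=500)
        rec = make_records(t, np.ones(500))
        fit = fit_aft(rec, frame(500), "weibull", [], LIGHT)
        s = fit.summary()
        assert s.loc["alpha", "mean"] == pytest.approx(1.0, abs=3 * s.loc["alpha", "sd"] + 0.05)
        lam = np.exp(s.loc["theta0", "mean"])
        assert lam == pytest.approx(t.mean(), rel=0.1)  # exponential MLE of the scale

    def test_requires_at_least_one_event(self):
        rec = make_records([5.0, 6.0], [0, 0])
        with pytest.raises(EvaluationError):
            fit_aft(rec, frame(2), "lognormal", [], LIGHT)

    def test_posterior_concentrates_on_mean_log_time(self):
        # no covariates, no censoring: mu -> sample mean of log T as n grows
        rng = np.random.default_rng(7)
        n = 2000
        logt = np.exp(1.25) + 0.544 * rng.standard_normal(n)
        rec = make_records(np.exp(logt), np.ones(n))
        fit = fit_aft(rec, frame(n), "lognormal", [], LIGHT)
        mu_hat = np.exp(fit.summary().loc["theta0", "mean"])
        assert abs(mu_hat - logt.mean()) / logt.mean() < 0.02

    def test_time_unit_change_leaves_af_invariant(self):
        cohort = generate_cohort(CohortConfig(n_patients=200, seed=21))
        cov = cohort.covariates.copy()
        cov["PTR_wk2"] = cohort.truth["ptr_wk2_true"]
        rec_w = cohort.survival
        rec_d = rec_w.assign(time_weeks=rec_w["time_weeks"] * 7.0)
        fit_w = fit_aft(rec_w, cov, "weibull", ["TS0"], LIGHT)
        fit_d = fit_aft(rec_d, cov, "weibull", ["TS0"], LIGHT)
        af_w = acceleration_factor(fit_w.posterior_mean_params, "TS0", 10.0)
        af_d = acceleration_factor(fit_d.posterior_mean_params, "TS0", 10.0)
        assert af_d == pytest.approx(af_w, rel=0.03)
        lam_w = np.exp(fit_w.summary().loc["theta0", "mean"])
        lam_d = np.exp(fit_d.summary().loc["theta0", "mean"])
        assert lam_d / lam_w == pytest.approx(7.0, rel=0.03)


class TestPsisLoo:
    def test_identical_fits_have_equal_elpd(self):
        rng = np.random.default_rng(8)
        rec = make_records(rng.lognormal(3.0, 0.5, 60), np.ones(60))
        f1 = fit_aft(rec, frame(60), "lognormal", [], LIGHT)
        f2 = fit_aft(rec, frame(60), "lognormal", [], LIGHT)
        assert psis_loo(f1)[0] == pytest.approx(psis_loo(f2)[0], abs=1e-9)

    def test_well_specified_model_has_small_pareto_k(self):
        rng = np.random.default_rng(9)
        rec = make_records(rng.lognormal(3.0, 0.5, 150), np.ones(150))
        fit = fit_aft(rec, frame(150), "lognormal", [], LIGHT)
        _, _, k = psis_loo(fit)
        assert np.mean(k < 0.7) > 0.9

    def test_too_few_draws_rejected(self):
        rng = np.random.default_rng(10)
        rec = make_records(rng.lognormal(3.0, 0.5, 20), np.ones(20))
        fit = fit_aft(rec, frame(20), "lognormal", [], SamplerConfig(chains=2, warmup=200, iters=20, thin=1))
        with pytest.raises(EvaluationError):
            psis_loo(fit)


class TestForwardSelect:
    def test_strong_effect_selected_first(self):
        rng = np.random.default_rng(11)
        n = 250
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        logt = np.exp(1.25) + 0.5 * x + 0.4 * rng.standard_normal(n)
        rec = make_records(np.exp(logt), np.ones(n))
        cov = frame(n, X=x, Z=noise)
        selected, _ = forward_select(rec, cov, "lognormal", ["X", "Z"], LIGHT)
        assert selected[:1] == ["X"]

    def test_empty_candidates_returns_base(self):
        rng = np.random.default_rng(12)
        rec = make_records(rng.lognormal(3.0, 0.5, 50), np.ones(50))
        selected, fits = forward_select(rec, frame(50), "lognormal", [], LIGHT)
        assert selected == [] and "" in fits

    def test_null_effects_rarely_selected(self):
        picks = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            n = 150
            rec = make_records(rng.lognormal(3.0, 0.5, n), np.ones(n))
            cov = frame(n, Z1=rng.normal(0, 1, n), Z2=rng.normal(0, 1, n))
            selected, _ = forward_select(rec, cov, "lognormal", ["Z1", "Z2"], LIGHT)
            picks += len(selected)
        assert picks <= 2  # mostly empty selections under the null


class TestSurvivorCurves:
    def test_survivor_function_monotone_and_starts_at_one(self):
        p = AFTParams(dist="weibull", theta0=3.5, coeffs={"X": 0.2}, sigma_ln=None, alpha=1.8)
        s = survivor_function(p, frame(3, X=[-1.0, 0.0, 2.0]), np.arange(0.0, 100.0, 1.0))
        assert np.allclose(s[:, 0], 1.0)
        assert np.all(np.diff(s, axis=1) <= 0)

    def test_degenerate_posterior_gives_zero_band(self):
        rng = np.random.default_rng(13)
        rec = make_records(rng.lognormal(3.0, 0.5, 40), np.ones(40))
        fit = fit_aft(rec, frame(40), "lognormal", [], LIGHT)
        fit.draws = np.broadcast_to(fit.draws[:1, :1, :], fit.draws.shape).copy()  # one draw everywhere
        curve = simulate_population_curve(fit, frame(1), n_draws=50, seed=0)
        assert np.allclose(curve["lo95"], curve["hi95"])
        assert curve.loc[0, "median"] == pytest.approx(1.0)

    def test_posterior_predictive_band_covers_km(self):
        from tgisurv.validation import kaplan_meier

        cohort = generate_cohort(CohortConfig(n_patients=300, seed=22))
        cov = cohort.covariates.copy()
        cov["PTR_wk2"] = cohort.truth["ptr_wk2_true"]
        fit = fit_aft(cohort.survival, cov, "lognormal", ["TS0", "PTR_wk2", "ALB"], LIGHT)
        curve = simulate_population_curve(fit, cov, n_draws=300, seed=1)
        km = kaplan_meier(cohort.survival)
        grid = curve[curve["time_weeks"] <= cohort.survival["time_weeks"].max()]
        inside = 0
        for _, row in grid.iterrows():
            pos = np.searchsorted(km.times, row["time_weeks"], side="right") - 1
            s_km = 1.0 if pos < 0 else km.survival[pos]
            inside += row["lo95"] - 0.02 <= s_km <= row["hi95"] + 0.02
        assert inside / len(grid) >= 0.9
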
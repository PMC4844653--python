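"""Cox proportional-hazards modelling: estimation, diagnostics, validation aids."""

import numpy as np
import pandas as pd
import pytest

from tgisurv.cox import (
    CoxError,
    backward_eliminate,
    bootstrap_ci,
    fit_cox,
    hazard_ratio,
    optimism_corrected_concordance,
    ph_diagnostics,
    predict_survival_probability,
)
from tgisurv.screening import _breslow_pll

from conftest import make_records


def sim_cox(n, beta, seed, censor_rate=0.2, changepoint=None):
    """Exponential survival with log-hazard beta'x; optional effect reversal."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{j}": rng.normal(0, 1, n) for j in range(len(beta))})
    eta = X.to_numpy() @ np.asarray(beta)
    if changepoint is None:
        t = rng.exponential(1.0, n) / np.exp(eta) * 20.0
    else:
        # hazard ratio reverses sign at the changepoint
        t1 = rng.exponential(1.0, n) / np.exp(eta) * 20.0
        t = np.where(
            t1 <= changepoint, t1, changepoint + rng.exponential(1.0, n) / np.exp(-eta) * 20.0
        )
    c = rng.exponential(20.0 / max(censor_rate, 1e-9), n) if censor_rate > 0 else np.full(n, np.inf)
    rec = make_records(np.minimum(t, c) + 1e-6, (t <= c).astype(int))
    return X, rec


class TestFitCox:
    def test_matches_grid_search_partial_likelihood(self):
        X = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 1.0]})
        rec = make_records([2.0, 4.0, 5.0, 7.0, 9.0], [1, 1, 1, 0, 1])
        fit = fit_cox(X, rec)
        grid = np.linspace(-4, 4, 160001)
        plls = [
            _breslow_pll(X.to_numpy(), rec["time_weeks"].to_numpy(), rec["event"].to_numpy(), np.array([b]))
            for b in grid
        ]
        b_star = grid[int(np.argmax(plls))]
        assert fit.coefficients["x"] == pytest.approx(b_star, abs=1e-4)

    def test_null_covariate_near_zero(self):
        X, rec = sim_cox(800, [0.0], seed=1)
        fit = fit_cox(X, rec)
        assert abs(fit.coefficients["x0"]) < 2 * fit.standard_errors["x0"]

    def test_scale_equivariance(self):
        X, rec = sim_cox(300, [0.5], seed=2)
        fit1 = fit_cox(X, rec)
        fit2 = fit_cox(X * 2.0, rec)
        assert fit2.coefficients["x0"] == pytest.approx(fit1.coefficients["x0"] / 2.0, rel=1e-6)

    def test_partial_likelihood_improves_over_null(self):
        X, rec = sim_cox(200, [0.7], seed=3)
        fit = fit_cox(X, rec)
        t, e = rec["time_weeks"].to_numpy(), rec["event"].to_numpy()
        pll_hat = _breslow_pll(X.to_numpy(), t, e, fit.coefficients.to_numpy())
        pll_zero = _breslow_pll(X.to_numpy(), t, e, np.zeros(1))
        assert pll_hat >= pll_zero

    def test_requires_events_and_variation(self):
        with pytest.raises(CoxError):
            fit_cox(pd.DataFrame({"x": [1.0, 2.0]}), make_records([3, 4], [0, 0]))
        with pytest.raises(CoxError):
            fit_cox(pd.DataFrame({"x": [1.0, 1.0]}), make_records([3, 4], [1, 1]))


class TestHazardRatio:
    @pytest.mark.parametrize(
        "beta, delta, expected",
        [
            (0.0064, 10.0, 1.07),   # baseline tumour size per cm
            (-1.29, 1.0, 0.275),    # best observed shrinkage per unit fraction
            (0.759, 1.0, 2.14),     # log neutrophil count
            (0.0, 3.0, 1.0),
        ],
    )
    def test_reproduces_printed_ratios(self, beta, delta, expected):
        fit = fit_cox(*sim_cox(50, [0.1], seed=4))
        fit.coefficients["x0"] = beta
        assert hazard_ratio(fit, "x0", delta) == pytest.approx(expected, abs=0.005)

    def test_reciprocal_property(self):
        fit = fit_cox(*sim_cox(50, [0.4], seed=5))
        assert hazard_ratio(fit, "x0", 1.5) * hazard_ratio(fit, "x0", -1.5) == pytest.approx(1.0)

    def test_unknown_variable_rejected(self):
        fit = fit_cox(*sim_cox(50, [0.4], seed=6))
        with pytest.raises(CoxError):
            hazard_ratio(fit, "zz", 1.0)


class TestBackwardElimination:
    def test_strong_effects_all_retained(self):
        X, rec = sim_cox(400, [0.8, -0.8], seed=7)
        fit = backward_eliminate(X, rec, alpha=0.05)
        assert set(fit.variables) == {"x0", "x1"}

    def test_single_insignificant_variable_gives_empty_model(self):
        X, rec = sim_cox(200, [0.0], seed=8)
        fit = backward_eliminate(X, rec, alpha=1e-6)
        assert fit.variables == []

    def test_alpha_one_never_deletes(self):
        X, rec = sim_cox(200, [0.0, 0.0, 0.0], seed=9)
        fit = backward_eliminate(X, rec, alpha=1.0)
        assert set(fit.variables) == {"x0", "x1", "x2"}


class TestPhDiagnostics:
    def test_reversing_hazard_detected(self):
        X, rec = sim_cox(500, [1.2], seed=10, censor_rate=0.0, changepoint=10.0)
        fit = fit_cox(X, rec)
        report = ph_diagnostics(fit, X, rec)
        assert report.loc["x0", "p_time_interaction"] < 0.01
        assert report.loc["x0", "p_schoenfeld"] < 0.01

    def test_weak_model_still_well_defined(self):
        X, rec = sim_cox(150, [0.0], seed=11)
        fit = fit_cox(X, rec)
        report = ph_diagnostics(fit, X, rec)
        assert np.isfinite(report.to_numpy(dtype=float)).all()


class TestBootstrapCi:
    def test_fixed_seed_reproducible(self):
        X, rec = sim_cox(120, [0.5], seed=12)
        ci1 = bootstrap_ci(X, rec, B=100, seed=3)
        ci2 = bootstrap_ci(X, rec, B=100, seed=3)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_covers_truth_across_replicates(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            X, rec = sim_cox(80, [0.6], seed=300 + rep)
            ci = bootstrap_ci(X, rec, B=100, seed=rep)
            if ci.loc["x0", "lo"] <= 0.6 <= ci.loc["x0", "hi"]:
                hits += 1
        assert hits >= 16  # ~95 % nominal coverage

    def test_small_b_rejected(self):
        X, rec = sim_cox(50, [0.5], seed=13)
        with pytest.raises(CoxError):
            bootstrap_ci(X, rec, B=10)


class TestConcordance:
    def test_perfect_risk_ordering(self):
        rec = make_records([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        X = pd.DataFrame({"x": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]})  # shortest lives, highest risk
        res = optimism_corrected_concordance(X, rec, B=50, seed=0)
        assert res["apparent"] == pytest.approx(1.0)

    def test_matches_pair_enumeration(self):
        rec = make_records([3, 5, 7, 2, 9, 4], [1, 0, 1, 1, 0, 1])
        X = pd.DataFrame({"x": [1.2, -0.3, 0.7, 2.0, -1.0, 0.1]})
        fit = fit_cox(X, rec)
        risk = fit.risk_score(X)
        t = rec["time_weeks"].to_numpy()
        e = rec["event"].to_numpy().astype(bool)
        conc = ties = total = 0
        for i in range(6):
            for j in range(6):
                if e[i] and t[i] < t[j]:  # i experiences the event first
                    total += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        ties += 1
        expected = (conc + 0.5 * ties) / total
        from lifelines.utils import concordance_index

        assert concordance_index(t, -risk, e) == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(14)
        t = rng.exponential(10, 100)
        e = rng.uniform(size=100) < 0.8
        risk = rng.normal(0, 1, 100)
        c1 = concordance_index(t, -risk, e)
        c2 = concordance_index(t, -(np.exp(risk) + 5.0), e)
        assert c1 == pytest.approx(c2)


class TestPredictSurvival:
    def _hand_fit(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        rec = make_records([2.0, 3.0, 5.0, 7.0], [1, 1, 1, 1])
        return fit_cox(X, rec), X, rec

    def test_time_zero_is_one(self):
        fit, X, _ = self._hand_fit()
        assert np.allclose(predict_survival_probability(fit, X, 0.0), 1.0)

    def test_matches_manual_breslow(self):
        fit, X, rec = self._hand_fit()
        beta = fit.coefficients["x"]
        xc = X["x"].to_numpy() - X["x"].mean()
        risk = np.exp(xc * beta)
        # manual Breslow cumulative hazard at the event times
        order = [0, 1, 2, 3]  # already sorted
        H = []
        cum = 0.0
        for k in order:
            cum += 1.0 / risk[k:].sum()
            H.append(cum)
        S_expected = np.exp(-H[1] * risk)  # at t = 3.0
        got = predict_survival_probability(fit, X, 3.0)
        assert np.allclose(got, S_expected, atol=1e-10)

    def test_null_model_equals_baseline_for_everyone(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0, 2.0]})
        rec = make_records([2.0, 3.0, 5.0, 7.0, 8.0], [1, 1, 0, 1, 1])
        fit = fit_cox(X[[]], rec)
        s = predict_survival_probability(fit, X, 4.0)
        assert np.allclose(s, s[0])

    def test_monotone_in_time_and_warns_beyond_followup(self):
        fit, X, _ = self._hand_fit()
        tgrid = np.array([0.0, 2.0, 3.0, 5.0, 7.0])
        S = predict_survival_probability(fit, X, tgrid)
        assert np.all(np.diff(S, axis=1) <= 0)
        with pytest.warns(UserWarning):
            late = predict_survival_probability(fit, X, 100.0)
        assert np.allclose(late, S[:, -1])

    def test_above_average_risk_below_baseline(self):
        X, rec = sim_cox(200, [0.8], seed=15)
        fit = fit_cox(X, rec)
        high = X["x0"] > X["x0"].mean() + 0.5
        base = fit_cox(X[[]], rec)
        s_high = predict_survival_probability(fit, X[high], 10.0)
        s_base = predict_survival_probability(base, X[high], 10.0)
        assert np.all(s_high < s_base + 1e-9)
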
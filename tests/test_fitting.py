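"""Maximum-likelihood survival fitting and information-criterion selection."""

import numpy as np
import pytest

from bilicea import fit_all, fit_parametric, median_of_fit, select_distribution, survival_at
from bilicea.fitting import (
    FAMILIES,
    FitError,
    ParametricFit,
    frozen_distribution,
    log_likelihood,
)
from bilicea.reconstruction import PseudoIPD
from bilicea.synthetic import sample_times

LN2 = np.log(2.0)


class TestExponentialClosedForm:
    def test_uncensored_mle(self):
        fit = fit_parametric(PseudoIPD([1.0, 2.0, 3.0], [1, 1, 1]),
                             "exponential")
        assert fit.params[0] == pytest.approx(0.5, abs=1e-8)

    def test_censored_mle_matches_events_over_time(self):
        t = sample_times("exponential", (0.2,), 500, seed=1)
        obs = np.minimum(t, 8.0)
        ev = (t <= 8.0).astype(int)
        fit = fit_parametric(PseudoIPD(obs, ev), "exponential")
        closed = ev.sum() / obs.sum()
        assert fit.params[0] == pytest.approx(closed, abs=1e-8)


class TestInformationCriteria:
    def test_aic_bic_formulas(self):
        fit = ParametricFit("weibull", (1.0, 1.0), loglik=-50.0, n_obs=100)
        assert fit.aic == pytest.approx(104.0)
        assert fit.bic == pytest.approx(2 * np.log(100) + 100)

    def test_single_candidate_selected(self):
        fit = ParametricFit("exponential", (0.5,), loglik=-10.0, n_obs=10)
        assert select_distribution([fit]) is fit

    def test_tie_break_fewer_params_then_family_order(self):
        # identical criterion values: 2(1)−2ℓ₁ = 2(2)−2ℓ₂ ⇒ ℓ₂ = ℓ₁ + 1
        exp_fit = ParametricFit("exponential", (0.5,), loglik=-11.0, n_obs=10)
        wei_fit = ParametricFit("weibull", (1.0, 2.0), loglik=-10.0, n_obs=10)
        assert select_distribution([wei_fit, exp_fit]).family == "exponential"
        # equal everything: fixed family order decides
        gam = ParametricFit("gamma", (1.0, 0.5), loglik=-10.0, n_obs=10)
        logn = ParametricFit("lognormal", (0.0, 1.0), loglik=-10.0, n_obs=10)
        assert select_distribution([logn, gam]).family == "gamma"

    def test_mixed_n_obs_rejected(self):
        a = ParametricFit("exponential", (0.5,), loglik=-10.0, n_obs=10)
        b = ParametricFit("weibull", (1.0, 2.0), loglik=-10.0, n_obs=11)
        with pytest.raises(ValueError, match="n_obs"):
            select_distribution([a, b])

    def test_invalid_criterion(self):
        a = ParametricFit("exponential", (0.5,), loglik=-10.0, n_obs=10)
        with pytest.raises(ValueError):
            select_distribution([a], criterion="DIC")


class TestParameterRecovery:
    def test_weibull_within_five_percent(self):
        t = sample_times("weibull", (1.5, 10.0), 2000, seed=42)
        fit = fit_parametric(PseudoIPD(t, np.ones(t.size, dtype=int)),
                             "weibull")
        assert fit.params[0] == pytest.approx(1.5, rel=0.05)
        assert fit.params[1] == pytest.approx(10.0, rel=0.05)

    def test_lognormal_selected_on_lognormal_data(self):
        t = sample_times("lognormal", (2.0, 0.5), 1000, seed=5)
        fits = fit_all(PseudoIPD(t, np.ones(t.size, dtype=int)))
        best = select_distribution(list(fits.values()), "AIC")
        assert best.family == "lognormal"

    def test_fit_reproducible(self):
        t = sample_times("gamma", (2.0, 0.3), 300, seed=9)
        ipd = PseudoIPD(t, np.ones(t.size, dtype=int))
        a = fit_parametric(ipd, "gamma")
        b = fit_parametric(ipd, "gamma")
        assert a.params == b.params and a.loglik == b.loglik

    def test_zero_events_rejected(self):
        with pytest.raises(FitError, match="zero events"):
            fit_parametric(PseudoIPD([1.0, 2.0], [0, 0]), "weibull")


class TestSurvivalEvaluation:
    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.3,)),
        ("weibull", (1.5, 10.0)),
        ("gamma", (2.0, 0.4)),
        ("loglogistic", (8.0, 2.0)),
        ("lognormal", (2.0, 0.5)),
    ])
    def test_survival_one_at_zero(self, family, params):
        fit = ParametricFit(family, params, loglik=0.0, n_obs=10)
        assert survival_at(fit, 0.0) == 1.0

    def test_exponential_median_point(self):
        fit = ParametricFit("exponential", (LN2 / 12.7,), loglik=0.0, n_obs=10)
        assert survival_at(fit, 12.7) == pytest.approx(0.5)

    def test_weibull_shape_one_equals_exponential(self):
        wei = ParametricFit("weibull", (1.0, 5.0), loglik=0.0, n_obs=10)
        exp_ = ParametricFit("exponential", (0.2,), loglik=0.0, n_obs=10)
        assert survival_at(wei, 3.7) == pytest.approx(
            survival_at(exp_, 3.7), abs=1e-12)

    def test_negative_time_rejected(self):
        fit = ParametricFit("exponential", (0.3,), loglik=0.0, n_obs=10)
        with pytest.raises(ValueError):
            survival_at(fit, -1.0)


class TestMedian:
    def test_closed_forms(self):
        assert median_of_fit(ParametricFit("exponential", (0.1,), 0.0, 10)) \
            == pytest.approx(LN2 / 0.1)
        assert median_of_fit(ParametricFit("lognormal", (2.0, 0.5), 0.0, 10)) \
            == pytest.approx(np.exp(2.0))
        assert median_of_fit(ParametricFit("loglogistic", (8.0, 2.0), 0.0, 10)) \
            == pytest.approx(8.0)

    def test_gamma_median_matches_bisection_oracle(self):
        fit = ParametricFit("gamma", (2.3, 0.4), loglik=0.0, n_obs=10)
        med = median_of_fit(fit)
        # independent bisection on S(t) − 0.5
        dist = frozen_distribution("gamma", fit.params)
        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if dist.sf(mid) > 0.5:
                lo = mid
            else:
                hi = mid
        assert med == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_median_halves_survival(self):
        for family, params in [("weibull", (1.4, 9.0)), ("gamma", (1.8, 0.25))]:
            fit = ParametricFit(family, params, loglik=0.0, n_obs=10)
            assert survival_at(fit, median_of_fit(fit)) == pytest.approx(0.5, abs=1e-7)


class TestLikelihoodInternals:
    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.3,)),
        ("weibull", (1.5, 10.0)),
        ("gamma", (2.0, 0.4)),
        ("loglogistic", (8.0, 2.0)),
        ("lognormal", (2.0, 0.5)),
    ])
    def test_density_is_negative_survival_derivative(self, family, params):
        """f(t) ≈ −dS/dt, checked numerically on a spread of points."""
        dist = frozen_distribution(family, params)
        rng = np.random.default_rng(0)
        t = rng.uniform(0.5, 30.0, size=200)
        h = 1e-6
        num = -(dist.sf(t + h) - dist.sf(t - h)) / (2 * h)
        pdf = dist.pdf(t)
        mask = pdf > 1e-12
        assert np.allclose(num[mask], pdf[mask], rtol=1e-5)

    def test_early_censoring_leaves_mle_unchanged(self):
        """A censored observation at t → 0⁺ carries no information."""
        t = sample_times("weibull", (1.3, 8.0), 400, seed=3)
        ipd = PseudoIPD(t, np.ones(t.size, dtype=int))
        augmented = PseudoIPD(np.append(t, 1e-9),
                              np.append(np.ones(t.size, dtype=int), 0))
        a = fit_parametric(ipd, "weibull", compute_covariance=False)
        b = fit_parametric(augmented, "weibull", compute_covariance=False)
        assert a.params[0] == pytest.approx(b.params[0], rel=1e-4)
        assert a.params[1] == pytest.approx(b.params[1], rel=1e-4)

    def test_loglik_value_matches_direct_sum(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 0])
        dist = frozen_distribution("weibull", (1.5, 3.0))
        expected = dist.logpdf(t[e == 1]).sum() + dist.logsf(t[e == 0]).sum()
        assert log_likelihood("weibull", (1.5, 3.0), t, e) \
            == pytest.approx(expected)


@pytest.fixture(scope="module")
def censored_sample():
    t = sample_times("weibull", (1.4, 11.0), 800, seed=17)
    obs = np.minimum(t, 18.0)
    ev = (t <= 18.0).astype(int)
    return PseudoIPD(obs, ev)


class TestCrossCheckAgainstLifelines:
    """lifelines' univariate parametric fitters are an independent MLE route."""

    def test_weibull_agrees(self, censored_sample):
        from lifelines import WeibullFitter

        ours = fit_parametric(censored_sample, "weibull")
        wf = WeibullFitter().fit(censored_sample.times, censored_sample.events)
        assert ours.params[0] == pytest.approx(wf.rho_, rel=1e-4)
        assert ours.params[1] == pytest.approx(wf.lambda_, rel=1e-4)
        assert ours.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_lognormal_agrees(self, censored_sample):
        from lifelines import LogNormalFitter

        ours = fit_parametric(censored_sample, "lognormal")
        lf = LogNormalFitter().fit(censored_sample.times, censored_sample.events)
        assert ours.params[0] == pytest.approx(lf.mu_, abs=1e-4)
        assert ours.params[1] == pytest.approx(lf.sigma_, rel=1e-4)
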
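"""Survival families, the interval-censored likelihood, fitting, and the
derived persistence quantities."""

import numpy as np
import pytest

from cptscale import IntervalCensoredSurvReg, ModelSpec
from cptscale.families import median_time, survival_function
from cptscale.survival import (
    FitError,
    aicc,
    avg_persistence_batch,
    avg_persistence_scalar,
    percentile_ci,
)
from cptscale.trials import ObservationSet

from conftest import exact_obs, simulated_obs

import pandas as pd


# --- survival functions ---------------------------------------------------


@pytest.mark.parametrize("family", ["exponential", "weibull", "loglogistic", "lognormal"])
def test_survival_boundaries(family):
    assert survival_function(family, 0.0, 1.2, 0.7 if family != "exponential" else 1.0) == 1.0
    assert survival_function(family, np.inf, 1.2, 0.7 if family != "exponential" else 1.0) == 0.0


def test_exponential_closed_form():
    assert survival_function("exponential", 30.0, np.log(30.0)) == pytest.approx(
        np.exp(-1.0), abs=1e-12
    )


def test_weibull_with_unit_scale_equals_exponential():
    t = np.linspace(0.0, 200.0, 50)
    np.testing.assert_allclose(
        survival_function("weibull", t, np.log(12.0), 1.0),
        survival_function("exponential", t, np.log(12.0)),
        atol=1e-14,
    )


def test_loglogistic_and_lognormal_formulas():
    t, mu, sigma = 17.0, np.log(9.0), 0.55
    assert survival_function("loglogistic", t, mu, sigma) == pytest.approx(
        1.0 / (1.0 + (t / np.exp(mu)) ** (1.0 / sigma)), rel=1e-12
    )
    from scipy.stats import norm

    assert survival_function("lognormal", t, mu, sigma) == pytest.approx(
        norm.sf((np.log(t) - mu) / sigma), rel=1e-12
    )


def test_negative_time_rejected():
    with pytest.raises(ValueError):
        survival_function("weibull", -1.0, 0.0, 1.0)


# --- likelihood -----------------------------------------------------------


def _single_obs(left, right):
    return ObservationSet(
        np.array([left]), np.array([right]),
        pd.DataFrame([{"bird_type": "raptor"}]), np.ones(1),
    )


def test_nloglik_total_probability_is_zero():
    m = IntervalCensoredSurvReg(_single_obs(0.0, np.inf), ModelSpec("exponential"))
    assert m.nloglik([np.log(30.0)]) == pytest.approx(0.0, abs=1e-12)


def test_nloglik_right_censoring_closed_form():
    m = IntervalCensoredSurvReg(_single_obs(56.0, np.inf), ModelSpec("exponential"))
    assert m.nloglik([np.log(30.0)]) == pytest.approx(56.0 / 30.0, rel=1e-12)


def test_nloglik_interval_closed_form():
    m = IntervalCensoredSurvReg(_single_obs(7.0, 14.0), ModelSpec("exponential"))
    expected = -np.log(np.exp(-7.0 / 30.0) - np.exp(-14.0 / 30.0))
    assert m.nloglik([np.log(30.0)]) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1.80302, abs=5e-5)


def test_nloglik_zero_mass_interval_returns_inf_not_exception():
    # a near-degenerate Weibull (sigma = 0.01) puts numerically zero mass on
    # a far-tail interval: the likelihood must signal +inf, not raise
    m = IntervalCensoredSurvReg(_single_obs(1e6, 1e6 + 1.0), ModelSpec("weibull"))
    assert m.nloglik([np.log(10.0), np.log(0.01)]) == np.inf


# --- AICc and selection helpers ------------------------------------------


def test_aicc_arithmetic_and_boundaries():
    assert aicc(-50.0, 2, 10) == pytest.approx(105.714, abs=5e-4)
    assert aicc(-50.0, 2, 10**9) == pytest.approx(-2 * -50.0 + 4.0, abs=1e-4)
    assert aicc(-50.0, 2, 3) == np.inf


# --- median and average persistence ---------------------------------------


def test_median_closed_forms():
    assert median_time("exponential", np.log(30.0)) == pytest.approx(
        30.0 * np.log(2.0), rel=1e-12
    )  # 20.794
    assert median_time("weibull", np.log(30.0), 0.5) == pytest.approx(
        30.0 * np.log(2.0) ** 0.5, rel=1e-12
    )  # 24.977
    assert median_time("loglogistic", np.log(30.0), 0.8) == pytest.approx(30.0)
    assert median_time("lognormal", np.log(30.0), 0.8) == pytest.approx(30.0)


def test_avg_persistence_exponential_closed_form():
    r = avg_persistence_scalar("exponential", np.log(30.0), 1.0, 30.0)
    assert r == pytest.approx(1.0 - np.exp(-1.0), abs=1e-8)  # 0.63212


def test_avg_persistence_short_interval_limit():
    assert avg_persistence_scalar("weibull", np.log(30.0), 0.7, 1e-6) == pytest.approx(
        1.0, abs=1e-5
    )


def test_avg_persistence_rejects_nonpositive_interval():
    with pytest.raises(ValueError):
        avg_persistence_scalar("weibull", 1.0, 1.0, 0.0)


def test_batch_quadrature_matches_adaptive_scalar():
    rng = np.random.default_rng(0)
    for family in ("exponential", "weibull", "loglogistic", "lognormal"):
        mu = rng.uniform(np.log(2.0), np.log(200.0), size=8)
        sigma = np.ones(8) if family == "exponential" else rng.uniform(0.3, 1.5, size=8)
        for t in (14.0, 30.0, 90.0):
            batch = avg_persistence_batch(family, mu, sigma, t)
            scalar = [avg_persistence_scalar(family, m, s, t) for m, s in zip(mu, sigma)]
            np.testing.assert_allclose(batch, scalar, atol=1e-8)


def test_r_hat_non_increasing_in_search_interval(exponential_fit):
    r = [exponential_fit.avg_persistence(t) for t in (14.0, 30.0, 60.0, 90.0)]
    assert r[0] >= r[1] >= r[2] >= r[3]
    assert 0.0 < r[-1] <= 1.0


def test_median_matches_numeric_root(exponential_fit):
    from scipy.optimize import brentq

    med = exponential_fit.median_time()
    root = brentq(lambda t: exponential_fit.survival(t) - 0.5, 1e-6, 1e4)
    assert med == pytest.approx(root, abs=1e-6)


# --- fitting --------------------------------------------------------------


def test_exact_time_exponential_mle_is_sample_mean():
    res = IntervalCensoredSurvReg(
        exact_obs([10.0, 20.0, 30.0]), ModelSpec("exponential")
    ).fit(min_n=1, seed=0)
    assert np.exp(res.params[0]) == pytest.approx(20.0, abs=0.5)


def test_weibull_parameter_recovery_within_3se():
    mu, sigma = np.log(40.0), 0.7
    obs = simulated_obs("weibull", mu, sigma, 500, seed=11)
    res = IntervalCensoredSurvReg(obs, ModelSpec("weibull")).fit(seed=1)
    se = res.bse()
    assert abs(res.params[0] - mu) < 3 * se[0]
    assert abs(res.params[1] - np.log(sigma)) < 3 * se[1]


def test_fit_matches_lifelines_interval_censored_oracle():
    """Independent oracle: lifelines' interval-censored Weibull and
    lognormal fitters on the same intervals."""
    lifelines = pytest.importorskip("lifelines")
    obs = simulated_obs("weibull", np.log(20.0), 0.8, 400, seed=13)
    res = IntervalCensoredSurvReg(obs, ModelSpec("weibull")).fit(seed=0)
    wf = lifelines.WeibullFitter().fit_interval_censoring(
        np.maximum(obs.left, 1e-9), obs.right
    )
    assert res.params[0] == pytest.approx(np.log(wf.lambda_), abs=1e-3)
    assert np.exp(res.params[1]) == pytest.approx(1.0 / wf.rho_, abs=1e-3)
    assert res.llf == pytest.approx(wf.log_likelihood_, abs=1e-4)

    obs2 = simulated_obs("lognormal", np.log(12.0), 0.9, 400, seed=14)
    res2 = IntervalCensoredSurvReg(obs2, ModelSpec("lognormal")).fit(seed=0)
    lnf = lifelines.LogNormalFitter().fit_interval_censoring(
        np.maximum(obs2.left, 1e-9), obs2.right
    )
    assert res2.params[0] == pytest.approx(lnf.mu_, abs=1e-3)
    assert np.exp(res2.params[1]) == pytest.approx(lnf.sigma_, abs=1e-3)


def test_covariate_effect_recovered():
    obs_a = simulated_obs("weibull", np.log(8.0), 0.7, 250, seed=31,
                          labels={"habitat": "forest"})
    obs_b = simulated_obs("weibull", np.log(30.0), 0.7, 250, seed=32,
                          labels={"habitat": "grassland"})
    obs = ObservationSet(
        np.concatenate([obs_a.left, obs_b.left]),
        np.concatenate([obs_a.right, obs_b.right]),
        pd.concat([obs_a.covariates, obs_b.covariates], ignore_index=True),
        np.concatenate([obs_a.weights, obs_b.weights]),
    )
    res = IntervalCensoredSurvReg(obs, ModelSpec("weibull", ("habitat",))).fit(seed=0)
    idx = res.model.param_names.index("loc.habitat[grassland]")
    effect = res.params[idx]
    se = res.bse()[idx]
    assert abs(effect - np.log(30.0 / 8.0)) < 3 * se
    mu_f, _ = res.mu_sigma({"habitat": "forest"})
    mu_g, _ = res.mu_sigma({"habitat": "grassland"})
    assert mu_g - mu_f == pytest.approx(effect)


def test_all_censored_refuses_to_fit():
    obs = ObservationSet(
        np.full(20, 56.0), np.full(20, np.inf),
        pd.DataFrame([{"bird_type": "raptor"}] * 20), np.ones(20),
    )
    with pytest.raises(FitError, match="censored"):
        IntervalCensoredSurvReg(obs, ModelSpec("exponential")).fit(seed=0)


def test_tiny_stratum_refuses_to_fit():
    with pytest.raises(FitError, match="refusing"):
        IntervalCensoredSurvReg(
            exact_obs([3.0, 5.0, 8.0]), ModelSpec("weibull")
        ).fit(seed=0)


# --- bootstrap ------------------------------------------------------------


def test_bootstrap_draw_count_and_degenerate_covariance(exponential_fit):
    draws = exponential_fit.bootstrap_draws(1000, seed=0)
    assert draws.shape == (1000, exponential_fit.k)

    exponential_fit.vcov = np.zeros_like(exponential_fit.vcov)
    same = exponential_fit.bootstrap_draws(5, seed=1)
    np.testing.assert_allclose(same, np.tile(exponential_fit.params, (5, 1)))


def test_bootstrap_rejects_non_psd_covariance(exponential_fit):
    exponential_fit.vcov = np.array([[-1.0]])
    with pytest.raises(FitError, match="positive semidefinite"):
        exponential_fit.bootstrap_draws(10, seed=0)


def test_scale_draws_stay_positive():
    obs = simulated_obs("weibull", np.log(20.0), 0.6, 300, seed=8)
    res = IntervalCensoredSurvReg(obs, ModelSpec("weibull")).fit(seed=0)
    draws = res.bootstrap_draws(500, seed=2)
    # scale coefficients are drawn on the log link: sigma = exp(.) > 0 always
    sigmas = np.exp(draws[:, res.model.k_loc])
    assert np.all(sigmas > 0)


# --- percentile CIs -------------------------------------------------------


def test_percentile_ci_interpolated_order_statistics():
    assert percentile_ci(np.arange(1.0, 11.0), 0.8) == pytest.approx((1.9, 9.1))


def test_percentile_ci_degenerate_and_symmetry():
    assert percentile_ci([3.0, 3.0, 3.0], 0.9) == (3.0, 3.0)
    vals = np.concatenate([np.linspace(-1, 1, 101)])
    lo, hi = percentile_ci(vals, 0.9)
    assert lo == pytest.approx(-hi, abs=1e-12)


def test_percentile_ci_usage_errors():
    with pytest.raises(ValueError):
        percentile_ci([1.0], 0.9)
    with pytest.raises(ValueError):
        percentile_ci([1.0, 2.0], 1.5)
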
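"""Unit and property tests for the probability-family layer."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from unimo.distributions import (SupportError, evaluate, fit_mle, get_family,
                                 information_criteria, list_families, sample)

CONTINUOUS = ["gamma", "weibull", "lognormal", "inverse_gaussian",
              "exponential", "beta", "logit_normal", "gaussian", "logistic",
              "reverse_gumbel"]

REFERENCE_THETA = {
    "gamma": [(2.0, 3.0), (0.7, 1.0), (10.0, 0.5)],
    "weibull": [(1.5, 2.0), (0.8, 1.0), (5.0, 0.3)],
    "lognormal": [(0.0, 0.5), (1.0, 1.0), (-1.0, 0.25)],
    "inverse_gaussian": [(1.0, 1.0), (2.0, 5.0), (0.5, 0.2)],
    "exponential": [(1.0,), (0.2,), (7.0,)],
    "beta": [(2.0, 5.0), (0.5, 0.5), (8.0, 8.0)],
    "logit_normal": [(0.0, 1.0), (1.0, 0.5), (-2.0, 0.7)],
    "gaussian": [(0.0, 1.0), (-3.0, 0.2), (10.0, 5.0)],
    "logistic": [(0.0, 1.0), (2.0, 0.5), (-1.0, 3.0)],
    "reverse_gumbel": [(0.0, 1.0), (5.0, 0.3), (-2.0, 2.0)],
}


@pytest.mark.parametrize("family,theta", [
    (f, th) for f, ths in REFERENCE_THETA.items() for th in ths])
def test_density_integrates_to_one(family, theta):
    fam = get_family(family)
    lo = float(fam._ppf(np.asarray(theta, float), np.array([1e-12]))[0])
    hi = float(fam._ppf(np.asarray(theta, float), np.array([1 - 1e-12]))[0])
    val, _ = integrate.quad(
        lambda x: math.exp(fam._logpdf(np.asarray(theta, float),
                                       np.array([x]))[0]),
        lo, hi, limit=200)
    assert abs(val - 1.0) <= 1e-6


@pytest.mark.parametrize("family,theta", [
    (f, ths[0]) for f, ths in REFERENCE_THETA.items()])
def test_quantile_inverts_cdf(family, theta):
    fam = get_family(family)
    p = np.linspace(0.01, 0.99, 21)
    q = fam._ppf(np.asarray(theta, float), p)
    back = fam._cdf(np.asarray(theta, float), q)
    assert np.max(np.abs(back - p)) <= 1e-8


@pytest.mark.parametrize("family,theta,x,which,expected,tol", [
    ("gaussian", (0.0, 1.0), 1.959964, "cdf", 0.975, 1e-6),
    ("gamma", (1.0, 1.0), 1.0, "cdf", 1.0 - math.exp(-1.0), 1e-10),
    ("beta", (1.0, 1.0), 0.3, "quantile", 0.3, 1e-10),
])
def test_evaluate_known_values(family, theta, x, which, expected, tol):
    assert evaluate(family, theta, x, which) == pytest.approx(expected,
                                                             abs=tol)


def test_evaluate_rejects_out_of_support():
    with pytest.raises((SupportError, ValueError)):
        evaluate("gamma", (2.0, 1.0), -1.0, "logpdf")
    with pytest.raises(ValueError):
        evaluate("gaussian", (0.0, 1.0), 1.2, "quantile")


def test_information_criteria_formulas():
    aic, bic = information_criteria(-100.0, 2, 100)
    assert aic == pytest.approx(204.0)
    assert bic == pytest.approx(200.0 + 2 * math.log(100), abs=1e-10)
    aic0, bic0 = information_criteria(-100.0, 0, 50)
    assert aic0 == bic0 == 200.0
    with pytest.raises(ValueError):
        information_criteria(-1.0, 1, 0)


def test_gaussian_closed_form_mle():
    fr = fit_mle("gaussian", [1.0, 2.0, 3.0])
    assert fr.params["mu"] == pytest.approx(2.0)
    assert fr.params["sigma"] == pytest.approx(math.sqrt(2.0 / 3.0))
    assert fr.aic == pytest.approx(-2 * fr.loglik + 4.0)


def test_binomial_pooled_mle():
    pairs = np.array([[10, 40], [20, 60]])
    fr = fit_mle("binomial", pairs)
    assert fr.params["p"] == pytest.approx(0.30)


def test_gamma_mle_matches_direct_maximization(rng):
    """The closed-ish Newton fit agrees with brute-force numeric
    maximization of the same log-likelihood (independent oracle)."""
    x = rng.gamma(2.0, 3.0, 10_000)
    fr = fit_mle("gamma", x)
    assert 1.9 <= fr.params["shape"] <= 2.1

    def nll(z):
        a, s = np.exp(z)
        return -np.sum(stats.gamma.logpdf(x, a, scale=s))

    res = optimize.minimize(nll, [0.0, 1.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10})
    a_ref, s_ref = np.exp(res.x)
    assert fr.params["shape"] == pytest.approx(a_ref, rel=1e-4)
    assert fr.params["scale"] == pytest.approx(s_ref, rel=1e-4)
    assert fr.loglik >= -res.fun - 1e-6


@pytest.mark.parametrize("family,theta", [
    ("weibull", (3.0, 1.5)),
    ("logistic", (0.5, 1.2)),
    ("reverse_gumbel", (2.0, 0.5)),
    ("beta", (8.0, 4.0)),
])
def test_specialized_fits_match_generic_optimizer(family, theta, rng):
    """Closed/Newton weighted fits land on the same optimum as the generic
    quasi-Newton path."""
    fam = get_family(family)
    x = sample(family, theta, 1500, rng)
    xc = fam._prep(x)
    w = np.ones(len(xc))
    closed = np.asarray(fam._fit_closed(xc, w), dtype=float)
    th_num, ll_num, _, _ = fam._fit_numeric(xc, w, {})
    assert fam.loglik(closed, xc) >= ll_num - 1e-6


def test_beta_binomial_newton_matches_bfgs(rng):
    fam = get_family("beta_binomial")
    kb = sample("beta_binomial", (0.3, 0.05), 800, rng, n_trials=100)
    fr = fit_mle("beta_binomial", kb)
    th, ll, _, _ = fam._fit_numeric(fam._prep(kb), np.ones(800), {})
    assert fr.loglik >= ll - 1e-6
    assert fr.params["p"] == pytest.approx(th[0], abs=1e-5)


def test_logit_normal_is_gaussian_on_logit_scale(rng):
    y = rng.beta(4.0, 3.0, 300)
    fr = fit_mle("logit_normal", y)
    z = np.log(y) - np.log1p(-y)
    assert fr.params["mu"] == pytest.approx(z.mean(), abs=1e-10)
    assert fr.params["sigma"] == pytest.approx(z.std(), abs=1e-10)


def test_weighted_fit_equals_replicated_fit(rng):
    """Integer weights reproduce the fit of the replicated sample."""
    x = rng.gamma(3.0, 1.0, 60)
    w = rng.integers(1, 4, 60).astype(float)
    fam = get_family("gamma")
    th_w, _, _, _ = fam.fit(x, weights=w)
    x_rep = np.repeat(x, w.astype(int))
    th_r, _, _, _ = fam.fit(x_rep)
    assert np.allclose(th_w, th_r, rtol=1e-8)


@pytest.mark.parametrize("family,theta,kw", [
    ("gaussian", (1.0, 2.0), {}),
    ("gamma", (4.0, 0.5), {}),
])
def test_se_matches_sampling_spread(family, theta, kw):
    """Reported standard errors track the empirical spread of the MLE over
    repeated sampling (within 15% at n=500)."""
    n, reps = 500, 500
    rng = np.random.default_rng(5)
    first = np.empty(reps)
    se = np.empty(reps)
    for i in range(reps):
        x = sample(family, theta, n, rng)
        fr = fit_mle(family, x)
        first[i] = fr.theta[0]
        se[i] = fr.se[0]
    emp = first.std()
    assert abs(np.median(se) - emp) / emp <= 0.15


def test_fit_reports_nonconvergence_not_crash():
    # two observations cannot identify three effective parameters
    with pytest.raises(ValueError):
        fit_mle("gamma", [1.0])


def test_zero_variance_data_is_an_error():
    with pytest.raises(ValueError):
        fit_mle("gaussian", [2.0, 2.0, 2.0])


def test_fitresult_serializes(rng):
    fr = fit_mle("gaussian", rng.normal(0, 1, 50))
    import json
    d = json.loads(fr.to_json())
    assert d["family"] == "gaussian"
    assert set(d["theta"]) == {"mu", "sigma"}


def test_family_registry_covers_catalogue():
    names = list_families()
    for f in CONTINUOUS + ["binomial", "beta_binomial", "poisson",
                           "negative_binomial"]:
        assert f in names
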
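"""Mixture EM, BIC component selection, confounder GLM, outlier rule."""

import numpy as np
import pytest

from unimo.distributions import fit_mle, sample
from unimo.modality import (adjust_confounders, assess_modality,
                            fit_mixture_em, select_components,
                            trim_outliers_one_percentile)

EM_KW = dict(n_restarts=3, tol=1e-6, max_iter=200)
SEL_KW = dict(c_max=4, n_restarts=3, n_randomizations=3, tol=1e-6,
              max_iter=200)


def test_single_component_equals_plain_mle(wt_gaussian):
    mf = fit_mixture_em("gaussian", wt_gaussian, 1, seed=0, **EM_KW)
    fr = fit_mle("gaussian", wt_gaussian)
    assert mf.loglik == pytest.approx(fr.loglik, abs=1e-6)
    assert mf.weights[0] == 1.0


def test_em_recovers_separated_gaussian_mixture(rng):
    x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250)])
    mf = fit_mixture_em("gaussian", x, 2, seed=1, **EM_KW)
    order = np.argsort([c[0] for c in mf.components])
    means = np.array([mf.components[i][0] for i in order])
    weights = mf.weights[order]
    assert np.allclose(weights, [0.5, 0.5], atol=0.05)
    assert abs(means[0] - 0.0) <= 0.2 and abs(means[1] - 6.0) <= 0.2


def test_em_loglik_nondecreasing(rng):
    x = np.concatenate([rng.normal(0, 1, 150), rng.normal(4, 1, 150)])
    mf = fit_mixture_em("gaussian", x, 3, seed=2, **EM_KW)
    trace = np.asarray(mf.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-9)


def test_mixture_nesting_in_loglik(rng):
    x = rng.normal(0, 1, 200)
    lls = [fit_mixture_em("gaussian", x, c, seed=3, **EM_KW).loglik
           for c in (1, 2, 3)]
    assert lls[1] >= lls[0] - 1e-6
    assert lls[2] >= lls[1] - 1e-6


def test_sum_of_weights_is_one(rng):
    x = np.concatenate([rng.gamma(2, 1, 150), rng.gamma(20, 1, 150)])
    mf = fit_mixture_em("gamma", x, 2, seed=4, **EM_KW)
    assert mf.weights.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(mf.weights > 0)


def test_feasibility_limits_component_count(rng):
    x = rng.normal(0, 1, 5)
    _, table, _ = select_components(x, "gaussian", c_max=10, n_restarts=2,
                                    n_randomizations=1, seed=0)
    assert set(table) == {1}


def test_bic_prefers_one_component_on_unimodal_data(wt_gaussian):
    c, table, votes = select_components(wt_gaussian, "gaussian", seed=5,
                                        **SEL_KW)
    assert c == 1


def test_bic_detects_separated_two_component_mixture(rng):
    x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250)])
    c, _, _ = select_components(x, "gaussian", seed=6, **SEL_KW)
    assert c == 2


def test_adjust_single_level_is_identity(rng):
    x = rng.normal(2, 1, 60)
    adj, rec = adjust_confounders(x, np.full(60, "only"), "gaussian")
    assert np.max(np.abs(adj - x)) <= 1e-10


def test_adjust_removes_planted_batch_shift(rng):
    y = np.concatenate([rng.normal(0, 1, 57), rng.normal(5, 1, 57)])
    levels = np.array(["a"] * 57 + ["b"] * 57)
    c_raw, _, _ = select_components(y, "gaussian", seed=7, **SEL_KW)
    adj, rec = adjust_confounders(y, levels, "gaussian")
    c_adj, _, _ = select_components(adj, "gaussian", seed=7, **SEL_KW)
    assert c_raw >= 2 and c_adj == 1
    # sum-to-zero effects preserve the overall location
    assert np.mean(adj) == pytest.approx(np.mean(y), abs=0.05)
    assert rec["effects"]["a"] == pytest.approx(-rec["effects"]["b"],
                                                abs=0.5)


def test_adjust_removes_multiplicative_gamma_batch(rng):
    a = rng.gamma(16.0, 1.0 / 4.0, 57)       # mean 4
    b = rng.gamma(16.0, 2.0 / 4.0, 57)       # mean 8: scale x2 batch
    y = np.concatenate([a, b])
    levels = np.array(["a"] * 57 + ["b"] * 57)
    adj, _ = adjust_confounders(y, levels, "gamma")
    c_adj, _, _ = select_components(adj, "gamma", seed=8, **SEL_KW)
    assert c_adj == 1
    assert np.mean(adj[:57]) == pytest.approx(np.mean(adj[57:]), rel=0.1)


def test_singleton_level_effect_zero_with_warning(rng):
    y = rng.normal(0, 1, 21)
    levels = np.array(["a"] * 20 + ["solo"])
    with pytest.warns(UserWarning, match="solo"):
        adj, rec = adjust_confounders(y, levels, "gaussian")
    assert rec["effects"]["solo"] == 0.0


def test_one_percentile_rule_on_known_fit(rng):
    fit = fit_mle("gaussian", rng.normal(0, 1, 1000))
    fit.theta = np.array([0.0, 1.0])
    kept, removed = trim_outliers_one_percentile(
        np.array([0.0, 1.0, 4.0, -0.5]), fit)
    assert removed == [2]           # |z|=4 is in the 1% two-sided tail
    assert 1.0 in kept              # |z|=1 is kept


def test_one_percentile_null_removal_fraction(rng):
    x = rng.normal(0, 1, 10_000)
    fit = fit_mle("gaussian", x)
    kept, removed = trim_outliers_one_percentile(x, fit)
    frac = len(removed) / len(x)
    assert 0.005 <= frac <= 0.015


def test_trimming_capped_at_two_percent(rng):
    x = np.concatenate([rng.normal(0, 1, 100), rng.normal(40, 1, 50)])
    fit = fit_mle("gaussian", rng.normal(0, 1, 100))
    fit.theta = np.array([0.0, 1.0])
    kept, removed = trim_outliers_one_percentile(x, fit)
    assert len(removed) <= int(np.ceil(0.02 * len(x)))


def test_assess_modality_stages(rng):
    # clean unimodal -> resolved at the raw stage
    rep = assess_modality(rng.normal(0, 1, 114), "gaussian", seed=9,
                          **SEL_KW)
    assert rep.final_unimodal and rep.final_stage == "raw"
    # planted batch -> resolved after confounder adjustment
    y = np.concatenate([rng.normal(0, 1, 57), rng.normal(6, 1, 57)])
    levels = np.array(["a"] * 57 + ["b"] * 57)
    rep = assess_modality(y, "gaussian", levels=levels, seed=10, **SEL_KW)
    assert rep.final_unimodal and rep.final_stage == "confounder-adjusted"
    assert [s.stage for s in rep.stages] == ["raw", "confounder-adjusted"]


def test_assess_modality_outlier_rescue(rng):
    x = rng.normal(0, 1, 114)
    x[:3] = [8.5, -8.2, 9.1]  # ~2.6% far-tail contamination
    rep = assess_modality(x, "gaussian", seed=11, **SEL_KW)
    if not rep.final_unimodal:
        pytest.fail("contaminated feature not rescued")
    assert rep.final_stage in ("raw", "outlier-trimmed")
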
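"""Parametric mutant phenotyping against wild-type null models.

For each feature, the assigned family is fitted to the (modality-processed)
wild-type replicates; that fit is the null model.  Each mutant observation
is then scored by

* a two-tailed tail probability under the null CDF,
  ``P = 2 * min(F0(y), 1 - F0(y))`` for continuous families and
  ``P = 2 * min(F0(y), 1 - F0(y-1))`` for discrete ones (capped at 1);
* a Wald Z value ``Z = (b_j - b_0) / SE`` where ``b_j`` is the location
  refitted to the mutant's observation(s) with the dispersion held at the
  null estimate, ``b_0`` the null location, and the standard error comes
  from the expected Fisher information of the location evaluated at the
  null parameters (so that Z is exactly centred and unit-scaled under the
  null for the mean-parameterized families);
* a Storey q-value estimated per feature across the mutant panel; a
  (mutant, feature) pair is significant at FDR f iff q <= f, and a mutant
  is morphologically abnormal iff it is significant in at least one
  feature.

Beta-binomial features follow a special rule: a mutant whose numerator
equals the wild-type-estimated value gets Z = 0 exactly, and any
non-finite Wald value is capped at the maximum finite |Z| of the other
mutants with matching sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from .distributions import FitResult, fit_mle, get_family

__all__ = [
    "NullModel",
    "fit_null",
    "mutant_test",
    "estimate_qvalues",
    "call_abnormal",
    "score_panel",
]


@dataclass
class NullModel:
    feature_id: str
    family: str
    fit: FitResult
    n_wt: int

    @property
    def theta(self) -> np.ndarray:
        return self.fit.theta

    @property
    def location(self) -> float:
        return get_family(self.family).location(self.theta)


def fit_null(wt_data, assignment, modality=None, min_obs: int = 20,
             feature_id: str = "") -> NullModel:
    """Fit the wild-type null model for one feature.

    Uses ``modality.processed_data`` (confounder-adjusted, outlier-trimmed)
    when a modality report is supplied, else the raw wild-type data.
    """
    family = assignment if isinstance(assignment, str) else assignment.family
    if modality is not None:
        data = modality.processed_data
        feature_id = feature_id or modality.feature_id
    else:
        data = wt_data
    fam = get_family(family)
    x = fam._prep(data)
    if len(x) < min_obs:
        raise ValueError(
            f"feature {feature_id!r}: only {len(x)} wild-type observations "
            f"after processing (need >= {min_obs})")
    fr = fit_mle(fam, x)
    return NullModel(feature_id=feature_id, family=fam.name, fit=fr,
                     n_wt=len(x))


# ---------------------------------------------------------------------------
# vectorized single-observation location refits (dispersion fixed at null)

def _location_mle_vec(fam, y, theta0):
    """Location MLE for each single observation, vectorized per family."""
    name = fam.name
    if name in ("gaussian", "logistic", "reverse_gumbel", "gamma",
                "exponential", "inverse_gaussian", "poisson",
                "negative_binomial"):
        return np.asarray(y, dtype=float)
    if name == "weibull":
        return np.asarray(y, float) * special.gamma(1.0 + 1.0 / theta0[0])
    if name == "lognormal":
        return np.asarray(y, dtype=float)  # exp(log y)
    if name == "logit_normal":
        return np.asarray(y, dtype=float)  # handled on the logit scale
    if name in ("binomial", "beta_binomial"):
        y = np.atleast_2d(y)
        return np.clip(y[:, 0] / y[:, 1], 1e-12, 1 - 1e-12)
    return np.array([fam.location_mle(np.atleast_1d(v), theta0) for v in y])


def _pvalues(fam, theta0, obs):
    if fam.proportion:
        obs = np.atleast_2d(obs)
        F = fam._cdf(theta0, obs)
        k, n = obs[:, 0], obs[:, 1]
        below = np.column_stack([k - 1, n])
        Fm = np.where(k > 0, fam._cdf(theta0, below), 0.0)
        P = 2.0 * np.minimum(F, 1.0 - Fm)
    elif fam.discrete:
        x = np.atleast_1d(obs)
        F = fam._cdf(theta0, x)
        Fm = np.where(x > 0, fam._cdf(theta0, np.maximum(x - 1, 0)), 0.0)
        P = 2.0 * np.minimum(F, 1.0 - Fm)
    else:
        x = np.atleast_1d(obs)
        F = fam._cdf(theta0, x)
        P = 2.0 * np.minimum(F, 1.0 - F)
    return np.clip(P, np.finfo(float).tiny, 1.0)


def _zvalues(fam, theta0, obs):
    if fam.name == "logit_normal":
        # Wald on the logit scale, where the family is exactly Gaussian
        x = np.clip(np.atleast_1d(np.asarray(obs, float)), 1e-12, 1 - 1e-12)
        z = special.logit(x)
        return (z - theta0[0]) / theta0[1]
    if fam.proportion:
        obs2 = np.atleast_2d(obs)
        b_j = _location_mle_vec(fam, obs2, theta0)
        info = np.array([fam.location_info(theta0, n_trials=nt)
                         for nt in obs2[:, 1]])
    else:
        x = np.atleast_1d(np.asarray(obs, float))
        b_j = _location_mle_vec(fam, x, theta0)
        info = np.full(len(x), fam.location_info(theta0))
    b_0 = fam.location(theta0)
    with np.errstate(all="ignore"):
        z = (b_j - b_0) * np.sqrt(info)
    return z


def mutant_test(observation, null: NullModel) -> tuple[float, float]:
    """Two-tailed tail probability and Wald Z for one mutant observation
    (a scalar, or a (k, n) pair for proportion features; an array of
    replicate observations is averaged into a joint location refit)."""
    fam = get_family(null.family)
    theta0 = null.theta
    obs = np.atleast_2d(observation) if fam.proportion \
        else np.atleast_1d(np.asarray(observation, dtype=float))
    fam._prep(obs)  # support check
    n_rep = len(obs)
    if n_rep == 1:
        P = float(_pvalues(fam, theta0, obs)[0])
        Z = float(_zvalues(fam, theta0, obs)[0])
        return P, Z
    # replicate case: joint location refit, pooled information
    b_j = fam.location_mle(obs, theta0)
    b_0 = fam.location(theta0)
    if fam.proportion:
        info = sum(fam.location_info(theta0, n_trials=nt) for nt in obs[:, 1])
    else:
        info = n_rep * fam.location_info(theta0)
    Z = (b_j - b_0) * np.sqrt(info)
    # P for the replicate mean via the location-refit Z (normal approx)
    from scipy.stats import norm
    P = float(np.clip(2.0 * norm.sf(abs(Z)), np.finfo(float).tiny, 1.0))
    return P, float(Z)


def _finalize_betabinom_z(z: np.ndarray, obs, theta0) -> np.ndarray:
    """Apply the beta-binomial rule: Z = 0 when the numerator equals the
    wild-type-estimated value; non-finite Wald values are capped at the
    maximum finite |Z| of the other mutants with matching sign."""
    obs = np.atleast_2d(obs)
    expected = theta0[0] * obs[:, 1]
    z = np.where(obs[:, 0] == expected, 0.0, z)
    bad = ~np.isfinite(z)
    if np.any(bad):
        finite = z[~bad]
        pos_cap = np.max(finite[finite > 0], initial=0.0)
        neg_cap = np.min(finite[finite < 0], initial=0.0)
        z = np.where(bad & (z > 0) | (bad & np.isnan(z)), pos_cap, z)
        z = np.where(~np.isfinite(z), neg_cap, z)
    return z


def estimate_qvalues(pvalues, pi0: Optional[float] = None,
                     lambdas=None) -> tuple[np.ndarray, float]:
    """Storey q-values.

    pi0 is estimated on the grid lambda = 0.05, 0.10, ..., 0.95 with a
    cubic-polynomial smoother evaluated at the largest lambda, clipped to
    (0, 1]; for fewer than 20 p-values pi0 = 1.  Forcing ``pi0=1``
    reproduces Benjamini–Hochberg adjusted p-values exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 20:
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.951, 0.05)
            lambdas = np.asarray(lambdas, dtype=float)
            pi0_l = np.array([np.mean(p > lam) / (1.0 - lam)
                              for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, float(pi0)


def score_panel(mutant_obs: dict, nulls: dict, fdr: float = 0.01,
               pooled_qvalues: bool = False
               ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Score a whole mutant panel.

    Parameters
    ----------
    mutant_obs : {feature_id: (mutant_ids, observations)} where
        observations is a 1-d array (or (n, 2) count pairs), one row per
        mutant.
    nulls : {feature_id: NullModel}.
    fdr : q-value threshold for significance.
    pooled_qvalues : estimate q-values over all features pooled instead of
        per feature.

    Returns
    -------
    results : long DataFrame (mutant, feature, value, P, Z, q, significant)
    summary : per-mutant DataFrame (n_significant_features, abnormal)
    pi0 : {feature_id: pi0 estimate}
    """
    if not mutant_obs:
        raise ValueError("empty mutant panel")
    rows = []
    for feat, (mutant_ids, obs) in mutant_obs.items():
        null = nulls[feat]
        fam = get_family(null.family)
        obs_arr = np.atleast_2d(obs) if fam.proportion \
            else np.asarray(obs, dtype=float)
        fam._prep(obs_arr)
        P = _pvalues(fam, null.theta, obs_arr)
        Z = _zvalues(fam, null.theta, obs_arr)
        if fam.name == "beta_binomial":
            Z = _finalize_betabinom_z(Z, obs_arr, null.theta)
        val = obs_arr[:, 0] / obs_arr[:, 1] if fam.proportion else obs_arr
        rows.append(pd.DataFrame({
            "mutant": mutant_ids, "feature": feat, "value": val,
            "P": P, "Z": Z}))
    results = pd.concat(rows, ignore_index=True)
    pi0_map: dict[str, float] = {}
    if pooled_qvalues:
        q, pi0 = estimate_qvalues(results["P"].to_numpy())
        results["q"] = q
        pi0_map = {f: pi0 for f in mutant_obs}
    else:
        results["q"] = np.nan
        for feat, grp in results.groupby("feature", sort=False):
            q, pi0 = estimate_qvalues(grp["P"].to_numpy())
            results.loc[grp.index, "q"] = q
            pi0_map[str(feat)] = pi0
    results["significant"] = results["q"] <= fdr
    summary = call_abnormal(results, fdr=fdr)
    return results, summary, pi0_map


def call_abnormal(results: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Per-mutant summary: number of significant features (q <= fdr) and
    the abnormal flag (significant in at least one feature)."""
    if len(results) == 0:
        raise ValueError("empty result table")
    sig = results["q"] <= fdr
    n_sig = sig.groupby(results["mutant"]).sum()
    out = pd.DataFrame({"n_significant_features": n_sig.astype(int)})
    out["abnormal"] = out["n_significant_features"] >= 1
    return out
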
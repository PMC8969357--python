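"""Unimodality assessment via family-specific finite mixtures.

A feature is called unimodal when mixture-model-based clustering under its
assigned family selects a single component: mixtures with c = 1..c_max
components are fitted by EM (multiple restarts), the component count is
chosen by minimum BIC, and a majority vote over several randomized
repetitions gives the final c*.  Features that look multimodal are given
two rescue stages, because apparent multimodality is often technical:

1. confounder adjustment — a generalized linear model of the feature on a
   single categorical factor (the observed combination of confounder
   levels, a one-way ANOVA layout) under the assigned family's canonical
   location link; estimated group effects are removed on the link scale and
   the grand location restored;
2. outlier trimming — observations in the extreme two-sided 1% tail of the
   fitted single-component model (CDF < 0.005 or > 0.995) are removed, at
   most 2% of the data.

The verdict at each stage is recorded; the feature is finally unimodal iff
any stage selects c = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distributions import (Family, FitResult, fit_mle, get_family,
                            information_criteria)

__all__ = [
    "MixtureFit",
    "StageResult",
    "ModalityReport",
    "fit_mixture_em",
    "select_components",
    "adjust_confounders",
    "trim_outliers_one_percentile",
    "assess_modality",
]


@dataclass
class MixtureFit:
    family: str
    c: int
    weights: np.ndarray
    components: list[np.ndarray]       # per-component parameter vectors
    loglik: float
    bic: float
    n: int
    n_restarts: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class StageResult:
    stage: str                         # raw | confounder-adjusted | outlier-trimmed
    c_star: int
    bic_table: dict[int, float]
    votes: dict[int, int]


@dataclass
class ModalityReport:
    feature_id: str
    family: str
    stages: list[StageResult]
    removed_outliers: list[int]
    final_unimodal: bool
    final_stage: Optional[str]
    processed_data: np.ndarray         # data after the applied rescue stages
    confounder_effects: Optional[dict] = None


def _mixture_k(fam: Family, c: int) -> int:
    return c * fam.k + (c - 1)


def _component_logpdf(fam: Family, components, x) -> np.ndarray:
    fn = getattr(fam, "_logpdf_fast", None) or fam._logpdf
    with np.errstate(all="ignore"):
        return np.stack([fn(th, x) for th in components], axis=1)


def fit_mixture_em(family, data, c: int, n_restarts: int = 10, seed=0,
                   tol: float = 1e-8, max_iter: int = 500) -> MixtureFit:
    """EM fit of a c-component mixture of one family.

    Restart 0 initializes responsibilities from a quantile-sliced partition
    of the data; further restarts use random responsibilities.  The best
    restart by log-likelihood wins.  A component whose weight falls below
    1/n (or whose fit degenerates) aborts the run; if every restart
    collapses the fit is flagged non-converged.
    """
    fam = get_family(family)
    x = fam._prep(data)
    n = len(x)
    if c < 1:
        raise ValueError("c must be >= 1")
    if n < 3 * c:
        raise ValueError(f"need n >= 3c ({3 * c}), got {n}")
    if c == 1:
        fr = fit_mle(fam, x, compute_se=False)
        _, bic = information_criteria(fr.loglik, _mixture_k(fam, 1), n)
        return MixtureFit(family=fam.name, c=1, weights=np.array([1.0]),
                          components=[fr.theta], loglik=fr.loglik, bic=bic,
                          n=n, n_restarts=1, converged=fr.converged,
                          loglik_trace=[fr.loglik])

    rng = np.random.default_rng(seed)
    order_stat = x[:, 0] / np.maximum(x[:, 1], 1) if fam.proportion else x
    best = None
    for r in range(n_restarts):
        if r == 0:
            # quantile-sliced hard partition
            ranks = np.argsort(np.argsort(order_stat, kind="stable"))
            lab = np.minimum((ranks * c) // n, c - 1)
            resp = np.zeros((n, c))
            resp[np.arange(n), lab] = 1.0
            resp = 0.9 * resp + 0.1 / c
        else:
            resp = rng.dirichlet(np.ones(c), size=n)
        fit = _em_run(fam, x, c, resp, tol, max_iter)
        if fit is None:
            continue
        ll, pi, comps, trace = fit
        if best is None or ll > best[0]:
            best = (ll, pi, comps, trace)
    if best is None:
        return MixtureFit(family=fam.name, c=c, weights=np.full(c, 1.0 / c),
                          components=[], loglik=-np.inf, bic=np.inf, n=n,
                          n_restarts=n_restarts, converged=False)
    ll, pi, comps, trace = best
    _, bic = information_criteria(ll, _mixture_k(fam, c), n)
    return MixtureFit(family=fam.name, c=c, weights=pi, components=comps,
                      loglik=ll, bic=bic, n=n, n_restarts=n_restarts,
                      converged=True, loglik_trace=trace)


def _em_run(fam, x, c, resp, tol, max_iter):
    n = len(x)
    ll_prev = -np.inf
    trace = []
    prev_comps: list = [None] * c
    for it in range(max_iter):
        pi = resp.mean(axis=0)
        if np.any(pi < 1.0 / n):
            return None  # component collapse
        comps = []
        for j in range(c):
            w = resp[:, j]
            try:
                closed = fam._fit_closed(x, w)
                if closed is not None:
                    theta, conv = np.asarray(closed, float), True
                else:
                    theta, _, conv, _ = fam.fit(x, weights=w,
                                                start=prev_comps[j])
            except (ValueError, FloatingPointError):
                return None
            if not conv or not np.all(np.isfinite(theta)):
                return None
            comps.append(np.asarray(theta))
        prev_comps = comps
        lp = _component_logpdf(fam, comps, x) + np.log(pi)
        mx = lp.max(axis=1)
        norm = mx + np.log(np.exp(lp - mx[:, None]).sum(axis=1))
        ll = float(np.sum(norm))
        if not np.isfinite(ll):
            return None
        trace.append(ll)
        resp = np.exp(lp - norm[:, None])
        if ll - ll_prev < tol * max(abs(ll), 1.0) and it > 0:
            break
        ll_prev = ll
    return ll, pi, comps, trace


def select_components(data, family, c_max: int = 10, n_restarts: int = 10,
                      n_randomizations: int = 10, seed=0,
                      tol: float = 1e-8, max_iter: int = 500
                      ) -> tuple[int, dict[int, float], dict[int, int]]:
    """Choose the number of mixture components by BIC with a majority vote
    over randomized EM repetitions.

    For each of ``n_randomizations`` repetitions (distinct restart seed
    streams) every feasible c (n >= 3c, c <= c_max) is fitted and the
    minimum-BIC c recorded; c* is the modal choice, ties going to the
    smaller c.  Returns (c*, BIC table of the first repetition, votes).
    """
    fam = get_family(family)
    x = fam._prep(data)
    n = len(x)
    cs = [c for c in range(1, c_max + 1) if n >= 3 * c]
    if not cs:
        raise ValueError("too few observations for even a 1-component fit")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_randomizations)
    votes: dict[int, int] = {}
    first_table: dict[int, float] = {}
    for r in range(n_randomizations):
        table = {}
        for c in cs:
            mf = fit_mixture_em(fam, x, c, n_restarts=n_restarts,
                                seed=int(child_seeds[r]), tol=tol,
                                max_iter=max_iter)
            table[c] = mf.bic if mf.converged else np.inf
        if r == 0:
            first_table = dict(table)
        if all(not np.isfinite(v) for v in table.values()):
            continue
        c_pick = min(table, key=lambda c: (table[c], c))
        votes[c_pick] = votes.get(c_pick, 0) + 1
    if not votes:
        raise RuntimeError("no component count converged in any repetition")
    top = max(votes.values())
    c_star = min(c for c, v in votes.items() if v == top)
    return c_star, first_table, votes


def adjust_confounders(data, levels, family, min_per_level: int = 2
                       ) -> tuple[np.ndarray, dict]:
    """Remove confounder-group effects from one feature.

    ``levels`` gives one categorical label per observation (the combination
    of all confounder factors).  A single-factor location model under the
    family's canonical link is fitted: the grand location and each group's
    location (dispersion held at the grand fit), and each observation is
    shifted on the link scale by minus its group effect.  Count-type data
    are adjusted by quantile mapping through the group CDF back through the
    grand CDF.  Groups with fewer than ``min_per_level`` observations keep
    an effect of zero (with a warning).
    """
    fam = get_family(family)
    x = fam._prep(data)
    levels = np.asarray(levels)
    if len(levels) != len(x):
        raise ValueError("levels must align with observations")
    grand = fit_mle(fam, x, compute_se=False)
    uniq = np.unique(levels)
    masks, etas, small = {}, {}, []
    for lev in uniq:
        mask = levels == lev
        masks[lev] = mask
        m = int(mask.sum())
        if m < min_per_level:
            warnings.warn(
                f"confounder level {lev!r} has {m} sample(s); effect set to 0",
                stacklevel=2)
            small.append(lev)
            continue
        etas[lev] = fam.link_fn(fam.location_mle(x[mask], grand.theta))
    if etas:
        # sum-to-zero parameterization: the grand location is the
        # sample-weighted mean of the level locations on the link scale
        eta0 = sum(etas[lev] * masks[lev].sum() for lev in etas) \
            / sum(masks[lev].sum() for lev in etas)
    else:
        eta0 = fam.link_fn(fam.location(grand.theta))
    adjusted = np.array(x, dtype=float, copy=True)
    effects: dict = {str(lev): 0.0 for lev in small}
    target_theta = fam.set_location(grand.theta, fam.inv_link_fn(eta0))
    for lev, eta_g in etas.items():
        mask = masks[lev]
        effects[str(lev)] = eta_g - eta0
        if fam.discrete:
            adjusted[mask] = _quantile_map_counts(
                fam, x[mask], target_theta, fam.inv_link_fn(eta_g))
        else:
            adjusted[mask] = fam.shift_data(x[mask], grand.theta,
                                            -(eta_g - eta0))
    return adjusted, {"family": fam.name, "grand_location_link": eta0,
                      "effects": effects}


def _quantile_map_counts(fam, x, theta_grand, loc_g):
    """Map count observations from the group fit to the grand fit through
    mid-CDF quantile residuals."""
    theta_g = fam.set_location(theta_grand, loc_g)
    out = np.array(x, dtype=float, copy=True)
    if fam.proportion:
        k, n = x[:, 0], x[:, 1]
        hi = fam._cdf(theta_g, x)
        lo = np.where(k > 0, fam._cdf(theta_g, np.column_stack([k - 1, n])), 0.0)
        u = np.clip(0.5 * (lo + hi), 1e-10, 1 - 1e-10)
        newk = np.array([fam.ppf_n(theta_grand, ui, ni)
                         for ui, ni in zip(u, n)])
        out[:, 0] = newk
    else:
        hi = fam._cdf(theta_g, x)
        lo = np.where(x > 0, fam._cdf(theta_g, x - 1), 0.0)
        u = np.clip(0.5 * (lo + hi), 1e-10, 1 - 1e-10)
        out = np.asarray(fam._ppf(theta_grand, u), dtype=float)
    return out


def trim_outliers_one_percentile(data, fit: FitResult
                                 ) -> tuple[np.ndarray, list[int]]:
    """Remove observations in the extreme two-sided 1% tail of a fitted
    single-component model: two-sided tail mass < 0.01, i.e. CDF < 0.005 or
    CDF > 0.995.  At most ceil(2% of n) observations are removed (the most
    extreme first)."""
    fam = get_family(fit.family)
    x = fam._prep(data)
    n = len(x)
    F = fam._cdf(fit.theta, x)
    if fam.discrete:
        if fam.proportion:
            below = np.column_stack([np.maximum(x[:, 0] - 1, -1), x[:, 1]])
            Fm = np.where(x[:, 0] > 0, fam._cdf(fit.theta, below), 0.0)
        else:
            Fm = np.where(x > 0, fam._cdf(fit.theta, np.maximum(x - 1, 0)), 0.0)
        tail = 2.0 * np.minimum(F, 1.0 - Fm)
    else:
        tail = 2.0 * np.minimum(F, 1.0 - F)
    tail = np.minimum(tail, 1.0)
    cand = np.where(tail < 0.01)[0]
    cap = math.ceil(0.02 * n)
    if len(cand) > cap:
        cand = cand[np.argsort(tail[cand], kind="stable")[:cap]]
    removed = sorted(int(i) for i in cand)
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    return x[keep], removed


def assess_modality(data, assignment, levels=None, feature_id: str = "",
                    c_max: int = 10, n_restarts: int = 10,
                    n_randomizations: int = 10, seed: int = 0,
                    tol: float = 1e-8, max_iter: int = 500) -> ModalityReport:
    """Staged unimodality verdict for one feature.

    Stage 1 checks the raw data; if multimodal, stage 2 removes confounder
    effects (when ``levels`` are given) and rechecks; if still multimodal,
    stage 3 trims one-percentile outliers from the adjusted data and makes
    a final check.  ``assignment`` is the feature's
    :class:`~unimo.model_selection.FamilyAssignment` (or a family name).
    """
    family = assignment if isinstance(assignment, str) else assignment.family
    fam = get_family(family)
    x = fam._prep(data)
    kwargs = dict(c_max=c_max, n_restarts=n_restarts,
                  n_randomizations=n_randomizations, tol=tol,
                  max_iter=max_iter)
    stages: list[StageResult] = []
    removed: list[int] = []
    effects = None
    current = x

    c1, tab1, votes1 = select_components(current, fam, seed=seed, **kwargs)
    stages.append(StageResult("raw", c1, tab1, votes1))
    final_stage = "raw" if c1 == 1 else None

    if final_stage is None and levels is not None:
        current, rec = adjust_confounders(current, levels, fam)
        effects = rec
        c2, tab2, votes2 = select_components(current, fam, seed=seed + 1,
                                             **kwargs)
        stages.append(StageResult("confounder-adjusted", c2, tab2, votes2))
        if c2 == 1:
            final_stage = "confounder-adjusted"

    if final_stage is None:
        base = fit_mle(fam, current, compute_se=False)
        current, removed = trim_outliers_one_percentile(current, base)
        c3, tab3, votes3 = select_components(current, fam, seed=seed + 2,
                                             **kwargs)
        stages.append(StageResult("outlier-trimmed", c3, tab3, votes3))
        if c3 == 1:
            final_stage = "outlier-trimmed"

    return ModalityReport(
        feature_id=feature_id, family=fam.name, stages=stages,
        removed_outliers=removed, final_unimodal=final_stage is not None,
        final_stage=final_stage, processed_data=current,
        confounder_effects=effects)
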
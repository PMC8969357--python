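"""Probability families, maximum-likelihood fitting, and information criteria.

Each morphological feature is modelled by a parametric family chosen from a
catalogue keyed by data type: non-negative continuous measures (gamma,
Weibull, log-normal, inverse Gaussian, exponential), bounded ratios (beta,
logit-normal), real-valued noise residuals (Gaussian, logistic, reverse
Gumbel — the minimum-type extreme-value distribution), cell-type proportions
as (successes k, trials n) count pairs (binomial, beta-binomial), and
unbounded counts (Poisson, negative binomial).

Parameterizations (fixed throughout the package):

====================  =======================================================
family                parameters
====================  =======================================================
gamma                 shape ``alpha > 0``, scale ``theta > 0``
weibull               shape ``k > 0``, scale ``lam > 0``
lognormal             ``mu`` (log scale), ``sigma > 0``
inverse_gaussian      mean ``mu > 0``, shape ``lam > 0``
exponential           scale (= mean) ``theta > 0``
beta                  ``a > 0``, ``b > 0``
logit_normal          ``mu`` (logit scale), ``sigma > 0``
gaussian              mean ``mu``, sd ``sigma > 0``
logistic              location ``mu``, scale ``s > 0``
reverse_gumbel        location ``mu``, scale ``s > 0`` (left-skewed minimum
                      form; the mirror image of the classical Gumbel)
binomial              success probability ``p`` in (0, 1); trials per pair
beta_binomial         mean ``p`` in (0, 1), overdispersion ``rho`` in (0, 1)
poisson               rate ``lam > 0``
negative_binomial     mean ``mu > 0``, size ``k > 0`` (variance mu + mu^2/k)
====================  =======================================================

All fits are deterministic: closed forms where they exist, otherwise
quasi-Newton optimization on an unconstrained transform of the parameters
started from method-of-moments values.  Standard errors come from the
observed Fisher information (central-difference Hessian of the
log-likelihood) unless a closed form is available.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Family",
    "FitResult",
    "get_family",
    "list_families",
    "evaluate",
    "fit_mle",
    "information_criteria",
    "SupportError",
]


class SupportError(ValueError):
    """Raised when data lie outside a family's support."""


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """Return ``(AIC, BIC)`` for a model with log-likelihood ``loglik``,
    ``k`` free parameters fitted on ``n`` observations.

    AIC = -2*loglik + 2k;  BIC = -2*loglik + k*ln(n).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return -2.0 * loglik + 2.0 * k, -2.0 * loglik + k * math.log(n)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one family to one data vector."""

    family: str
    theta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    k: int
    aic: float
    bic: float
    converged: bool
    fixed_params: Optional[dict] = None
    message: str = ""

    @property
    def params(self) -> dict:
        fam = get_family(self.family)
        return dict(zip(fam.param_names, (float(v) for v in self.theta)))

    def to_json(self) -> str:
        fam = get_family(self.family)
        return json.dumps(
            {
                "family": self.family,
                "theta": self.params,
                "se": dict(zip(fam.param_names, (float(v) for v in self.se))),
                "loglik": float(self.loglik),
                "aic": float(self.aic),
                "bic": float(self.bic),
                "n": int(self.n),
                "converged": bool(self.converged),
            }
        )


# ---------------------------------------------------------------------------
# parameter transforms (natural <-> unconstrained optimizer scale)

def _to_unc(x, domain):
    if domain == "pos":
        return math.log(x)
    if domain == "unit":
        return math.log(x / (1.0 - x))
    return x


def _from_unc(x, domain):
    if domain == "pos":
        return math.exp(x)
    if domain == "unit":
        return 1.0 / (1.0 + math.exp(-x))
    return x


def _shrink_unit(y: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 values off the boundary with the standard
    (y*(n-1)+0.5)/n adjustment so that log/logit likelihoods stay finite."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        n = y.size
        y = (y * (n - 1) + 0.5) / n
    return y


class Family:
    """Base class: density/CDF/quantile evaluation, MLE, location interface.

    Subclasses define ``param_names``/``param_domains``, the scipy
    distribution mapping, and (where possible) closed-form weighted fits.
    The *location* interface exposes, for each family, the parameter that a
    mutant test or confounder model shifts: its value, its link function,
    the expected per-observation Fisher information, and a refit with the
    dispersion held fixed.
    """

    name: str = ""
    param_names: tuple[str, ...] = ()
    param_domains: tuple[str, ...] = ()
    discrete: bool = False
    proportion: bool = False  # data are (k, n) pairs
    link: str = "identity"    # identity | log | logit (link of the location)

    # -- subclass hooks ----------------------------------------------------
    def _logpdf(self, theta, x):
        raise NotImplementedError

    def _cdf(self, theta, x):
        raise NotImplementedError

    def _ppf(self, theta, q):
        raise NotImplementedError

    def _support_ok(self, x) -> np.ndarray:
        raise NotImplementedError

    def _start(self, x, w):
        """Method-of-moments starting values (natural scale)."""
        raise NotImplementedError

    def _fit_closed(self, x, w):
        """Closed-form weighted MLE, or None to use the numeric path."""
        return None

    # -- generic machinery -------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.param_names)

    def _check_theta(self, theta):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(
                f"{self.name} expects {self.k} parameters {self.param_names}, "
                f"got {theta.shape}"
            )
        for v, d, nm in zip(theta, self.param_domains, self.param_names):
            if d == "pos" and not v > 0:
                raise ValueError(f"{self.name}: {nm} must be > 0, got {v}")
            if d == "unit" and not (0 < v < 1):
                raise ValueError(f"{self.name}: {nm} must be in (0,1), got {v}")
        return theta

    def _prep(self, data):
        """Validate data against the support; return as float array."""
        x = np.asarray(data, dtype=float)
        if self.proportion:
            if x.ndim != 2 or x.shape[1] != 2:
                raise SupportError(
                    f"{self.name} expects (k, n) count pairs, got shape {x.shape}"
                )
            k, n = x[:, 0], x[:, 1]
            if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
                raise SupportError(f"{self.name}: require 0 <= k <= n, n >= 1")
        else:
            if x.ndim != 1:
                x = np.ravel(x)
            if not np.all(self._support_ok(x)):
                bad = x[~self._support_ok(x)][:3]
                raise SupportError(
                    f"{self.name}: data outside support (e.g. {bad.tolist()})"
                )
        return x

    def loglik(self, theta, data, weights=None) -> float:
        lp = self._logpdf(self._check_theta(theta), self._prep(data))
        if weights is None:
            return float(np.sum(lp))
        return float(np.sum(np.asarray(weights, float) * lp))

    def fit(self, data, weights=None, fixed_params=None, start=None):
        """Weighted MLE; returns (theta, loglik, converged, message).
        ``start`` warm-starts the numeric optimizer (ignored by closed
        forms)."""
        x = self._prep(data)
        nobs = len(x)
        if weights is None:
            w = np.ones(nobs)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (nobs,) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per observation")
        fixed = dict(fixed_params or {})
        if not fixed:
            closed = self._fit_closed(x, w)
            if closed is not None:
                theta = np.asarray(closed, dtype=float)
                return theta, self.loglik(theta, x, w), True, "closed-form"
        return self._fit_numeric(x, w, fixed, start=start)

    def _fit_numeric(self, x, w, fixed, start=None):
        if start is not None:
            start = np.asarray(start, dtype=float)
        else:
            start = np.asarray(self._start(x, w), dtype=float)
        free_idx = [i for i, nm in enumerate(self.param_names) if nm not in fixed]
        if not free_idx:
            theta = np.array([fixed[nm] for nm in self.param_names], float)
            return theta, self.loglik(theta, x, w), True, "all-fixed"
        domains = [self.param_domains[i] for i in free_idx]

        def unpack(z):
            theta = start.copy()
            for j, i in enumerate(free_idx):
                theta[i] = _from_unc(z[j], domains[j])
            for i, nm in enumerate(self.param_names):
                if nm in fixed:
                    theta[i] = fixed[nm]
            return theta

        logpdf = getattr(self, "_logpdf_fast", None) or self._logpdf

        def nll(z):
            theta = unpack(z)
            with np.errstate(all="ignore"):
                lp = logpdf(theta, x)
            val = -np.sum(w * lp)
            return val if np.isfinite(val) else 1e300

        z0 = np.array(
            [_to_unc(start[i], self.param_domains[i]) for i in free_idx]
        )
        res = optimize.minimize(nll, z0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        if not res.success:
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-10,
                                              "maxiter": 2000})
            if res2.fun <= res.fun:
                res = res2
        theta = unpack(res.x)
        grad = optimize.approx_fprime(res.x, nll, 1e-6)
        gtol = 1e-4 * max(abs(float(res.fun)), 1.0)
        converged = bool(np.isfinite(res.fun)
                         and (res.success or np.linalg.norm(grad) < gtol))
        return theta, -float(res.fun), converged, str(res.message)

    # -- standard errors ---------------------------------------------------
    def standard_errors(self, theta, data, weights=None, fixed_params=None):
        """SEs from the observed Fisher information (numeric Hessian of the
        log-likelihood on the natural scale, central differences)."""
        theta = self._check_theta(theta)
        x = self._prep(data)
        w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
        fixed = set((fixed_params or {}).keys())
        free = [i for i, nm in enumerate(self.param_names) if nm not in fixed]
        se = np.full(self.k, np.nan)
        if not free:
            return se
        closed = self._se_closed(theta, x, w)
        if closed is not None and not fixed:
            return np.asarray(closed, dtype=float)

        def nll_free(v):
            th = theta.copy()
            th[free] = v
            with np.errstate(all="ignore"):
                return -np.sum(w * self._logpdf(th, x))

        v0 = theta[free]
        h = 1e-5 * np.maximum(np.abs(v0), 1.0)
        m = len(free)
        H = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h[i]
                ej = np.zeros(m); ej[j] = h[j]
                f_pp = nll_free(v0 + ei + ej)
                f_pm = nll_free(v0 + ei - ej)
                f_mp = nll_free(v0 - ei + ej)
                f_mm = nll_free(v0 - ei - ej)
                H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            with np.errstate(invalid="ignore"):
                se_free = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            se_free = np.full(m, np.nan)
        se[free] = se_free
        return se

    def _se_closed(self, theta, x, w):
        return None

    # -- location interface (mutant testing, confounder models) -----------
    def location(self, theta) -> float:
        """The family's location parameter on its natural scale."""
        raise NotImplementedError

    def set_location(self, theta, loc) -> np.ndarray:
        """Return parameters with the location replaced, dispersion kept."""
        raise NotImplementedError

    def location_info(self, theta, n_trials=None) -> float:
        """Expected Fisher information for the location (per observation,
        dispersion fixed), evaluated at ``theta``."""
        raise NotImplementedError

    def location_mle(self, data, theta0) -> float:
        """Location MLE with the dispersion held at the values in theta0."""
        raise NotImplementedError

    def link_fn(self, loc):
        if self.link == "log":
            return math.log(loc)
        if self.link == "logit":
            return math.log(loc / (1 - loc))
        return loc

    def inv_link_fn(self, eta):
        if self.link == "log":
            return math.exp(eta)
        if self.link == "logit":
            return 1.0 / (1.0 + math.exp(-eta))
        return eta

    def shift_data(self, data, theta, delta_eta):
        """Shift observations by ``delta_eta`` on the link scale (used to
        remove confounder effects and to plant synthetic effects)."""
        x = np.asarray(data, dtype=float)
        if self.link == "log":
            return x * math.exp(delta_eta)
        if self.link == "logit":
            with np.errstate(divide="ignore"):
                lg = np.log(x / (1 - x))
            return 1.0 / (1.0 + np.exp(-(lg + delta_eta)))
        return x + delta_eta


# ---------------------------------------------------------------------------
# continuous non-negative families

class Gamma(Family):
    name = "gamma"
    param_names = ("shape", "scale")
    param_domains = ("pos", "pos")
    link = "log"

    def _support_ok(self, x):
        return x > 0

    def _logpdf(self, theta, x):
        return stats.gamma.logpdf(x, theta[0], scale=theta[1])

    def _logpdf_fast(self, theta, x):
        a, sc = theta
        return ((a - 1.0) * np.log(x) - x / sc
                - a * math.log(sc) - special.gammaln(a))

    def _cdf(self, theta, x):
        return stats.gamma.cdf(x, theta[0], scale=theta[1])

    def _ppf(self, theta, q):
        return stats.gamma.ppf(q, theta[0], scale=theta[1])

    def _start(self, x, w):
        m = np.average(x, weights=w)
        v = np.average((x - m) ** 2, weights=w)
        v = max(v, 1e-12 * m * m + 1e-300)
        return (m * m / v, v / m)

    def _fit_closed(self, x, w):
        # weighted Newton on the shape via the profile likelihood
        m = np.average(x, weights=w)
        mlog = np.average(np.log(x), weights=w)
        s = math.log(m) - mlog
        if s <= 0:  # numerically constant data
            return None
        a = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        for _ in range(100):
            num = math.log(a) - special.digamma(a) - s
            den = 1.0 / a - special.polygamma(1, a)
            step = num / den
            a_new = a - step
            if a_new <= 0:
                a_new = a / 2.0
            if abs(a_new - a) < 1e-12 * a:
                a = a_new
                break
            a = a_new
        return (a, m / a)

    def location(self, theta):
        return theta[0] * theta[1]

    def set_location(self, theta, loc):
        return np.array([theta[0], loc / theta[0]])

    def location_info(self, theta, n_trials=None):
        mu = self.location(theta)
        return theta[0] / mu ** 2

    def location_mle(self, data, theta0):
        return float(np.mean(self._prep(data)))


class Weibull(Family):
    name = "weibull"
    param_names = ("shape", "scale")
    param_domains = ("pos", "pos")
    link = "log"

    def _support_ok(self, x):
        return x > 0

    def _logpdf(self, theta, x):
        return stats.weibull_min.logpdf(x, theta[0], scale=theta[1])

    def _logpdf_fast(self, theta, x):
        k, lam = theta
        z = x / lam
        return math.log(k / lam) + (k - 1.0) * np.log(z) - z ** k

    def _cdf(self, theta, x):
        return stats.weibull_min.cdf(x, theta[0], scale=theta[1])

    def _ppf(self, theta, q):
        return stats.weibull_min.ppf(q, theta[0], scale=theta[1])

    def _start(self, x, w):
        lx = np.log(x)
        m, s = np.average(lx, weights=w), math.sqrt(np.average(
            (lx - np.average(lx, weights=w)) ** 2, weights=w))
        shape = max(1e-2, 1.2 / max(s, 1e-6))
        scale = math.exp(m + 0.5772 / shape)
        return (shape, scale)

    def _fit_closed(self, x, w):
        lx = np.log(x)
        wl = np.average(lx, weights=w)

        def g(k):
            xk = x ** k
            return np.average(xk * lx, weights=w) / np.average(xk, weights=w) \
                - 1.0 / k - wl

        k0 = self._start(x, w)[0]
        lo, hi = k0, k0
        try:
            while g(lo) > 0 and lo > 1e-6:
                lo /= 2.0
            while g(hi) < 0 and hi < 1e6:
                hi *= 2.0
            k = optimize.brentq(g, lo, hi, xtol=1e-12)
        except ValueError:
            return None
        scale = float(np.average(x ** k, weights=w)) ** (1.0 / k)
        return (k, scale)

    def location(self, theta):
        return theta[1] * special.gamma(1.0 + 1.0 / theta[0])

    def set_location(self, theta, loc):
        return np.array([theta[0], loc / special.gamma(1.0 + 1.0 / theta[0])])

    def location_info(self, theta, n_trials=None):
        mu = self.location(theta)
        return theta[0] ** 2 / mu ** 2

    def location_mle(self, data, theta0):
        k = theta0[0]
        x = self._prep(data)
        return float(np.mean(x ** k) ** (1.0 / k) * special.gamma(1.0 + 1.0 / k))


class LogNormal(Family):
    name = "lognormal"
    param_names = ("mu", "sigma")
    param_domains = ("real", "pos")
    link = "log"

    def _support_ok(self, x):
        return x > 0

    def _logpdf(self, theta, x):
        return stats.lognorm.logpdf(x, theta[1], scale=math.exp(theta[0]))

    def _cdf(self, theta, x):
        return stats.lognorm.cdf(x, theta[1], scale=math.exp(theta[0]))

    def _ppf(self, theta, q):
        return stats.lognorm.ppf(q, theta[1], scale=math.exp(theta[0]))

    def _start(self, x, w):
        return self._fit_closed(x, w)

    def _fit_closed(self, x, w):
        lx = np.log(x)
        mu = np.average(lx, weights=w)
        sd = math.sqrt(np.average((lx - mu) ** 2, weights=w))
        return (mu, max(sd, 1e-12))

    def _se_closed(self, theta, x, w):
        n = np.sum(w)
        return (theta[1] / math.sqrt(n), theta[1] / math.sqrt(2 * n))

    def location(self, theta):
        return math.exp(theta[0])

    def set_location(self, theta, loc):
        return np.array([math.log(loc), theta[1]])

    def location_info(self, theta, n_trials=None):
        mu = self.location(theta)
        return 1.0 / (theta[1] ** 2 * mu ** 2)

    def location_mle(self, data, theta0):
        return float(math.exp(np.mean(np.log(self._prep(data)))))


class InverseGaussian(Family):
    name = "inverse_gaussian"
    param_names = ("mu", "lam")
    param_domains = ("pos", "pos")
    link = "log"

    def _support_ok(self, x):
        return x > 0

    def _sp(self, theta):
        mu, lam = theta
        return dict(mu=mu / lam, scale=lam)

    def _logpdf(self, theta, x):
        return stats.invgauss.logpdf(x, **self._sp(theta))

    def _cdf(self, theta, x):
        return stats.invgauss.cdf(x, **self._sp(theta))

    def _ppf(self, theta, q):
        return stats.invgauss.ppf(q, **self._sp(theta))

    def _start(self, x, w):
        return self._fit_closed(x, w)

    def _fit_closed(self, x, w):
        mu = np.average(x, weights=w)
        inv = np.average(1.0 / x - 1.0 / mu, weights=w)
        return (mu, 1.0 / max(inv, 1e-12))

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc, theta[1]])

    def location_info(self, theta, n_trials=None):
        return theta[1] / theta[0] ** 3

    def location_mle(self, data, theta0):
        return float(np.mean(self._prep(data)))


class Exponential(Family):
    name = "exponential"
    param_names = ("scale",)
    param_domains = ("pos",)
    link = "log"

    def _support_ok(self, x):
        return x >= 0

    def _logpdf(self, theta, x):
        return stats.expon.logpdf(x, scale=theta[0])

    def _cdf(self, theta, x):
        return stats.expon.cdf(x, scale=theta[0])

    def _ppf(self, theta, q):
        return stats.expon.ppf(q, scale=theta[0])

    def _start(self, x, w):
        return (np.average(x, weights=w),)

    def _fit_closed(self, x, w):
        return (float(np.average(x, weights=w)),)

    def _se_closed(self, theta, x, w):
        return (theta[0] / math.sqrt(np.sum(w)),)

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc])

    def location_info(self, theta, n_trials=None):
        return 1.0 / theta[0] ** 2

    def location_mle(self, data, theta0):
        return float(np.mean(self._prep(data)))


# ---------------------------------------------------------------------------
# bounded-ratio families

class Beta(Family):
    name = "beta"
    param_names = ("a", "b")
    param_domains = ("pos", "pos")
    link = "logit"

    def _support_ok(self, x):
        return (x > 0) & (x < 1)

    def _logpdf(self, theta, x):
        return stats.beta.logpdf(x, theta[0], theta[1])

    def _logpdf_fast(self, theta, x):
        a, b = theta
        return ((a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x)
                - special.betaln(a, b))

    def _cdf(self, theta, x):
        return stats.beta.cdf(x, theta[0], theta[1])

    def _ppf(self, theta, q):
        return stats.beta.ppf(q, theta[0], theta[1])

    def _prep(self, data):
        x = np.asarray(data, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise SupportError("beta: data outside [0, 1]")
        return _shrink_unit(x)

    def _start(self, x, w):
        m = np.average(x, weights=w)
        v = max(np.average((x - m) ** 2, weights=w), 1e-10)
        phi = max(m * (1 - m) / v - 1.0, 1e-2)
        return (m * phi, (1 - m) * phi)

    def _fit_closed(self, x, w):
        # Newton on (a, b) using the sufficient statistics E[ln x], E[ln(1-x)]
        sw = np.sum(w)
        t1 = np.dot(w, np.log(x)) / sw
        t2 = np.dot(w, np.log1p(-x)) / sw
        a, b = self._start(x, w)
        for _ in range(200):
            dg_ab = special.digamma(a + b)
            g = np.array([special.digamma(a) - dg_ab - t1,
                          special.digamma(b) - dg_ab - t2])
            tg_ab = special.polygamma(1, a + b)
            H = np.array([[special.polygamma(1, a) - tg_ab, -tg_ab],
                          [-tg_ab, special.polygamma(1, b) - tg_ab]])
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                return None
            a_new, b_new = a - step[0], b - step[1]
            while a_new <= 0 or b_new <= 0:
                step /= 2.0
                a_new, b_new = a - step[0], b - step[1]
            if max(abs(a_new - a), abs(b_new - b)) < 1e-10 * max(a, b, 1.0):
                return (a_new, b_new)
            a, b = a_new, b_new
        return (a, b)

    def location(self, theta):
        return theta[0] / (theta[0] + theta[1])

    def set_location(self, theta, loc):
        phi = theta[0] + theta[1]
        return np.array([loc * phi, (1 - loc) * phi])

    def location_info(self, theta, n_trials=None):
        phi = theta[0] + theta[1]
        p = theta[0] / phi
        return phi ** 2 * (special.polygamma(1, p * phi)
                           + special.polygamma(1, (1 - p) * phi))

    def location_mle(self, data, theta0):
        x = self._prep(data)
        phi = theta0[0] + theta0[1]
        target = float(np.mean(np.log(x) - np.log1p(-x)))

        def score(p):
            return (special.digamma(p * phi)
                    - special.digamma((1 - p) * phi)) - target

        return float(optimize.brentq(score, 1e-9, 1 - 1e-9, xtol=1e-12))


class LogitNormal(Family):
    """Gaussian on the logit scale; the fit is exactly a Gaussian fit of
    logit-transformed data."""

    name = "logit_normal"
    param_names = ("mu", "sigma")
    param_domains = ("real", "pos")
    link = "logit"

    def _support_ok(self, x):
        return (x > 0) & (x < 1)

    def _prep(self, data):
        x = np.asarray(data, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise SupportError("logit_normal: data outside [0, 1]")
        return _shrink_unit(x)

    @staticmethod
    def _logit(x):
        return np.log(x) - np.log1p(-x)

    def _logpdf(self, theta, x):
        z = self._logit(x)
        return stats.norm.logpdf(z, theta[0], theta[1]) - np.log(x) - np.log1p(-x)

    def _logpdf_fast(self, theta, x):
        lx, l1mx = np.log(x), np.log1p(-x)
        z = lx - l1mx
        return (-0.5 * ((z - theta[0]) / theta[1]) ** 2 - math.log(theta[1])
                - _LOG_SQRT_2PI - lx - l1mx)

    def _cdf(self, theta, x):
        return stats.norm.cdf(self._logit(x), theta[0], theta[1])

    def _ppf(self, theta, q):
        return special.expit(stats.norm.ppf(q, theta[0], theta[1]))

    def _start(self, x, w):
        return self._fit_closed(x, w)

    def _fit_closed(self, x, w):
        z = self._logit(x)
        mu = np.average(z, weights=w)
        sd = math.sqrt(np.average((z - mu) ** 2, weights=w))
        return (mu, max(sd, 1e-12))

    def _se_closed(self, theta, x, w):
        n = np.sum(w)
        return (theta[1] / math.sqrt(n), theta[1] / math.sqrt(2 * n))

    def location(self, theta):
        return special.expit(theta[0])  # natural-scale median

    def set_location(self, theta, loc):
        return np.array([special.logit(loc), theta[1]])

    def location_info(self, theta, n_trials=None):
        # information for the logit-scale mean; Wald Z is computed on that scale
        p = special.expit(theta[0])
        return 1.0 / (theta[1] ** 2 * (p * (1 - p)) ** 2)

    def location_mle(self, data, theta0):
        z = self._logit(self._prep(data))
        return float(special.expit(np.mean(z)))


# ---------------------------------------------------------------------------
# real-valued families

class Gaussian(Family):
    name = "gaussian"
    param_names = ("mu", "sigma")
    param_domains = ("real", "pos")
    link = "identity"

    def _support_ok(self, x):
        return np.isfinite(x)

    def _logpdf(self, theta, x):
        return stats.norm.logpdf(x, theta[0], theta[1])

    def _cdf(self, theta, x):
        return stats.norm.cdf(x, theta[0], theta[1])

    def _ppf(self, theta, q):
        return stats.norm.ppf(q, theta[0], theta[1])

    def _logpdf_fast(self, theta, x):
        mu, sd = theta
        return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI

    def _start(self, x, w):
        return self._fit_closed(x, w)

    def _fit_closed(self, x, w):
        sw = np.sum(w)
        mu = np.dot(w, x) / sw
        var = np.dot(w, (x - mu) ** 2) / sw
        if var <= 0:
            raise ValueError("gaussian fit requires non-constant data")
        return (mu, math.sqrt(var))

    def _se_closed(self, theta, x, w):
        n = np.sum(w)
        return (theta[1] / math.sqrt(n), theta[1] / math.sqrt(2 * n))

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc, theta[1]])

    def location_info(self, theta, n_trials=None):
        return 1.0 / theta[1] ** 2

    def location_mle(self, data, theta0):
        return float(np.mean(self._prep(data)))


class Logistic(Family):
    name = "logistic"
    param_names = ("mu", "s")
    param_domains = ("real", "pos")
    link = "identity"

    def _support_ok(self, x):
        return np.isfinite(x)

    def _logpdf(self, theta, x):
        return stats.logistic.logpdf(x, theta[0], theta[1])

    def _logpdf_fast(self, theta, x):
        z = (x - theta[0]) / theta[1]
        return -z - 2.0 * np.log1p(np.exp(-z)) - math.log(theta[1])

    def _cdf(self, theta, x):
        return stats.logistic.cdf(x, theta[0], theta[1])

    def _ppf(self, theta, q):
        return stats.logistic.ppf(q, theta[0], theta[1])

    def _start(self, x, w):
        mu = np.average(x, weights=w)
        sd = math.sqrt(np.average((x - mu) ** 2, weights=w))
        return (mu, max(sd * math.sqrt(3.0) / math.pi, 1e-12))

    def _fit_closed(self, x, w):
        # damped Newton on (mu, s); the score has a closed form through the
        # logistic CDF, the Hessian is finite-differenced from it
        sw = float(np.sum(w))
        mu, s = self._start(x, w)

        def ll(mu, s):
            z = (x - mu) / s
            return float(np.dot(w, -z - 2.0 * np.logaddexp(0.0, -z))
                         - sw * math.log(s))

        def grad(mu, s):
            z = (x - mu) / s
            t = 2.0 * special.expit(z) - 1.0
            return np.array([np.dot(w, t) / s,
                             (np.dot(w, t * z) - sw) / s])

        cur = ll(mu, s)
        for _ in range(100):
            g = grad(mu, s)
            if np.linalg.norm(g) < 1e-9 * max(sw, 1.0):
                break
            h = 1e-6 * max(s, 1e-6)
            H = np.column_stack([(grad(mu + h, s) - g) / h,
                                 (grad(mu, s + h) - g) / h])
            H = 0.5 * (H + H.T)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                return None
            stp = 1.0
            for _ in range(40):
                mn, sn = mu - stp * step[0], s - stp * step[1]
                if sn > 1e-12:
                    new = ll(mn, sn)
                    if new >= cur - 1e-12:
                        break
                stp /= 2.0
            else:
                break
            done = max(abs(mn - mu), abs(sn - s)) < 1e-11 * max(abs(mu), s, 1.0)
            mu, s, cur = mn, sn, new
            if done:
                break
        return (mu, s)

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc, theta[1]])

    def location_info(self, theta, n_trials=None):
        return 1.0 / (3.0 * theta[1] ** 2)

    def location_mle(self, data, theta0):
        x = self._prep(data)
        if len(x) == 1:
            return float(x[0])
        res = optimize.minimize_scalar(
            lambda m: -np.sum(stats.logistic.logpdf(x, m, theta0[1])),
            bracket=(np.min(x), np.max(x) + 1e-9))
        return float(res.x)


class ReverseGumbel(Family):
    """Minimum-type (left-skewed) type I extreme-value distribution."""

    name = "reverse_gumbel"
    param_names = ("mu", "s")
    param_domains = ("real", "pos")
    link = "identity"

    def _support_ok(self, x):
        return np.isfinite(x)

    def _logpdf(self, theta, x):
        return stats.gumbel_l.logpdf(x, theta[0], theta[1])

    def _logpdf_fast(self, theta, x):
        z = (x - theta[0]) / theta[1]
        return z - np.exp(z) - math.log(theta[1])

    def _cdf(self, theta, x):
        return stats.gumbel_l.cdf(x, theta[0], theta[1])

    def _ppf(self, theta, q):
        return stats.gumbel_l.ppf(q, theta[0], theta[1])

    def _start(self, x, w):
        mu = np.average(x, weights=w)
        sd = math.sqrt(np.average((x - mu) ** 2, weights=w))
        s = max(sd * math.sqrt(6.0) / math.pi, 1e-12)
        return (mu - 0.5772 * s, s)  # mean = mu - gamma*s for the min form

    def _fit_closed(self, x, w):
        # weighted MLE via the max-form Gumbel of z = -x: the profile score
        # for the scale is one-dimensional and monotone
        sw = np.sum(w)
        z = -x
        zbar = np.dot(w, z) / sw
        z0 = z - z.min()  # e^{-z0/s} <= 1: overflow-safe, shifts cancel

        def g(s):
            e = np.exp(-z0 / s)
            return s - zbar + np.dot(w, z * e) / np.dot(w, e)

        s0 = self._start(x, w)[1]
        lo = hi = s0
        try:
            it = 0
            while g(lo) > 0 and it < 80:
                lo /= 2.0
                it += 1
            it = 0
            while g(hi) < 0 and it < 80:
                hi *= 2.0
                it += 1
            s = optimize.brentq(g, lo, hi, xtol=1e-12)
        except (ValueError, FloatingPointError):
            return None
        e = np.exp(-z0 / s)
        loc_r = -s * math.log(np.dot(w, e) / sw) + z.min()
        return (-loc_r, s)

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc, theta[1]])

    def location_info(self, theta, n_trials=None):
        return 1.0 / theta[1] ** 2

    def location_mle(self, data, theta0):
        x = self._prep(data)
        if len(x) == 1:
            return float(x[0])
        s = theta0[1]
        # closed-form profile MLE of the location for the min-Gumbel
        return float(s * math.log(np.mean(np.exp(x / s))))


# ---------------------------------------------------------------------------
# proportion (count-pair) families

class Binomial(Family):
    name = "binomial"
    param_names = ("p",)
    param_domains = ("unit",)
    discrete = True
    proportion = True
    link = "logit"

    def _logpdf(self, theta, x):
        return stats.binom.logpmf(x[:, 0], x[:, 1].astype(int), theta[0])

    def _cdf(self, theta, x):
        return stats.binom.cdf(x[:, 0], x[:, 1].astype(int), theta[0])

    def _ppf(self, theta, q):
        raise NotImplementedError("binomial quantile needs a trial count")

    def ppf_n(self, theta, q, n_trials):
        return stats.binom.ppf(q, int(n_trials), theta[0])

    def _start(self, x, w):
        return self._fit_closed(x, w)

    def _fit_closed(self, x, w):
        p = np.sum(w * x[:, 0]) / np.sum(w * x[:, 1])
        return (min(max(p, 1e-12), 1 - 1e-12),)

    def _se_closed(self, theta, x, w):
        p = theta[0]
        return (math.sqrt(p * (1 - p) / np.sum(w * x[:, 1])),)

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc])

    def location_info(self, theta, n_trials=None):
        n = 1.0 if n_trials is None else float(n_trials)
        return n / (theta[0] * (1 - theta[0]))

    def location_mle(self, data, theta0):
        x = self._prep(data)
        p = float(np.sum(x[:, 0]) / np.sum(x[:, 1]))
        return min(max(p, 1e-12), 1 - 1e-12)


class BetaBinomial(Family):
    """Binomial with a beta-distributed success probability; ``rho`` is the
    intra-class correlation (variance n*p*(1-p)*(1+(n-1)*rho))."""

    name = "beta_binomial"
    param_names = ("p", "rho")
    param_domains = ("unit", "unit")
    discrete = True
    proportion = True
    link = "logit"

    @staticmethod
    def _ab(theta):
        p, rho = theta
        s = (1.0 - rho) / rho
        return p * s, (1.0 - p) * s

    def _logpdf(self, theta, x):
        a, b = self._ab(theta)
        return stats.betabinom.logpmf(x[:, 0], x[:, 1].astype(int), a, b)

    def _cdf(self, theta, x):
        a, b = self._ab(theta)
        return stats.betabinom.cdf(x[:, 0], x[:, 1].astype(int), a, b)

    def _ppf(self, theta, q):
        raise NotImplementedError("beta-binomial quantile needs a trial count")

    def ppf_n(self, theta, q, n_trials):
        a, b = self._ab(theta)
        return stats.betabinom.ppf(q, int(n_trials), a, b)

    def _start(self, x, w):
        k, n = x[:, 0], x[:, 1]
        p = np.sum(w * k) / np.sum(w * n)
        p = min(max(p, 1e-6), 1 - 1e-6)
        r = k / n
        v = np.average((r - p) ** 2, weights=w)
        nbar = np.average(n, weights=w)
        denom = p * (1 - p) * (1 - 1 / nbar)
        rho = (v - p * (1 - p) / nbar) / denom if denom > 0 else 0.01
        return (p, min(max(rho, 1e-4), 0.99))

    def _fit_closed(self, x, w):
        # Newton on (a, b) with analytic digamma/trigamma derivatives
        k, n = x[:, 0], x[:, 1]
        p0, rho0 = self._start(x, w)
        s = (1.0 - rho0) / rho0
        a, b = max(p0 * s, 1e-3), max((1.0 - p0) * s, 1e-3)

        def ll(a, b):
            return float(np.dot(w, special.gammaln(k + a)
                                + special.gammaln(n - k + b)
                                - special.gammaln(n + a + b)
                                - special.gammaln(a) - special.gammaln(b)
                                + special.gammaln(a + b)))

        cur = ll(a, b)
        for _ in range(100):
            dga, dgb = special.digamma(a), special.digamma(b)
            dgab = special.digamma(a + b)
            dnab = special.digamma(n + a + b)
            ga = float(np.dot(w, special.digamma(k + a) - dnab - dga + dgab))
            gb = float(np.dot(w, special.digamma(n - k + b) - dnab - dgb + dgab))
            tab = special.polygamma(1, a + b)
            tnab = special.polygamma(1, n + a + b)
            haa = float(np.dot(w, special.polygamma(1, k + a) - tnab
                               - special.polygamma(1, a) + tab))
            hbb = float(np.dot(w, special.polygamma(1, n - k + b) - tnab
                               - special.polygamma(1, b) + tab))
            hab = float(np.dot(w, tab - tnab))
            det = haa * hbb - hab * hab
            if not np.isfinite(det) or det == 0:
                return None
            da = (hbb * ga - hab * gb) / det
            db = (haa * gb - hab * ga) / det
            step = 1.0
            for _ in range(40):
                an, bn = a - step * da, b - step * db
                if an > 1e-8 and bn > 1e-8:
                    new = ll(an, bn)
                    if new >= cur - 1e-12:
                        break
                step /= 2.0
            else:
                break
            if max(abs(an - a), abs(bn - b)) < 1e-10 * max(a, b, 1.0):
                a, b, cur = an, bn, new
                break
            a, b, cur = an, bn, new
            if a + b > 1e9:  # effectively binomial; stop at the boundary
                break
        s = a + b
        return (a / s, 1.0 / (1.0 + s))

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc, theta[1]])

    def location_info(self, theta, n_trials=None):
        n = 1.0 if n_trials is None else float(n_trials)
        p, rho = theta
        return n / (p * (1 - p) * (1.0 + (n - 1.0) * rho))

    def location_mle(self, data, theta0):
        x = self._prep(data)
        rho = theta0[1]
        p0 = float(np.sum(x[:, 0]) / np.sum(x[:, 1]))
        p0 = min(max(p0, 1e-9), 1 - 1e-9)
        if len(x) == 1:
            return p0
        res = optimize.minimize_scalar(
            lambda z: -float(np.sum(self._logpdf(
                (special.expit(z), rho), x))),
            bracket=(special.logit(p0) - 1, special.logit(p0) + 1))
        return float(special.expit(res.x))


# ---------------------------------------------------------------------------
# unbounded count families

class Poisson(Family):
    name = "poisson"
    param_names = ("lam",)
    param_domains = ("pos",)
    discrete = True
    link = "log"

    def _support_ok(self, x):
        return (x >= 0) & (np.floor(x) == x)

    def _logpdf(self, theta, x):
        return stats.poisson.logpmf(x.astype(int), theta[0])

    def _cdf(self, theta, x):
        return stats.poisson.cdf(x, theta[0])

    def _ppf(self, theta, q):
        return stats.poisson.ppf(q, theta[0])

    def _start(self, x, w):
        return self._fit_closed(x, w)

    def _fit_closed(self, x, w):
        return (max(float(np.average(x, weights=w)), 1e-12),)

    def _se_closed(self, theta, x, w):
        return (math.sqrt(theta[0] / np.sum(w)),)

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc])

    def location_info(self, theta, n_trials=None):
        return 1.0 / theta[0]

    def location_mle(self, data, theta0):
        return float(np.mean(self._prep(data)))


class NegativeBinomial(Family):
    name = "negative_binomial"
    param_names = ("mu", "k")
    param_domains = ("pos", "pos")
    discrete = True
    link = "log"

    def _support_ok(self, x):
        return (x >= 0) & (np.floor(x) == x)

    def _sp(self, theta):
        mu, k = theta
        return dict(n=k, p=k / (k + mu))

    def _logpdf(self, theta, x):
        return stats.nbinom.logpmf(x.astype(int), **self._sp(theta))

    def _cdf(self, theta, x):
        return stats.nbinom.cdf(x, **self._sp(theta))

    def _ppf(self, theta, q):
        return stats.nbinom.ppf(q, **self._sp(theta))

    def _start(self, x, w):
        m = np.average(x, weights=w)
        v = np.average((x - m) ** 2, weights=w)
        k = m * m / max(v - m, 1e-6) if v > m else 100.0
        return (max(m, 1e-12), min(max(k, 1e-3), 1e4))

    def location(self, theta):
        return theta[0]

    def set_location(self, theta, loc):
        return np.array([loc, theta[1]])

    def location_info(self, theta, n_trials=None):
        mu, k = theta
        return 1.0 / (mu + mu * mu / k)

    def location_mle(self, data, theta0):
        return float(np.mean(self._prep(data)))


# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Family] = {
    f.name: f
    for f in (
        Gamma(), Weibull(), LogNormal(), InverseGaussian(), Exponential(),
        Beta(), LogitNormal(),
        Gaussian(), Logistic(), ReverseGumbel(),
        Binomial(), BetaBinomial(),
        Poisson(), NegativeBinomial(),
    )
}


def get_family(name) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def list_families() -> list[str]:
    return sorted(_REGISTRY)


def evaluate(family, theta, x, which: str):
    """Evaluate ``logpdf``, ``cdf`` or ``quantile`` of a family.

    ``logpdf`` raises :class:`SupportError` outside the support; ``cdf``
    saturates at 0/1 beyond the support edges; ``quantile`` requires
    probabilities in (0, 1).
    """
    fam = get_family(family)
    theta = fam._check_theta(theta)
    if which == "logpdf":
        xx = fam._prep(np.atleast_1d(np.asarray(x, float))
                       if not fam.proportion else np.atleast_2d(x))
        out = fam._logpdf(theta, xx)
    elif which == "cdf":
        xx = np.atleast_1d(np.asarray(x, float)) if not fam.proportion \
            else np.atleast_2d(x)
        if fam.proportion:
            out = fam._cdf(theta, xx)
        else:
            out = fam._cdf(theta, xx)
            lo_mask = ~fam._support_ok(xx)
            # scipy already saturates; just guard NaN for out-of-support
            out = np.where(np.isnan(out) & lo_mask, 0.0, out)
    elif which == "quantile":
        q = np.atleast_1d(np.asarray(x, float))
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile probabilities must lie in (0, 1)")
        out = fam._ppf(theta, q)
    else:
        raise ValueError("which must be 'logpdf', 'cdf' or 'quantile'")
    out = np.asarray(out, dtype=float)
    return float(out[0]) if out.size == 1 else out


def fit_mle(family, data, weights=None, fixed_params=None,
            compute_se: bool = True) -> FitResult:
    """Maximum-likelihood fit of ``family`` to ``data``.

    ``data`` is a 1-d array of observations, or an (n, 2) array of
    (successes, trials) pairs for the proportion families.  Optional
    non-negative ``weights`` give a weighted MLE (used by the mixture
    EM steps).  ``fixed_params`` pins named parameters at given values;
    they are excluded from k, AIC/BIC and the standard errors.
    """
    fam = get_family(family)
    x = fam._prep(data)
    n_eff = len(x)
    fixed = dict(fixed_params or {})
    k_free = fam.k - len(fixed)
    if n_eff < k_free + 1:
        raise ValueError(
            f"{fam.name}: need at least {k_free + 1} observations, got {n_eff}"
        )
    theta, ll, converged, msg = fam.fit(x, weights=weights, fixed_params=fixed)
    aic, bic = information_criteria(ll, k_free, n_eff)
    if compute_se and converged:
        se = fam.standard_errors(theta, x, weights=weights, fixed_params=fixed)
    else:
        se = np.full(fam.k, np.nan)
    return FitResult(
        family=fam.name, theta=np.asarray(theta, float), se=se,
        loglik=ll, n=n_eff, k=k_free, aic=aic, bic=bic,
        converged=converged, fixed_params=fixed or None, message=msg,
    )


def sample(family, theta, size, rng, n_trials=None):
    """Draw ``size`` observations from a family (count pairs for the
    proportion families; ``n_trials`` may be a scalar or per-draw array)."""
    fam = get_family(family)
    theta = fam._check_theta(theta)
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    if fam.proportion:
        if n_trials is None:
            raise ValueError(f"{fam.name} sampling requires n_trials")
        n = np.broadcast_to(np.asarray(n_trials, int), (size,)).copy()
        if fam.name == "binomial":
            k = rng.binomial(n, theta[0])
        else:
            a, b = BetaBinomial._ab(theta)
            k = rng.binomial(n, rng.beta(a, b, size=size))
        return np.column_stack([k, n])
    u = rng.uniform(1e-12, 1 - 1e-12, size=size)
    return np.asarray(fam._ppf(theta, u), dtype=float)
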
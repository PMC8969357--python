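"""Convert per-sample (mean, CV) pairs of a single-cell measure into
real-valued "noise" features.

The coefficient of variation of a single-cell measure depends systematically
on its mean; the biologically interesting quantity is the residual variation
after that trend is removed.  A local polynomial (LOESS) curve f is fitted
to CV versus mean across samples, and noise_i = cv_i - f(mean_i).  The
residuals are unbounded reals centred near zero and are treated as
REAL-typed features downstream, where a Gaussian (or logistic / reverse
Gumbel) model is fitted.

The trend is estimated from wild-type replicates only and evaluated — with
linear extrapolation beyond the observed mean range — for mutants, so that
mutant noise is measured against the wild-type trend.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_smooth", "cv_to_noise", "NoiseTransform"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _local_fit(x0: float, x: np.ndarray, y: np.ndarray, span: float,
               degree: int) -> float:
    n = len(x)
    q = max(int(np.ceil(span * n)), degree + 2)
    q = min(q, n)
    d = np.abs(x - x0)
    idx = np.argpartition(d, q - 1)[:q]
    h = np.max(d[idx])
    if h <= 0:
        # all neighbours at x0: local mean
        return float(np.mean(y[idx]))
    w = _tricube(d[idx] / h)
    if np.sum(w > 0) <= degree:
        w = np.maximum(w, 1e-12)
    X = np.vander(x[idx] - x0, degree + 1, increasing=True)
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ y[idx], rcond=None)
    return float(beta[0])


def loess_smooth(x, y, span: float = 0.75, degree: int = 2,
                 x_out=None) -> np.ndarray:
    """Local polynomial regression with tricube weights (classical LOESS,
    no robustness iterations).

    Fits a degree-``degree`` polynomial in a sliding window containing a
    fraction ``span`` of the points, weighted by tricube distance, and
    returns the fitted value at each ``x`` (or at ``x_out`` if given, with
    linear extrapolation outside the range of ``x``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < max(10, 3 * degree):
        raise ValueError(f"need at least {max(10, 3 * degree)} points, got {n}")
    if span * n < degree + 2:
        raise ValueError("span too small for the requested degree")

    targets = x if x_out is None else np.asarray(x_out, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    inside = np.clip(targets, lo, hi)
    fitted = np.array([_local_fit(t, x, y, span, degree) for t in inside])
    if x_out is not None:
        # linear extrapolation using the boundary slope of the fitted curve
        eps = 1e-3 * (hi - lo) if hi > lo else 1e-6
        below, above = targets < lo, targets > hi
        if np.any(below):
            s = (_local_fit(lo + eps, x, y, span, degree)
                 - _local_fit(lo, x, y, span, degree)) / eps
            fitted[below] += s * (targets[below] - lo)
        if np.any(above):
            s = (_local_fit(hi, x, y, span, degree)
                 - _local_fit(hi - eps, x, y, span, degree)) / eps
            fitted[above] += s * (targets[above] - hi)
    return fitted


class NoiseTransform:
    """Wild-type-anchored CV-to-noise transform for one measure.

    Parameters
    ----------
    span, degree : smoother settings (LOESS defaults 0.75 / 2).
    """

    def __init__(self, span: float = 0.75, degree: int = 2):
        self.span = span
        self.degree = degree
        self._means = None
        self._cvs = None

    def fit(self, means, cvs) -> "NoiseTransform":
        means = np.asarray(means, dtype=float)
        cvs = np.asarray(cvs, dtype=float)
        if len(means) != len(cvs):
            raise ValueError("means and cvs must have equal length")
        if len(means) < 10:
            raise ValueError(f"need at least 10 samples, got {len(means)}")
        if np.any(cvs < 0):
            raise ValueError("CVs must be non-negative")
        self._means, self._cvs = means, cvs
        return self

    def transform(self, means, cvs) -> np.ndarray:
        if self._means is None:
            raise RuntimeError("call fit() first")
        means = np.asarray(means, dtype=float)
        cvs = np.asarray(cvs, dtype=float)
        trend = loess_smooth(self._means, self._cvs, span=self.span,
                             degree=self.degree, x_out=means)
        return cvs - trend


def cv_to_noise(means, cvs, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """One-shot CV-to-noise conversion: fit the LOESS trend of CV on mean
    across the given samples and return the residuals ``cv - f(mean)``."""
    t = NoiseTransform(span=span, degree=degree).fit(means, cvs)
    return t.transform(means, cvs)


def derive_noise_features(table, fit_samples=None, span: float = 0.75,
                          degree: int = 2):
    """Append a REAL ``<f>__noise`` feature for every ``<f>__mean`` /
    ``<f>__cv`` column pair of a feature table.

    The trend is fitted on ``fit_samples`` (typically the wild-type
    replicates) and evaluated for all samples.  Returns the list of new
    feature ids; the table is modified in place.
    """
    from .feature_model import DataType

    added = []
    cols = list(table.values.columns)
    for mc in cols:
        if not mc.endswith("__mean"):
            continue
        base = mc[:-6]
        cc = base + "__cv"
        if cc not in table.values.columns:
            continue
        m_all = table.values[mc].to_numpy(dtype=float)
        cv_all = table.values[cc].to_numpy(dtype=float)
        if fit_samples is not None:
            pos = table.values.index.get_indexer(fit_samples)
            t = NoiseTransform(span, degree).fit(m_all[pos], cv_all[pos])
        else:
            t = NoiseTransform(span, degree).fit(m_all, cv_all)
        name = base + "__noise"
        table.values[name] = t.transform(m_all, cv_all)
        table.feature_types[name] = DataType.REAL
        added.append(name)
    return added
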
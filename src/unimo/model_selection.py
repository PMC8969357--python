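"""Per-feature probability-family assignment.

Each data type has an ordered candidate list of families.  REAL features
first pass through a Shapiro–Wilk normality gate (Bonferroni-corrected
across the REAL features in the run): when normality is *not* rejected the
Gaussian is assigned without a race; otherwise the remaining real-support
candidates compete by AIC.  All other data types run a straight AIC race
over their candidates, ties broken by fewer parameters, then candidate
order.  The full AIC table is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .distributions import FitResult, fit_mle, get_family
from .feature_model import DataType, FeatureTable

__all__ = [
    "DEFAULT_CANDIDATES",
    "CandidateSet",
    "GateRecord",
    "FamilyAssignment",
    "shapiro_gate",
    "select_family",
    "assign_families",
]

DEFAULT_CANDIDATES: dict[DataType, tuple[str, ...]] = {
    DataType.NONNEG: ("gamma", "weibull", "lognormal",
                      "inverse_gaussian", "exponential"),
    DataType.RATIO: ("beta", "logit_normal"),
    DataType.REAL: ("gaussian", "logistic", "reverse_gumbel"),
    DataType.PROPORTION: ("binomial", "beta_binomial"),
    DataType.COUNT: ("poisson", "negative_binomial"),
}


@dataclass
class CandidateSet:
    """Mapping data type -> ordered candidate families (user-extensible)."""

    mapping: dict[DataType, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CANDIDATES))

    def for_type(self, dtype: DataType) -> tuple[str, ...]:
        return self.mapping[dtype]


@dataclass
class GateRecord:
    W: float
    p_raw: float
    p_adjusted: float
    m: int
    is_gaussian: bool


@dataclass
class FamilyAssignment:
    feature_id: str
    data_type: DataType
    family: str
    fit: FitResult
    aic_table: dict[str, float]          # family -> AIC (NaN if not converged)
    gate: Optional[GateRecord] = None
    via_gate: bool = False


def shapiro_gate(values, alpha: float = 0.05, m: int = 1) -> GateRecord:
    """Shapiro–Wilk normality gate for one REAL feature.

    The raw P value is Bonferroni-multiplied by ``m`` (the number of REAL
    features tested simultaneously) and capped at 1.  The feature is
    declared Gaussian when normality is NOT rejected, i.e. adjusted
    P >= alpha.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3 or len(x) > 5000:
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant values: normality test undefined")
    W, p = stats.shapiro(x)
    p_adj = min(1.0, float(p) * m)
    return GateRecord(W=float(W), p_raw=float(p), p_adjusted=p_adj, m=m,
                      is_gaussian=p_adj >= alpha)


def select_family(data, data_type: DataType,
                  candidates: Optional[CandidateSet] = None,
                  feature_id: str = "",
                  alpha_gate: float = 0.05, m_gate: int = 1,
                  use_gate: bool = True) -> FamilyAssignment:
    """Assign the best-fitting family for one feature.

    ``data`` is a 1-d value array, or an (n, 2) array of count pairs for
    PROPORTION features.  For REAL features the Shapiro–Wilk gate decides
    Gaussian first; the AIC race covers the remaining candidates.
    """
    candidates = candidates or CandidateSet()
    cand = list(candidates.for_type(data_type))
    gate = None
    via_gate = False
    if data_type == DataType.REAL and use_gate and "gaussian" in cand:
        gate = shapiro_gate(data, alpha=alpha_gate, m=m_gate)
        if gate.is_gaussian:
            via_gate = True
            cand = ["gaussian"]
        else:
            cand = [c for c in cand if c != "gaussian"]

    fits: dict[str, FitResult] = {}
    aic_table: dict[str, float] = {}
    errors: dict[str, str] = {}
    for name in cand:
        try:
            fr = fit_mle(name, data)
        except Exception as exc:  # fit infeasible for this candidate
            errors[name] = str(exc)
            aic_table[name] = float("nan")
            continue
        fits[name] = fr
        aic_table[name] = fr.aic if fr.converged else float("nan")
    ok = {nm: fr for nm, fr in fits.items() if fr.converged}
    if not ok:
        raise RuntimeError(
            f"no candidate family converged for feature {feature_id!r}: "
            f"{errors}")
    order = {nm: i for i, nm in enumerate(cand)}
    best = min(ok, key=lambda nm: (ok[nm].aic, ok[nm].k, order[nm]))
    return FamilyAssignment(
        feature_id=feature_id, data_type=data_type, family=best,
        fit=ok[best], aic_table=aic_table, gate=gate, via_gate=via_gate)


def assign_families(table: FeatureTable, samples=None,
                    candidates: Optional[CandidateSet] = None,
                    alpha_gate: float = 0.05,
                    min_obs: int = 20) -> dict[str, FamilyAssignment]:
    """Assign families to every feature of a table (wild-type samples).

    The Bonferroni m for the Shapiro–Wilk gate is the number of REAL
    features present.  Features with fewer than ``min_obs`` non-missing
    observations are skipped (insufficient replicates).
    """
    candidates = candidates or CandidateSet()
    m_real = sum(1 for t in table.feature_types.values() if t == DataType.REAL)
    out: dict[str, FamilyAssignment] = {}
    for f, dtype in table.feature_types.items():
        data, _ = table.feature_data(f, samples=samples)
        if len(data) < min_obs:
            continue
        out[f] = select_family(
            data, dtype, candidates=candidates, feature_id=f,
            alpha_gate=alpha_gate, m_gate=max(m_real, 1))
    return out
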
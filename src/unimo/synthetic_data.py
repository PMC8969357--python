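"""Synthetic morphological panels with known ground truth.

The generator emulates the structure of a wild-type replicate experiment:
114 replicate samples by default, features of all five data types drawn
from their generating families, an optional categorical confounder design
(e.g. a 5-level factor combining microscope filter set and acquisition
period) applying batch effects on the link scale, optional contaminating
second components, and optional far-tail outliers.  A mutant panel draws
one observation per (mutant, feature) from the same null families, with
specified effect sizes applied on the link scale; mutants without an
effect spec are fully null.  A third generator produces coupled
phenotype-score / annotation data with planted gene groups to exercise the
network stage.

A single integer master seed expands into per-feature substreams through
``numpy.random.SeedSequence`` keyed by the feature index, so adding a
feature does not perturb the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import get_family, sample as draw_sample
from .feature_model import DataType, FeatureTable, Role, SampleMeta

__all__ = [
    "FeatureSpec",
    "EffectSpec",
    "gen_wildtype_panel",
    "gen_mutant_panel",
    "gen_annotation_coupling",
    "default_feature_specs",
]


@dataclass
class FeatureSpec:
    """Generating model of one synthetic feature."""

    feature_id: str
    data_type: DataType
    family: str
    params: tuple
    n_trials: int = 200                      # proportion features only
    confounder_effects: Optional[dict] = None  # level -> link-scale shift
    contamination: Optional[tuple] = None      # (params, weight in [0, 0.5))
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0             # in null-sd units

    def __post_init__(self):
        fam = get_family(self.family)
        fam._check_theta(np.asarray(self.params, dtype=float))
        if self.contamination is not None:
            cp, w = self.contamination
            fam._check_theta(np.asarray(cp, dtype=float))
            if not 0 <= w < 0.5:
                raise ValueError("contamination weight must be in [0, 0.5)")
        if not 0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier rate must be in [0, 0.5)")


@dataclass
class EffectSpec:
    """Planted mutant effect: link-scale shift of one feature's location."""

    mutant_id: str
    feature_id: str
    effect: float


def _feature_rng(master_seed: int, tag: int, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(tag, index))
    return np.random.default_rng(ss)


def link_scale_sd(spec: FeatureSpec) -> float:
    """Half the central 68% spread of the feature on its family's link
    scale — the natural unit for planting effect sizes comparable across
    identity-, log- and logit-link features."""
    fam = get_family(spec.family)
    theta = np.asarray(spec.params, dtype=float)
    if fam.proportion:
        p = theta[0]
        sd_p = _null_sd(spec)
        return sd_p / (p * (1 - p))  # delta method through the logit
    q = fam._ppf(theta, np.array([0.158655, 0.841345]))
    lo, hi = fam.link_fn(float(q[0])), fam.link_fn(float(q[1]))
    return (hi - lo) / 2.0


def _null_sd(spec: FeatureSpec) -> float:
    fam = get_family(spec.family)
    theta = np.asarray(spec.params, dtype=float)
    if fam.proportion:
        p = theta[0]
        return math.sqrt(p * (1 - p) / spec.n_trials)
    q = fam._ppf(theta, np.array([0.158655, 0.841345]))
    return float(q[1] - q[0]) / 2.0


def _draw_feature(spec: FeatureSpec, levels: np.ndarray,
                  rng: np.random.Generator):
    fam = get_family(spec.family)
    theta = np.asarray(spec.params, dtype=float)
    n = len(levels)
    out_theta = []
    for lev in levels:
        delta = (spec.confounder_effects or {}).get(str(lev), 0.0)
        if delta:
            eta = fam.link_fn(fam.location(theta)) + delta
            out_theta.append(fam.set_location(theta, fam.inv_link_fn(eta)))
        else:
            out_theta.append(theta)
    obs = np.stack([
        np.atleast_1d(np.squeeze(draw_sample(
            fam, th, 1, rng, n_trials=spec.n_trials if fam.proportion else None)))
        for th in out_theta])
    if fam.proportion:
        obs = obs.reshape(n, 2)
    else:
        obs = obs.reshape(n)
    if spec.contamination is not None:
        cp, w = spec.contamination
        mask = rng.uniform(size=n) < w
        if mask.any():
            extra = draw_sample(fam, np.asarray(cp, float), int(mask.sum()),
                                rng, n_trials=spec.n_trials if fam.proportion
                                else None)
            obs[mask] = np.squeeze(extra) if not fam.proportion else extra
    if spec.outlier_rate > 0 and not fam.proportion:
        mask = rng.uniform(size=n) < spec.outlier_rate
        if mask.any():
            sd = _null_sd(spec)
            sign = rng.choice([-1.0, 1.0], size=int(mask.sum()))
            shifted = fam.location(theta) + sign * spec.outlier_magnitude * sd
            if fam.link != "identity":
                shifted = np.maximum(shifted, fam.location(theta) * 1e-3)
            if fam.link == "logit":
                shifted = np.clip(shifted, 1e-4, 1 - 1e-4)
            obs[mask] = shifted
    return obs


def _build_table(specs, obs_by_feature, sample_ids, role, strain_ids,
                 levels=None) -> tuple[FeatureTable, SampleMeta]:
    values = {}
    counts = {}
    ftypes = {}
    for spec in specs:
        ftypes[spec.feature_id] = spec.data_type
        if spec.data_type == DataType.PROPORTION:
            counts[spec.feature_id] = obs_by_feature[spec.feature_id]
        else:
            values[spec.feature_id] = obs_by_feature[spec.feature_id]
    vdf = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"))
    if not values:
        vdf = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    table = FeatureTable(values=vdf, feature_types=ftypes, counts=counts)
    meta = pd.DataFrame({"role": role, "strain_id": strain_ids},
                        index=pd.Index(sample_ids, name="sample_id"))
    if levels is not None:
        meta["batch"] = levels
    return table, SampleMeta(meta)


def gen_wildtype_panel(specs: Sequence[FeatureSpec], n_samples: int = 114,
                       n_confounder_levels: int = 5, seed: int = 0
                       ) -> tuple[FeatureTable, SampleMeta, dict]:
    """Generate wild-type replicates.

    Samples are assigned cyclically to ``n_confounder_levels`` levels of a
    single combined confounder factor; each spec's ``confounder_effects``
    shift its location on the link scale per level.  Returns the table,
    metadata, and a ground-truth record (specs + design).
    """
    sample_ids = [f"wt_{i:03d}" for i in range(n_samples)]
    levels = np.array([f"L{i % n_confounder_levels}"
                       for i in range(n_samples)])
    obs = {}
    for idx, spec in enumerate(specs):
        rng = _feature_rng(seed, 0, idx)
        obs[spec.feature_id] = _draw_feature(spec, levels, rng)
    table, meta = _build_table(
        specs, obs, sample_ids, Role.WILDTYPE_REPLICATE.value,
        ["his3"] * n_samples, levels)
    truth = {"specs": list(specs), "levels": levels, "seed": seed}
    return table, meta, truth


def gen_mutant_panel(specs: Sequence[FeatureSpec],
                     effects: Sequence[EffectSpec] = (),
                     n_mutants: int = 1000, seed: int = 0
                     ) -> tuple[FeatureTable, SampleMeta, dict]:
    """Generate a mutant panel: one observation per (mutant, feature) from
    each spec's null family, with listed effects applied on the link scale.
    Confounders, contamination and outliers are not applied — the panel
    represents cleaned mutant measurements."""
    known = {s.feature_id for s in specs}
    for e in effects:
        if e.feature_id not in known:
            raise ValueError(f"effect references unknown feature {e.feature_id!r}")
    mutant_ids = [f"mut_{i:04d}" for i in range(n_mutants)]
    eff_map: dict[tuple[str, str], float] = {
        (e.mutant_id, e.feature_id): e.effect for e in effects}
    obs = {}
    for idx, spec in enumerate(specs):
        rng = _feature_rng(seed, 1, idx)
        fam = get_family(spec.family)
        theta = np.asarray(spec.params, dtype=float)
        base = draw_sample(fam, theta, n_mutants, rng,
                           n_trials=spec.n_trials if fam.proportion else None)
        col = np.asarray(base, dtype=float)
        for j, mid in enumerate(mutant_ids):
            d = eff_map.get((mid, spec.feature_id), 0.0)
            if d:
                eta = fam.link_fn(fam.location(theta)) + d
                th = fam.set_location(theta, fam.inv_link_fn(eta))
                redraw = draw_sample(
                    fam, th, 1, _feature_rng(seed, 2, idx * 100003 + j),
                    n_trials=spec.n_trials if fam.proportion else None)
                col[j] = np.squeeze(redraw)
        obs[spec.feature_id] = col
    table, meta = _build_table(specs, obs, mutant_ids, Role.MUTANT.value,
                               mutant_ids)
    truth = {"effects": list(effects), "seed": seed}
    return table, meta, truth


def gen_annotation_coupling(n_genes: int, n_terms: int, n_groups: int,
                            coupling: float, seed: int = 0, n_pcv: int = 8
                            ) -> tuple[pd.DataFrame, list, dict]:
    """Generate coupled phenotype scores and gene annotations.

    Genes are partitioned into ``n_groups`` groups; each group owns a
    disjoint block of terms, including one hub term annotating every
    member (so within-group binary distances stay below 1 and cross-group
    distances equal 1).  Phenotype scores are
    ``coupling * group_latent + N(0, 1)`` per pCV dimension.

    Returns (scores DataFrame genes x pCV, list of (gene, term) pairs,
    {gene: group label}).
    """
    if not (n_genes >= n_groups >= 2):
        raise ValueError("need n_genes >= n_groups >= 2")
    if n_genes < 3 * n_groups:
        raise ValueError("need at least 3 genes per group")
    if n_terms < 2 * n_groups:
        raise ValueError("need at least 2 terms per group")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    labels = {g: i % n_groups for i, g in enumerate(genes)}
    members = {k: [g for g in genes if labels[g] == k] for k in range(n_groups)}
    per_group = n_terms // n_groups
    pairs = []
    for k in range(n_groups):
        mem = members[k]
        hub = f"t{k:03d}_hub"
        pairs.extend((g, hub) for g in mem)
        seen = {frozenset(mem)}
        for t in range(per_group - 1):
            term = f"t{k:03d}_{t:02d}"
            for _ in range(50):
                size = int(rng.integers(3, max(4, min(len(mem), 199))))
                sub = frozenset(rng.choice(mem, size=size, replace=False))
                if sub not in seen:
                    seen.add(sub)
                    break
            pairs.extend((g, term) for g in sub)
    latents = rng.standard_normal((n_groups, n_pcv))
    noise = rng.standard_normal((n_genes, n_pcv))
    scores = np.stack([coupling * latents[labels[g]] for g in genes]) + noise
    sdf = pd.DataFrame(scores, index=pd.Index(genes, name="gene"),
                       columns=[f"pCV{i + 1}" for i in range(n_pcv)])
    return sdf, pairs, labels


def load_specs_yaml(path) -> list[FeatureSpec]:
    """Read a list of feature specs from YAML.

    Each entry: ``feature_id``, ``data_type``, ``family``, ``params``
    (list), and optionally ``n_trials``, ``confounder_effects`` (mapping),
    ``contamination`` (``{params: [...], weight: w}``), ``outlier_rate``,
    ``outlier_magnitude``.
    """
    import yaml

    raw = yaml.safe_load(open(path)) or []
    specs = []
    for d in raw:
        cont = d.get("contamination")
        specs.append(FeatureSpec(
            feature_id=d["feature_id"],
            data_type=DataType(d["data_type"]),
            family=d["family"],
            params=tuple(d["params"]),
            n_trials=int(d.get("n_trials", 200)),
            confounder_effects=d.get("confounder_effects"),
            contamination=(tuple(cont["params"]), float(cont["weight"]))
            if cont else None,
            outlier_rate=float(d.get("outlier_rate", 0.0)),
            outlier_magnitude=float(d.get("outlier_magnitude", 8.0)),
        ))
    return specs


def default_feature_specs() -> list[FeatureSpec]:
    """The default synthetic wild-type panel: one well-behaved feature per
    data type plus one feature each with a planted batch effect and planted
    outlier contamination."""
    return [
        FeatureSpec("cell_size", DataType.NONNEG, "gamma", (4.0, 2.0)),
        FeatureSpec("neck_width", DataType.NONNEG, "weibull", (3.0, 1.5)),
        FeatureSpec("axis_ratio", DataType.RATIO, "beta", (8.0, 4.0)),
        FeatureSpec("actin_noise", DataType.REAL, "gaussian", (0.0, 1.0)),
        FeatureSpec("budded_fraction", DataType.PROPORTION, "beta_binomial",
                    (0.35, 0.02), n_trials=200),
        FeatureSpec("nucleus_count", DataType.COUNT, "poisson", (3.0,)),
        # batch shifts are centred so the confounder-adjusted grand location
        # matches the batch-free mutant draws
        FeatureSpec(
            "batchy_noise", DataType.REAL, "gaussian", (0.0, 1.0),
            confounder_effects={"L0": -3.0, "L1": -3.0, "L2": 3.0,
                                "L3": 3.0, "L4": 0.0}),
        FeatureSpec("outliery_noise", DataType.REAL, "gaussian", (0.0, 1.0),
                    outlier_rate=0.02, outlier_magnitude=8.0),
    ]
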
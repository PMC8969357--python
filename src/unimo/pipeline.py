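"""End-to-end orchestration of the phenotyping pipeline.

Stages (each writes plain-text artifacts into the output directory and a
manifest recording inputs, configuration hash and seeds):

* ``simulate`` — generate a synthetic wild-type + mutant panel (TSVs,
  type sidecar, ground-truth JSON);
* ``assign``   — per-feature family assignment (AIC / Shapiro–Wilk gate);
* ``modality`` — staged unimodality check with confounder adjustment and
  one-percentile outlier trimming; writes processed wild-type data;
* ``test``     — null-model fits, mutant P/Z/q, abnormal calls;
* ``network``  — annotation filtering, PCA/CCA, gene groups, pairwise CCA,
  correlation network with core/dense classification.

Identical configuration and inputs give byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import functional_cca as fc
from .feature_model import (DataType, FeatureTable, SampleMeta,
                            read_feature_table, write_feature_table)
from .modality import assess_modality
from .model_selection import CandidateSet, assign_families
from .phenotype_testing import NullModel, fit_null, score_panel
from .synthetic_data import (EffectSpec, default_feature_specs,
                             gen_annotation_coupling, gen_mutant_panel,
                             gen_wildtype_panel, link_scale_sd)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "assign", "modality", "test", "network")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "unimo_out"
    seed: int = 0
    # simulate
    n_wildtype: int = 114
    n_mutants: int = 200
    n_confounder_levels: int = 5
    n_effects: int = 10
    effect_size: float = 6.0
    spec_file: Optional[str] = None   # YAML feature specs (default panel if unset)
    # inputs (override simulate outputs)
    wt_values: Optional[str] = None
    wt_meta: Optional[str] = None
    mut_values: Optional[str] = None
    mut_meta: Optional[str] = None
    sidecar: Optional[str] = None
    annotation: Optional[str] = None
    # thresholds
    alpha_gate: float = 0.05
    c_max: int = 10
    n_restarts: int = 4
    n_randomizations: int = 3
    em_tol: float = 1e-6
    em_max_iter: int = 200
    fdr: float = 0.01
    alpha_cca: float = 0.05
    alpha_pairwise: float = 0.0005
    ccr_phenotype: float = 0.95
    ccr_function: float = 0.99
    min_wt_obs: int = 20

    def validate(self):
        for nm in ("alpha_gate", "fdr", "alpha_cca", "alpha_pairwise",
                   "ccr_phenotype", "ccr_function"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must be in [0, 1], got {v}")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {stage!r} stage first")
    return path


def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.spec_file:
        from .synthetic_data import load_specs_yaml
        specs = load_specs_yaml(cfg.spec_file)
    else:
        specs = default_feature_specs()
    wt, wt_meta, truth = gen_wildtype_panel(
        specs, n_samples=cfg.n_wildtype,
        n_confounder_levels=cfg.n_confounder_levels, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed,
                                                       spawn_key=(9,)))
    testable = [s for s in specs if s.data_type != DataType.COUNT]
    effects = []
    for i in range(cfg.n_effects):
        spec = testable[int(rng.integers(len(testable)))]
        # effect_size counts link-scale spread units, so log/logit features
        # get shifts comparable to the identity-link ones
        delta = cfg.effect_size * link_scale_sd(spec)
        effects.append(EffectSpec(f"mut_{i:04d}", spec.feature_id, delta))
    mut, mut_meta, mtruth = gen_mutant_panel(
        specs, effects, n_mutants=cfg.n_mutants, seed=cfg.seed + 1)
    write_feature_table(wt, wt_meta, out / "wt_values.tsv",
                        out / "wt_meta.tsv", out / "feature_types.json")
    write_feature_table(mut, mut_meta, out / "mut_values.tsv",
                        out / "mut_meta.tsv")
    (out / "ground_truth.json").write_text(json.dumps({
        "effects": [dataclasses.asdict(e) for e in effects],
        "seed": cfg.seed}, indent=1))
    return {"wt_values": "wt_values.tsv", "mut_values": "mut_values.tsv",
            "n_planted_effects": len(effects)}


def _load_wt(cfg: PipelineConfig, out: Path):
    vp = Path(cfg.wt_values) if cfg.wt_values else _require(
        out / "wt_values.tsv", "simulate")
    mp = Path(cfg.wt_meta) if cfg.wt_meta else _require(
        out / "wt_meta.tsv", "simulate")
    sc = Path(cfg.sidecar) if cfg.sidecar else (
        out / "feature_types.json" if (out / "feature_types.json").exists()
        else None)
    return read_feature_table(vp, mp, sc)


def _load_mut(cfg: PipelineConfig, out: Path):
    vp = Path(cfg.mut_values) if cfg.mut_values else _require(
        out / "mut_values.tsv", "simulate")
    mp = Path(cfg.mut_meta) if cfg.mut_meta else _require(
        out / "mut_meta.tsv", "simulate")
    sc = out / "feature_types.json" if (out / "feature_types.json").exists() \
        else None
    return read_feature_table(vp, mp, sc)


def _stage_assign(cfg: PipelineConfig, out: Path) -> dict:
    table, meta = _load_wt(cfg, out)
    assignments = assign_families(table, samples=meta.wildtype_ids(),
                                  alpha_gate=cfg.alpha_gate,
                                  min_obs=cfg.min_wt_obs)
    rows = []
    for f, a in assignments.items():
        rows.append({
            "feature": f, "data_type": a.data_type.value, "family": a.family,
            "theta": json.dumps(a.fit.params), "aic_best": a.fit.aic,
            "via_gate": a.via_gate,
            "gate_p_adjusted": a.gate.p_adjusted if a.gate else np.nan,
            "aic_table": json.dumps(a.aic_table),
        })
    pd.DataFrame(rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
    return {"n_features_assigned": len(rows)}


def _stage_modality(cfg: PipelineConfig, out: Path) -> dict:
    table, meta = _load_wt(cfg, out)
    asg = pd.read_csv(_require(out / "assignments.tsv", "assign"), sep="\t")
    wt_ids = meta.wildtype_ids()
    levels_all = meta.combined_confounder(wt_ids)
    rows = []
    processed: dict[str, pd.Series] = {}
    for _, arow in asg.iterrows():
        f = arow["feature"]
        data, ids = table.feature_data(f, samples=wt_ids)
        levels = levels_all.loc[ids].to_numpy()
        rep = assess_modality(
            data, arow["family"], levels=levels, feature_id=f,
            c_max=cfg.c_max, n_restarts=cfg.n_restarts,
            n_randomizations=cfg.n_randomizations, seed=cfg.seed,
            tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        rows.append({
            "feature": f, "family": rep.family,
            "final_unimodal": rep.final_unimodal,
            "final_stage": rep.final_stage,
            "n_outliers_removed": len(rep.removed_outliers),
            "stages": json.dumps([
                {"stage": s.stage, "c_star": s.c_star,
                 "bic": {str(k): v if np.isfinite(v) else None
                         for k, v in s.bic_table.items()}}
                for s in rep.stages]),
        })
        fam_prop = table.dtype_of(f) == DataType.PROPORTION
        if fam_prop:
            processed[f + "__k"] = pd.Series(rep.processed_data[:, 0])
            processed[f + "__n"] = pd.Series(rep.processed_data[:, 1])
        else:
            processed[f] = pd.Series(rep.processed_data)
    pd.DataFrame(rows).to_csv(out / "modality.tsv", sep="\t", index=False)
    pd.DataFrame({k: v for k, v in processed.items()}).to_csv(
        out / "wt_processed.tsv", sep="\t", index=False,
        float_format="%.17g")
    n_uni = sum(r["final_unimodal"] for r in rows)
    return {"n_unimodal": n_uni, "n_features": len(rows)}


def _stage_test(cfg: PipelineConfig, out: Path) -> dict:
    asg = pd.read_csv(_require(out / "assignments.tsv", "assign"), sep="\t")
    mod = pd.read_csv(_require(out / "modality.tsv", "modality"), sep="\t")
    proc = pd.read_csv(_require(out / "wt_processed.tsv", "modality"),
                       sep="\t")
    mut, mut_meta = _load_mut(cfg, out)
    unimodal = set(mod.loc[mod["final_unimodal"], "feature"])
    stage_map = dict(zip(mod["feature"], mod["final_stage"]))
    fam_map = dict(zip(asg["feature"], asg["family"]))
    type_map = dict(zip(asg["feature"], asg["data_type"]))
    n_real = sum(1 for t in type_map.values() if t == DataType.REAL.value)
    nulls: dict[str, NullModel] = {}
    obs: dict[str, tuple] = {}
    for f in unimodal:
        if f + "__k" in proc.columns:
            wt_data = proc[[f + "__k", f + "__n"]].dropna().to_numpy()
        else:
            wt_data = proc[f].dropna().to_numpy()
        if f not in mut.feature_types:
            continue
        family = fam_map[f]
        if stage_map.get(f) != "raw":
            # the family was assigned on confounded/contaminated raw data;
            # re-select it on the processed wild-type distribution
            from .model_selection import select_family
            family = select_family(
                wt_data, DataType(type_map[f]), feature_id=f,
                alpha_gate=cfg.alpha_gate, m_gate=max(n_real, 1)).family
        nulls[f] = fit_null(wt_data, family, feature_id=f,
                            min_obs=cfg.min_wt_obs)
        data, ids = mut.feature_data(f)
        obs[f] = (ids, data)
    results, summary, pi0 = score_panel(obs, nulls, fdr=cfg.fdr)
    results.to_csv(out / "test_results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    summary.to_csv(out / "test_summary.tsv", sep="\t",
                   index_label="mutant")
    (out / "pi0.json").write_text(json.dumps(pi0, indent=1))
    zmat = results.pivot(index="mutant", columns="feature", values="Z")
    zmat.to_csv(out / "z_matrix.tsv", sep="\t", float_format="%.10g")
    return {"n_features_tested": len(nulls),
            "n_abnormal": int(summary["abnormal"].sum()),
            "n_mutants": int(len(summary))}


def _stage_network(cfg: PipelineConfig, out: Path) -> dict:
    zmat = pd.read_csv(_require(out / "z_matrix.tsv", "test"), sep="\t",
                       index_col=0)
    if cfg.annotation:
        pairs = fc.read_gene_terms(cfg.annotation)
    else:
        # demo: couple annotations to the mutants with a planted group structure
        _, pairs, _ = gen_annotation_coupling(
            n_genes=len(zmat), n_terms=40, n_groups=6, coupling=0.8,
            seed=cfg.seed)
        pairs = [(zmat.index[int(g[1:])], t) for g, t in pairs]
    ann = fc.build_annotation_matrix(pairs)
    genes = [g for g in ann.genes if g in zmat.index]
    ann.matrix = ann.matrix.loc[genes]
    Z = zmat.loc[genes].to_numpy()
    p_red = fc.pca_reduce(Z, ccr_threshold=cfg.ccr_phenotype)
    g_red = fc.pca_reduce(ann.matrix.to_numpy().astype(float),
                          ccr_threshold=cfg.ccr_function)
    cca = fc.fit_cca(p_red.scores, g_red.scores, alpha=cfg.alpha_cca)
    # keep at least a handful of pCV dimensions so the pairwise-CCA stage
    # has enough observations even when few canonical pairs are significant
    d = min(len(cca.rho), max(cca.n_significant, 8))
    pcv = pd.DataFrame(cca.x_scores[:, :d], index=genes,
                       columns=[f"pCV{i + 1}" for i in range(d)])
    pcv.to_csv(out / "pcv_scores.tsv", sep="\t", float_format="%.10g")
    groups = fc.cluster_gene_groups(ann)
    groups = fc.enrich_groups(groups, ann)
    pairs_df = fc.pairwise_group_cca(groups, pcv, alpha=cfg.alpha_pairwise)
    pairs_df.to_csv(out / "group_pairs.tsv", sep="\t", index=False,
                    float_format="%.10g")
    net = fc.build_correlation_network(pcv, groups, pairs_df,
                                       layout_seed=cfg.seed)
    net.edges.to_csv(out / "edges.tsv", sep="\t", index=False,
                     float_format="%.10g")
    net.coordinates.to_csv(out / "coordinates.tsv", sep="\t",
                           float_format="%.10g")
    deg = np.array([g.degree for g in groups], dtype=float)
    dist = np.array([g.mean_within_distance for g in groups], dtype=float)
    if len(groups) >= 4 and np.ptp(deg) >= 0:
        core, dense, bounds = fc.classify_core_dense(deg, dist)
    else:
        core = dense = np.zeros(len(groups), dtype=bool)
        bounds = {}
    gtab = pd.DataFrame({
        "group": [g.group_id for g in groups],
        "n_members": [len(g.members) for g in groups],
        "members": [";".join(g.members) for g in groups],
        "representative_term": [g.representative_term for g in groups],
        "representative_p": [g.representative_p for g in groups],
        "degree": [g.degree for g in groups],
        "mean_within_distance": dist,
        "core": core, "dense": dense,
    })
    gtab.to_csv(out / "groups.tsv", sep="\t", index=False,
                float_format="%.10g")
    (out / "cca_report.json").write_text(json.dumps({
        "rho": cca.rho.tolist(), "bartlett_p": cca.bartlett_p.tolist(),
        "n_significant": int(cca.n_significant),
        "n_pPC": int(p_red.n_retained), "n_gPC": int(g_red.n_retained),
        "core_dense_boundaries": bounds}, indent=1))
    return {"n_groups": len(groups),
            "n_pairs_tested": int(len(pairs_df)),
            "n_significant_pairs": int(pairs_df["significant"].sum()),
            "n_canonical_pairs": int(cca.n_significant)}


_STAGE_FN = {"simulate": _stage_simulate, "assign": _stage_assign,
             "modality": _stage_modality, "test": _stage_test,
             "network": _stage_network}


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in order and write a manifest."""
    config.validate()
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = _out(config)
    manifest = {"config": dataclasses.asdict(config),
                "config_hash": config.digest(), "seed": config.seed,
                "stages": {}}
    for s in STAGES:
        if s in stages:
            manifest["stages"][s] = _STAGE_FN[s](config, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
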
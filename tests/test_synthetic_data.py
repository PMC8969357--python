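"""Synthetic-panel generators: determinism, invariants, recoverability."""

import numpy as np
import pytest

from unimo.distributions import fit_mle
from unimo.feature_model import DataType
from unimo.synthetic_data import (EffectSpec, FeatureSpec,
                                  default_feature_specs,
                                  gen_annotation_coupling, gen_mutant_panel,
                                  gen_wildtype_panel, link_scale_sd)


def test_same_seed_reproduces_tables():
    specs = default_feature_specs()
    t1, m1, _ = gen_wildtype_panel(specs, n_samples=50, seed=9)
    t2, m2, _ = gen_wildtype_panel(specs, n_samples=50, seed=9)
    assert t1.values.equals(t2.values)
    for f in t1.counts:
        assert np.array_equal(t1.counts[f], t2.counts[f])


def test_adding_a_feature_does_not_perturb_others():
    base = default_feature_specs()[:3]
    extended = base + [FeatureSpec("extra", DataType.REAL, "gaussian",
                                   (0.0, 1.0))]
    t1, _, _ = gen_wildtype_panel(base, n_samples=40, seed=5)
    t2, _, _ = gen_wildtype_panel(extended, n_samples=40, seed=5)
    for f in t1.values.columns:
        assert np.array_equal(t1.values[f], t2.values[f])


def test_generated_tables_satisfy_invariants():
    table, meta, _ = gen_wildtype_panel(default_feature_specs(),
                                        n_samples=60, seed=2)
    table.validate()  # raises on violation
    arr = table.counts["budded_fraction"]
    assert np.all(arr[:, 0] <= arr[:, 1])
    assert len(meta.sample_ids) == 60


def test_parameter_recovery_from_large_panel():
    spec = [FeatureSpec("g", DataType.NONNEG, "gamma", (4.0, 2.0))]
    table, _, _ = gen_wildtype_panel(spec, n_samples=10_000, seed=1)
    fr = fit_mle("gamma", table.values["g"].to_numpy())
    assert abs(fr.params["shape"] - 4.0) / 4.0 <= 0.05


def test_planted_batch_is_detected_as_multimodal():
    from unimo.modality import select_components
    spec = [FeatureSpec("b", DataType.REAL, "gaussian", (0.0, 1.0),
                        confounder_effects={"L0": -3.0, "L1": 3.0})]
    hits = 0
    for seed in range(10):
        table, _, _ = gen_wildtype_panel(spec, n_samples=114,
                                         n_confounder_levels=2, seed=seed)
        c, _, _ = select_components(table.values["b"].to_numpy(), "gaussian",
                                    c_max=3, n_restarts=3,
                                    n_randomizations=2, seed=seed,
                                    tol=1e-6, max_iter=200)
        hits += c >= 2
    assert hits >= 9


def test_mutant_panel_applies_link_scale_effects():
    specs = [FeatureSpec("g", DataType.NONNEG, "gamma", (4.0, 2.0))]
    effects = [EffectSpec("mut_0000", "g", 1.0)]  # log-link: mean x e
    table, meta, _ = gen_mutant_panel(specs, effects, n_mutants=2000, seed=3)
    vals = table.values["g"]
    assert meta.mutant_ids() == list(table.sample_ids)
    # null mutants centred at 8, the shifted one near 8e
    assert np.median(vals.iloc[1:]) == pytest.approx(8.0, rel=0.2)


def test_effect_on_unknown_feature_is_an_error():
    specs = [FeatureSpec("g", DataType.NONNEG, "gamma", (4.0, 2.0))]
    with pytest.raises(ValueError, match="nope"):
        gen_mutant_panel(specs, [EffectSpec("m", "nope", 1.0)], 10, seed=0)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        FeatureSpec("bad", DataType.NONNEG, "gamma", (-1.0, 2.0))
    with pytest.raises(ValueError):
        FeatureSpec("bad", DataType.NONNEG, "gamma", (1.0, 2.0),
                    contamination=((2.0, 2.0), 0.7))


def test_link_scale_sd_is_order_unity_for_standard_specs():
    for spec in default_feature_specs():
        sd = link_scale_sd(spec)
        assert 0 < sd < 5


def test_annotation_coupling_matrix_passes_filters():
    from unimo.functional_cca import build_annotation_matrix
    scores, pairs, labels = gen_annotation_coupling(100, 20, 4, 0.5, seed=6)
    am = build_annotation_matrix(pairs)
    assert all(len(v) == 0 for v in am.filter_log.values())
    assert set(am.genes) == set(labels)
    assert scores.shape[0] == 100


def test_annotation_coupling_recovers_groups():
    from sklearn.metrics import adjusted_rand_score

    from unimo.functional_cca import build_annotation_matrix, \
        cluster_gene_groups
    scores, pairs, labels = gen_annotation_coupling(200, 40, 5, 0.9, seed=0)
    am = build_annotation_matrix(pairs)
    groups = cluster_gene_groups(am)
    gmap = {m: g.group_id for g in groups for m in g.members}
    genes = am.genes
    ari = adjusted_rand_score([labels[g] for g in genes],
                              [gmap.get(g, -1) for g in genes])
    assert ari >= 0.9


def test_infeasible_sizes_are_errors():
    with pytest.raises(ValueError):
        gen_annotation_coupling(5, 20, 3, 0.5)   # < 3 genes per group
    with pytest.raises(ValueError):
        gen_annotation_coupling(50, 3, 3, 0.5)   # < 2 terms per group


def test_specs_round_trip_through_yaml(tmp_path):
    from unimo.synthetic_data import load_specs_yaml

    p = tmp_path / "specs.yaml"
    p.write_text(
        "- feature_id: size\n"
        "  data_type: NONNEG\n"
        "  family: gamma\n"
        "  params: [4.0, 2.0]\n"
        "  confounder_effects: {L0: 0.5}\n"
        "- feature_id: frac\n"
        "  data_type: PROPORTION\n"
        "  family: beta_binomial\n"
        "  params: [0.3, 0.05]\n"
        "  n_trials: 150\n"
        "  contamination: {params: [0.8, 0.05], weight: 0.1}\n")
    specs = load_specs_yaml(p)
    assert [s.feature_id for s in specs] == ["size", "frac"]
    assert specs[0].confounder_effects == {"L0": 0.5}
    assert specs[1].contamination == ((0.8, 0.05), 0.1)
    table, meta, _ = gen_wildtype_panel(specs, n_samples=30, seed=0)
    assert set(table.feature_ids) == {"size", "frac"}
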
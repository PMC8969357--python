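"""Feature-table data model, I/O round-trips, and type classification."""

import numpy as np
import pandas as pd
import pytest

from unimo.feature_model import (DataType, FeatureTable, SampleMeta,
                                 ValidationError, classify_data_type,
                                 read_feature_table, write_feature_table)
from unimo.synthetic_data import default_feature_specs, gen_wildtype_panel


def _write(tmp_path, values_text, meta_text):
    vp = tmp_path / "values.tsv"
    mp = tmp_path / "meta.tsv"
    vp.write_text(values_text)
    mp.write_text(meta_text)
    return vp, mp


META3 = ("sample_id\trole\tstrain_id\tbatch\n"
         "s1\twildtype\this3\tA\n"
         "s2\twildtype\this3\tA\n"
         "s3\tmutant\tyfg1\tB\n")


def test_read_wellformed_table(tmp_path):
    vp, mp = _write(
        tmp_path,
        "sample_id\tsize\tratio__k\tratio__n\n"
        "s1\t1.5\t3\t10\n"
        "s2\t2.5\t7\t10\n"
        "s3\t0.5\t5\t12\n",
        META3)
    table, meta = read_feature_table(vp, mp)
    assert table.sample_ids == ["s1", "s2", "s3"]
    assert set(table.feature_ids) == {"size", "ratio"}
    assert table.dtype_of("ratio") == DataType.PROPORTION
    assert meta.confounder_names == ["batch"]
    assert meta.wildtype_ids() == ["s1", "s2"]


def test_k_greater_than_n_names_the_cell(tmp_path):
    vp, mp = _write(
        tmp_path,
        "sample_id\tratio__k\tratio__n\n"
        "s1\t3\t10\ns2\t5\t3\ns3\t2\t8\n",
        META3)
    with pytest.raises(ValidationError, match=r"s2"):
        read_feature_table(vp, mp)


def test_negative_nonneg_value_is_rejected():
    vals = pd.DataFrame({"size": [1.0, -0.5, 2.0]},
                        index=["s1", "s2", "s3"])
    with pytest.raises(ValidationError, match="s2"):
        FeatureTable(values=vals, feature_types={"size": DataType.NONNEG})


def test_duplicate_sample_ids_rejected():
    vals = pd.DataFrame({"f": [1.0, 2.0]}, index=["s1", "s1"])
    with pytest.raises(ValidationError, match="duplicate"):
        FeatureTable(values=vals, feature_types={"f": DataType.NONNEG})


def test_write_then_read_round_trip(tmp_path):
    table, meta, _ = gen_wildtype_panel(default_feature_specs(),
                                        n_samples=30, seed=11)
    write_feature_table(table, meta, tmp_path / "v.tsv", tmp_path / "m.tsv",
                        tmp_path / "t.json")
    back, meta2 = read_feature_table(tmp_path / "v.tsv", tmp_path / "m.tsv",
                                     tmp_path / "t.json")
    for f in table.values.columns:
        a = table.values[f].to_numpy()
        b = back.values[f].to_numpy()
        assert np.max(np.abs(a - b)) <= 1e-12 * max(np.max(np.abs(a)), 1.0)
    for f, arr in table.counts.items():
        assert np.array_equal(arr, back.counts[f])  # integers bit-exact
    assert meta2.table.equals(meta.table)


@pytest.mark.parametrize("values,kwargs,expected", [
    ([-0.3, 0.2, 1.1], {}, DataType.REAL),
    ([0.10, 0.55, 0.99], {"declared_bounds": (0, 1)}, DataType.RATIO),
    ([3.0, 7.0, 5.0], {"declared_count": True}, DataType.COUNT),
    ([3.5, 7.0, 5.0], {}, DataType.NONNEG),
])
def test_classify_data_type(values, kwargs, expected):
    assert classify_data_type(values, **kwargs) == expected


def test_classify_count_pairs():
    assert classify_data_type(
        counts=[(3, 10), (7, 10), (5, 12)]) == DataType.PROPORTION


def test_classify_needs_three_observations():
    with pytest.raises(ValidationError):
        classify_data_type([1.0, np.nan, np.nan])


def test_unit_interval_without_bounds_warns_nonneg():
    with pytest.warns(UserWarning, match="no bounds"):
        t = classify_data_type([0.1, 0.5, 0.9])
    assert t == DataType.NONNEG


def test_fuzz_single_cell_corruption_detected(rng):
    """Randomly corrupting one cell of a valid table always trips
    validation."""
    table, meta, _ = gen_wildtype_panel(default_feature_specs(),
                                        n_samples=25, seed=4)
    for _ in range(25):
        kind = rng.integers(3)
        if kind == 0:  # negative value in a NONNEG column
            vals = table.values.copy()
            i = int(rng.integers(len(vals)))
            vals.iloc[i, vals.columns.get_loc("cell_size")] = -abs(
                rng.normal())
            with pytest.raises(ValidationError):
                FeatureTable(values=vals,
                             feature_types=dict(table.feature_types),
                             counts={k: v.copy()
                                     for k, v in table.counts.items()})
        elif kind == 1:  # k > n in a proportion pair
            counts = {k: v.copy() for k, v in table.counts.items()}
            arr = counts["budded_fraction"]
            i = int(rng.integers(len(arr)))
            arr[i, 0] = arr[i, 1] + 1
            with pytest.raises(ValidationError):
                FeatureTable(values=table.values.copy(),
                             feature_types=dict(table.feature_types),
                             counts=counts)
        else:  # non-integer count
            vals = table.values.copy()
            i = int(rng.integers(len(vals)))
            vals.iloc[i, vals.columns.get_loc("nucleus_count")] = 2.5
            with pytest.raises(ValidationError):
                FeatureTable(values=vals,
                             feature_types=dict(table.feature_types),
                             counts={k: v.copy()
                                     for k, v in table.counts.items()})


def test_meta_requires_known_roles():
    df = pd.DataFrame({"role": ["alien"], "strain_id": ["x"]}, index=["s1"])
    with pytest.raises(ValidationError, match="role"):
        SampleMeta(df)


def test_combined_confounder_joins_levels():
    df = pd.DataFrame({"role": ["wildtype"] * 2, "strain_id": ["h"] * 2,
                       "filter": ["F1", "F2"], "period": ["P1", "P1"]},
                      index=["s1", "s2"])
    meta = SampleMeta(df)
    combo = meta.combined_confounder()
    assert list(combo) == ["F1|P1", "F2|P1"]
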
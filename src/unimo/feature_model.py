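"""Data model and I/O for morphological feature tables.

A feature table holds samples (wild-type replicates and mutants) by
features.  Each feature carries one of five data types:

* ``NONNEG`` — continuous non-negative measures (lengths, areas);
* ``RATIO`` — continuous ratios bounded in [0, 1];
* ``REAL`` — unbounded real values (e.g. noise residuals of the CV);
* ``PROPORTION`` — (successes k, trials n) count pairs such as the
  fraction of cells of a given type;
* ``COUNT`` — unbounded non-negative integers.

On disk a table is a delimited text file with samples as rows.  Proportion
features are encoded as a column pair ``<feature>__k`` / ``<feature>__n``.
Sample metadata is a second table with columns ``sample_id``, ``role``
(``wildtype`` or ``mutant``), ``strain_id``, plus one column per categorical
confounder factor (microscope filter set, acquisition period, ...).
An optional JSON sidecar declares per-feature data types and bounds; without
it the classifier below infers types from the data.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DataType",
    "Role",
    "FeatureTable",
    "SampleMeta",
    "ValidationError",
    "classify_data_type",
    "read_feature_table",
    "write_feature_table",
]


class DataType(str, enum.Enum):
    NONNEG = "NONNEG"
    RATIO = "RATIO"
    REAL = "REAL"
    PROPORTION = "PROPORTION"
    COUNT = "COUNT"


class Role(str, enum.Enum):
    WILDTYPE_REPLICATE = "wildtype"
    MUTANT = "mutant"


class ValidationError(ValueError):
    """Invariant violation in a feature table, with cell coordinates."""


@dataclass
class SampleMeta:
    """Per-sample metadata: role, strain, and categorical confounders."""

    table: pd.DataFrame  # index: sample_id; columns: role, strain_id, factors

    CONFOUNDER_PREFIX_EXEMPT = ("role", "strain_id")

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
        if "role" not in self.table.columns:
            raise ValidationError("metadata must have a 'role' column")
        bad = set(self.table["role"]) - {r.value for r in Role}
        if bad:
            raise ValidationError(f"unknown roles in metadata: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def confounder_names(self) -> list[str]:
        return [c for c in self.table.columns
                if c not in self.CONFOUNDER_PREFIX_EXEMPT]

    def roles(self) -> pd.Series:
        return self.table["role"]

    def wildtype_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == Role.WILDTYPE_REPLICATE.value])

    def mutant_ids(self) -> list[str]:
        return list(self.table.index[self.table["role"] == Role.MUTANT.value])

    def combined_confounder(self, samples=None) -> pd.Series:
        """One categorical factor formed by the observed combination of all
        confounder levels (the one-way layout used by the confounder model)."""
        t = self.table if samples is None else self.table.loc[samples]
        cols = self.confounder_names
        if not cols:
            return pd.Series("all", index=t.index)
        return t[cols].astype(str).agg("|".join, axis=1)


@dataclass
class FeatureTable:
    """Samples x features container.

    ``values`` holds scalar features (NONNEG/RATIO/REAL/COUNT) with NaN for
    missing entries; ``counts`` maps each PROPORTION feature to an (n_samples,
    2) float array of (k, n) pairs (NaN rows = missing).
    """

    values: pd.DataFrame                     # index samples, columns scalar features
    feature_types: dict[str, DataType]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns) + [
            f for f in self.feature_types if f not in self.values.columns]

    def dtype_of(self, feature: str) -> DataType:
        return self.feature_types[feature]

    def feature_data(self, feature: str, samples=None):
        """Non-missing observations (values, or (k,n) pairs) and their
        sample ids, optionally restricted to a sample subset."""
        if self.feature_types[feature] == DataType.PROPORTION:
            arr = self.counts[feature]
            ids = np.asarray(self.values.index)
            if samples is not None:
                pos = self.values.index.get_indexer(samples)
                arr, ids = arr[pos], ids[pos]
            keep = ~np.isnan(arr).any(axis=1)
            return arr[keep], list(ids[keep])
        col = self.values[feature]
        if samples is not None:
            col = col.loc[samples]
        col = col.dropna()
        return col.to_numpy(dtype=float), list(col.index)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            raise ValidationError(
                f"duplicate sample ids: {idx[idx.duplicated()].tolist()[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate feature ids")
        for f in self.values.columns:
            if f not in self.feature_types:
                raise ValidationError(f"feature {f!r} has no declared data type")
            t = self.feature_types[f]
            col = self.values[f].to_numpy(dtype=float)
            obs = col[~np.isnan(col)]
            if t == DataType.PROPORTION:
                raise ValidationError(
                    f"feature {f!r}: PROPORTION features belong in counts, "
                    "not scalar values")
            if t == DataType.NONNEG and np.any(obs < 0):
                i = int(np.where(col < 0)[0][0])
                raise ValidationError(
                    f"feature {f!r}, sample {idx[i]!r}: negative value "
                    f"{col[i]} for a NONNEG feature")
            if t == DataType.RATIO and np.any((obs < 0) | (obs > 1)):
                bad = np.where((col < 0) | (col > 1))[0][0]
                raise ValidationError(
                    f"feature {f!r}, sample {idx[bad]!r}: value {col[bad]} "
                    "outside [0, 1] for a RATIO feature")
            if t == DataType.COUNT and np.any(
                    (obs < 0) | (np.floor(obs) != obs)):
                bad = int(np.where((col < 0) | (np.floor(col) != col))[0][0])
                raise ValidationError(
                    f"feature {f!r}, sample {idx[bad]!r}: value {col[bad]} "
                    "is not a non-negative integer for a COUNT feature")
        for f, arr in self.counts.items():
            if self.feature_types.get(f) != DataType.PROPORTION:
                raise ValidationError(
                    f"feature {f!r} has count pairs but type "
                    f"{self.feature_types.get(f)}")
            if arr.shape != (len(idx), 2):
                raise ValidationError(
                    f"feature {f!r}: count array shape {arr.shape} does not "
                    f"match {len(idx)} samples")
            k, n = arr[:, 0], arr[:, 1]
            obs = ~np.isnan(arr).any(axis=1)
            if np.any(np.isnan(arr[obs])):
                raise ValidationError(f"feature {f!r}: half-missing (k, n) pair")
            bad = obs & ((k < 0) | (n < 1) | (k > n)
                         | (np.floor(k) != k) | (np.floor(n) != n))
            if np.any(bad):
                i = int(np.where(bad)[0][0])
                raise ValidationError(
                    f"feature {f!r}, sample {idx[i]!r}: invalid count pair "
                    f"(k={k[i]}, n={n[i]}); require integers 0 <= k <= n, n >= 1")


def classify_data_type(values=None, counts=None, declared_bounds=None,
                       declared_count: bool = False) -> DataType:
    """Assign a data type to one feature.

    Count pairs are PROPORTION.  Non-negative integers declared as counts
    are COUNT.  Any negative value forces REAL.  Values in [0, 1] are RATIO
    only when bounds [0, 1] are declared — a small non-negative measure that
    happens to stay below 1 is otherwise NONNEG (with a logged warning for
    the ambiguity).
    """
    if counts is not None:
        arr = np.asarray(counts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("count pairs must be an (n, 2) array")
        return DataType.PROPORTION
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValidationError(
            f"need >= 3 non-missing observations to classify, got {len(x)}")
    if np.any(x < 0):
        return DataType.REAL
    if declared_count:
        if np.all(np.floor(x) == x):
            return DataType.COUNT
        raise ValidationError("feature declared COUNT has non-integer values")
    if declared_bounds is not None:
        lo, hi = declared_bounds
        if (lo, hi) == (0, 1):
            if np.any((x < 0) | (x > 1)):
                raise ValidationError("values outside declared [0, 1] bounds")
            return DataType.RATIO
    if np.all((x >= 0) & (x <= 1)):
        warnings.warn(
            "all values lie in [0, 1] but no bounds were declared; "
            "classifying as NONNEG", stacklevel=2)
    return DataType.NONNEG


# ---------------------------------------------------------------------------
# I/O

def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.columns.size == 0:
        raise ValidationError(f"{path}: no data columns (missing header?)")
    return df


def read_feature_table(values_path, meta_path, sidecar_path=None
                       ) -> tuple[FeatureTable, SampleMeta]:
    """Read a feature table and its sample metadata from delimited text.

    Column pairs ``<f>__k``/``<f>__n`` become PROPORTION features.  A JSON
    sidecar (``{"types": {feature: type}, "bounds": {feature: [lo, hi]}}``)
    declares data types; undeclared scalar features are classified from
    their values.
    """
    raw = _read_delimited(values_path)
    meta_df = _read_delimited(meta_path)
    sidecar = {}
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text())
    declared = {k: DataType(v) for k, v in sidecar.get("types", {}).items()}
    bounds = sidecar.get("bounds", {})

    k_cols = [c for c in raw.columns if c.endswith("__k")]
    counts: dict[str, np.ndarray] = {}
    feature_types: dict[str, DataType] = {}
    scalar_cols = [c for c in raw.columns
                   if not (c.endswith("__k") or c.endswith("__n"))]
    for kc in k_cols:
        base = kc[:-3]
        nc = base + "__n"
        if nc not in raw.columns:
            raise ValidationError(f"column {kc!r} lacks its partner {nc!r}")
        counts[base] = raw[[kc, nc]].to_numpy(dtype=float)
        feature_types[base] = DataType.PROPORTION
    for c in scalar_cols:
        vals = raw[c].to_numpy(dtype=float)
        if c in declared:
            feature_types[c] = declared[c]
        else:
            feature_types[c] = classify_data_type(
                vals, declared_bounds=tuple(bounds[c]) if c in bounds else None)
    values = raw[scalar_cols].astype(float)
    table = FeatureTable(values=values, feature_types=feature_types,
                         counts=counts)
    meta = SampleMeta(meta_df.astype(str))
    missing = set(table.sample_ids) - set(meta.sample_ids)
    if missing:
        raise ValidationError(
            f"samples without metadata: {sorted(missing)[:5]}")
    meta = SampleMeta(meta.table.loc[table.sample_ids])
    return table, meta


def write_feature_table(table: FeatureTable, meta: SampleMeta,
                        values_path, meta_path, sidecar_path=None) -> None:
    """Write a table + metadata back to delimited text (inverse of
    :func:`read_feature_table`)."""
    df = table.values.copy()
    for f, arr in table.counts.items():
        df[f + "__k"] = arr[:, 0]
        df[f + "__n"] = arr[:, 1]
    sep = "," if str(values_path).endswith(".csv") else "\t"
    df.to_csv(values_path, sep=sep, index_label="sample_id",
              float_format="%.17g")
    meta.table.to_csv(meta_path, sep=sep, index_label="sample_id")
    if sidecar_path is not None:
        types = {f: t.value for f, t in table.feature_types.items()}
        Path(sidecar_path).write_text(json.dumps({"types": types}, indent=1))
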
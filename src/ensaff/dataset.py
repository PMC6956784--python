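"""Affinity transforms, multi-representation dataset assembly and splitting.

Splits and cross-validation folds are stratified on quantile bins of the
continuous affinity label and grouped per ligand by default: all
representation rows of one ligand land on the same side of every boundary,
which prevents representation-duplicate leakage in combined datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

MEASURE_KINDS = ("Ki", "IC50", "RBA")

#: Factors converting supported concentration units to nM.
UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9, "pM": 1e-3}

#: Representation-tag groupings for combined datasets.
GROUPINGS: dict[str, tuple[str, ...]] = {
    "dConf": ("BDB", "OB3D", "Frog3D"),
    "dCharge": ("MMFF", "Gast", "BDB"),
    "ALL": ("MMFF", "Gast", "BDB", "OB3D", "Frog3D"),
}


def to_p_affinity(kind: str, value: float, units: str = "nM") -> float:
    """Map a measured affinity to the p-scale label.

    Ki/IC50 (concentration, nM by default): ``9 - log10(value_nM)``.
    RBA (percent relative binding activity): ``log10(value) - 8``.
    """
    if kind not in MEASURE_KINDS:
        raise ValidationError(f"unknown measure kind {kind!r}; expected one of {MEASURE_KINDS}")
    if not (value > 0):
        raise ValidationError(f"affinity value must be > 0, got {value}")
    if kind == "RBA":
        return math.log10(value) - 8.0
    if units not in UNIT_TO_NM:
        raise ValidationError(f"unknown units {units!r}; expected one of {sorted(UNIT_TO_NM)}")
    return 9.0 - math.log10(value * UNIT_TO_NM[units])


@dataclass(frozen=True)
class AffinityRecord:
    ligand_id: str
    measure_kind: str
    value: float
    units: str = "nM"
    p_affinity: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "p_affinity", to_p_affinity(self.measure_kind, self.value, self.units)
        )


def affinity_labels(df: pd.DataFrame) -> pd.DataFrame:
    """Add/derive a ``p_affinity`` column from an affinity table."""
    required = {"ligand_id", "measure_kind", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"affinity table is missing columns: {sorted(missing)}")
    units = df["units"] if "units" in df.columns else pd.Series("nM", index=df.index)
    out = df.copy()
    out["p_affinity"] = [
        to_p_affinity(k, v, u) for k, v, u in zip(df["measure_kind"], df["value"], units)
    ]
    return out


@dataclass
class SplitSpec:
    test_fraction: float = 0.2
    n_bins: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must lie in (0, 1)")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")


@dataclass
class CVSpec:
    k: int = 10
    repeats: int = 10
    n_bins: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


@dataclass
class DatasetTable:
    """Feature table with labels: ligand_id, representation_tag, p_affinity, features."""

    df: pd.DataFrame
    feature_names: tuple[str, ...]
    grouping_label: str | None = None

    def __post_init__(self) -> None:
        required = ["ligand_id", "representation_tag", "p_affinity", *self.feature_names]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"dataset table is missing columns: {missing}")
        if self.df.duplicated(subset=["ligand_id", "representation_tag"]).any():
            raise ValidationError("duplicate (ligand_id, representation_tag) rows")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ligand_ids(self) -> np.ndarray:
        return self.df["ligand_id"].to_numpy()

    @property
    def n_ligands(self) -> int:
        return self.df["ligand_id"].nunique()

    def features(self) -> pd.DataFrame:
        return self.df[list(self.feature_names)]

    def labels(self) -> np.ndarray:
        return self.df["p_affinity"].to_numpy(dtype=float)


def build_dataset(
    feature_df: pd.DataFrame,
    affinity_df: pd.DataFrame,
    feature_names: Sequence[str],
    grouping_label: str | None = None,
) -> DatasetTable:
    """Join an assembled feature table with p-scale labels."""
    labels = affinity_df
    if "p_affinity" not in labels.columns:
        labels = affinity_labels(labels)
    labels = labels[["ligand_id", "p_affinity"]].drop_duplicates("ligand_id")
    merged = feature_df.merge(labels, on="ligand_id", how="left", validate="many_to_one")
    if merged["p_affinity"].isna().any():
        lig = merged.loc[merged["p_affinity"].isna(), "ligand_id"].iloc[0]
        raise ValidationError(f"no affinity label for ligand {lig!r}")
    cols = ["ligand_id", "representation_tag", "p_affinity", *feature_names]
    return DatasetTable(merged[cols], tuple(feature_names), grouping_label)


def combine_representations(
    tagged_tables: Mapping[str, DatasetTable], grouping: str
) -> DatasetTable:
    """Row-wise concatenation of the member representation datasets."""
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; expected one of {sorted(GROUPINGS)}")
    members = GROUPINGS[grouping]
    missing = [t for t in members if t not in tagged_tables]
    if missing:
        raise ValidationError(f"grouping {grouping!r} is missing member tags: {missing}")
    schema = tagged_tables[members[0]].feature_names
    for tag in members[1:]:
        if tagged_tables[tag].feature_names != schema:
            raise SchemaError(f"feature schema of tag {tag!r} differs from {members[0]!r}")
    df = pd.concat([tagged_tables[t].df for t in members], ignore_index=True)
    return DatasetTable(df, schema, grouping_label=grouping)


# ---------------------------------------------------------------------------
# Stratification helpers
# ---------------------------------------------------------------------------

def _group_units(table: DatasetTable, grouped: bool) -> tuple[np.ndarray, np.ndarray]:
    """(unit keys, unit labels): ligands when grouped, rows otherwise."""
    if grouped:
        per = table.df.groupby("ligand_id", sort=True)["p_affinity"].mean()
        return per.index.to_numpy(), per.to_numpy(dtype=float)
    return np.arange(len(table.df)), table.labels()


def _quantile_bins(labels: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Equal-count contiguous bins of unit indices ordered by label value."""
    order = np.lexsort((np.arange(len(labels)), labels))
    return [chunk for chunk in np.array_split(order, n_bins)]


def stratified_holdout(
    table: DatasetTable, spec: SplitSpec, grouped: bool = True
) -> tuple[DatasetTable, DatasetTable]:
    """Deterministic stratified hold-out split.

    Labels are cut into ``n_bins`` equal-count quantile bins; per-bin test
    quotas are allocated by largest remainder so the test partition holds
    exactly ``floor(test_fraction * n)`` units.  With ``grouped`` (default)
    a unit is a ligand and all its representation rows travel together.
    """
    keys, labels = _group_units(table, grouped)
    n = len(keys)
    if n < spec.n_bins:
        raise ValidationError(f"need >= n_bins={spec.n_bins} units, got {n}")
    bins = _quantile_bins(labels, spec.n_bins)
    n_test = int(math.floor(spec.test_fraction * n))
    raw = [spec.test_fraction * len(b) for b in bins]
    quotas = [int(math.floor(q)) for q in raw]
    remainder = n_test - sum(quotas)
    frac_order = sorted(range(len(bins)), key=lambda i: (-(raw[i] - quotas[i]), i))
    for i in frac_order[:remainder]:
        quotas[i] += 1
    rng = np.random.default_rng(spec.seed)
    test_units: set = set()
    for b, quota in zip(bins, quotas):
        chosen = rng.permutation(len(b))[:quota]
        test_units.update(keys[b[chosen]])
    if grouped:
        mask = table.df["ligand_id"].isin(test_units).to_numpy()
    else:
        mask = np.zeros(len(table.df), dtype=bool)
        mask[list(test_units)] = True
    train = DatasetTable(table.df[~mask].copy(), table.feature_names, table.grouping_label)
    test = DatasetTable(table.df[mask].copy(), table.feature_names, table.grouping_label)
    return train, test


def make_cv_folds(
    table: DatasetTable, spec: CVSpec, grouped: bool = True
) -> list[dict]:
    """Repeated stratified k-fold assignments.

    Returns one ``{unit_key: fold}`` mapping per repeat; unit keys are ligand
    ids when ``grouped``.  Within every label bin fold sizes differ by at
    most one (continuous round-robin deal over shuffled bins).
    """
    keys, labels = _group_units(table, grouped)
    n = len(keys)
    if n < spec.k:
        raise ValidationError(f"need >= k={spec.k} units for {spec.k}-fold CV, got {n}")
    master = np.random.default_rng(spec.seed)
    assignments: list[dict] = []
    for _ in range(spec.repeats):
        rng = np.random.default_rng(master.integers(0, 2**63 - 1))
        bins = _quantile_bins(labels, spec.n_bins)
        mapping: dict = {}
        cursor = 0
        for b in bins:
            for idx in rng.permutation(b):
                mapping[keys[idx]] = cursor % spec.k
                cursor += 1
        assignments.append(mapping)
    return assignments


def fold_row_masks(
    table: DatasetTable, assignment: Mapping, fold: int, grouped: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(train_mask, validation_mask) over table rows for one fold."""
    if grouped:
        folds = table.df["ligand_id"].map(assignment).to_numpy()
    else:
        folds = np.array([assignment[i] for i in range(len(table.df))])
    val = folds == fold
    return ~val, val
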
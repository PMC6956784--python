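"""Template selection, pose clustering and per-ligand metric aggregation.

Per-ligand "unified instances" are the median and sample standard deviation
of each docking metric over all poses of that ligand, optionally joined with
the ligand descriptors into a named feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chem import (
    DESCRIPTOR_NAMES,
    ENGINEERED_FEATURE,
    ENGINEERED_NAME,
    N_MACCS_BITS,
    FingerprintBits,
    tanimoto,
)
from .docking import KEY_COLUMNS, METRICS
from .errors import MissingValueError, SchemaError, ValidationError

FEATURE_MODES: tuple[str, ...] = (
    "structure_only", "ligand_only", "combined", "combined_engineered",
    "maccs_only", "combined_maccs",
)

STRUCTURE_FEATURES: tuple[str, ...] = tuple(
    f"{m}_{suffix}" for m in METRICS for suffix in ("Med", "SD")
)
LIGAND_FEATURES: tuple[str, ...] = DESCRIPTOR_NAMES
MACCS_FEATURES: tuple[str, ...] = tuple(f"MACCS_{i}" for i in range(1, N_MACCS_BITS + 1))

AGGREGATE_TABLE_COLUMNS: tuple[str, ...] = (
    "ligand_id", "representation_tag", "n_poses", *STRUCTURE_FEATURES,
)


def feature_names(mode: str) -> tuple[str, ...]:
    """Frozen, ordered feature-name schema for each assembly mode."""
    if mode == "structure_only":
        return STRUCTURE_FEATURES
    if mode == "ligand_only":
        return LIGAND_FEATURES
    if mode == "combined":
        return STRUCTURE_FEATURES + LIGAND_FEATURES
    if mode == "combined_engineered":
        ligand = tuple(n for n in LIGAND_FEATURES if n not in ("nRotBond", "nBond"))
        return STRUCTURE_FEATURES + ligand + (ENGINEERED_FEATURE,)
    if mode == "maccs_only":
        return MACCS_FEATURES
    if mode == "combined_maccs":
        return STRUCTURE_FEATURES + LIGAND_FEATURES + MACCS_FEATURES
    raise ValidationError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")


@dataclass(frozen=True)
class TemplateRecord:
    """A receptor template and the fingerprint of its co-crystallized ligand."""

    template_id: str
    anchor_fingerprint: FingerprintBits
    anchor_p_affinity: float | None = None


@dataclass(frozen=True)
class DockingProtocolConfig:
    """Recorded configuration of the external ensemble-docking protocol."""

    n_templates: int = 20
    shape_restraint_weight: float = -3.0
    site_cutoff: float = 8.0
    poses_per_template: int = 1

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValidationError("n_templates must be >= 1")
        if self.site_cutoff <= 0:
            raise ValidationError("site_cutoff must be > 0")


@dataclass(frozen=True)
class AggregatedFeatures:
    """Median/SD of each metric over one ligand's poses."""

    ligand_id: str
    representation_tag: str
    n_poses: int
    values: dict[str, float]  # keys: "<Metric>_Med" and "<Metric>_SD"


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, named per-ligand feature vector."""

    ligand_id: str
    representation_tag: str
    mode: str
    names: tuple[str, ...]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# Template selection
# ---------------------------------------------------------------------------

def rank_templates(
    candidate: FingerprintBits, library: Sequence[TemplateRecord]
) -> list[tuple[str, float]]:
    """All templates ranked by anchor similarity (desc), ties by template_id."""
    if not library:
        raise ValidationError("template library is empty")
    scored = [(t.template_id, tanimoto(candidate, t.anchor_fingerprint)) for t in library]
    return sorted(scored, key=lambda x: (-x[1], x[0]))


def select_templates(
    candidate: FingerprintBits,
    library: Sequence[TemplateRecord],
    k: int = 20,
) -> list[str]:
    """The ``k`` most anchor-similar templates, highest first."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    ranked = rank_templates(candidate, library)
    if k > len(ranked):
        warnings.warn(
            f"requested k={k} templates but library holds only {len(ranked)}",
            stacklevel=2,
        )
    return [tid for tid, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# Pose clustering and selection
# ---------------------------------------------------------------------------

def pose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Coordinate RMSD between two poses with identical atom ordering."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"pose shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def cluster_poses(poses: Sequence[np.ndarray], rmsd_threshold: float = 2.0) -> list[list[int]]:
    """Single-linkage partition of poses under pairwise RMSD <= threshold.

    Poses must share atom count and ordering and live in a common reference
    frame (structural alignment happens upstream).  No symmetry correction.
    """
    if len(poses) == 0:
        raise ValidationError("cannot cluster an empty pose list")
    arrs = [np.asarray(p, dtype=float) for p in poses]
    shape = arrs[0].shape
    for i, p in enumerate(arrs):
        if p.shape != shape:
            raise ValidationError(f"pose {i} has shape {p.shape}, expected {shape}")
    n = len(arrs)
    if n == 1:
        return [[0]]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pose_rmsd(arrs[i], arrs[j])
    labels = fcluster(linkage(squareform(dist), method="single"), t=rmsd_threshold,
                      criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    return sorted(clusters.values(), key=lambda c: c[0])


def select_best_pose(clusters: Sequence[Sequence[int]], pose_scores: Mapping[int, float] | Sequence[float]) -> int:
    """Best-scoring member of the largest cluster.

    Cluster-size ties go to the cluster with the higher mean consensus score,
    then to the earlier cluster (stable).
    """
    if not clusters:
        raise ValidationError("no clusters given")

    def score(idx: int) -> float:
        try:
            s = pose_scores[idx]
        except (KeyError, IndexError) as exc:
            raise MissingValueError(f"no consensus score for pose {idx}") from exc
        if s is None or not np.isfinite(s):
            raise MissingValueError(f"no consensus score for pose {idx}")
        return float(s)

    best_cluster = None
    best_key = None
    for rank, cluster in enumerate(clusters):
        mean_score = float(np.mean([score(i) for i in cluster]))
        key = (-len(cluster), -mean_score, rank)
        if best_key is None or key < best_key:
            best_key, best_cluster = key, list(cluster)
    return max(best_cluster, key=score)


# ---------------------------------------------------------------------------
# Aggregation into unified instances
# ---------------------------------------------------------------------------

def aggregate_metrics(rows: pd.DataFrame, min_poses: int = 2) -> AggregatedFeatures:
    """Median/sample-SD aggregation of one ligand's pose rows."""
    if rows.empty or len(rows) < min_poses:
        raise ValidationError(
            f"aggregation needs >= {min_poses} poses, got {len(rows)}"
        )
    lig = rows["ligand_id"].unique()
    tag = rows["representation_tag"].unique()
    if len(lig) != 1 or len(tag) != 1:
        raise ValidationError("aggregate_metrics expects rows of a single (ligand, tag)")
    values: dict[str, float] = {}
    for metric in METRICS:
        col = rows[metric]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any():
            bad = col.index[numeric.isna()][0]
            raise ValidationError(f"non-numeric value at row {bad}, column {metric!r}")
        values[f"{metric}_Med"] = float(numeric.median())
        if len(numeric) == 1:
            warnings.warn("single pose: SD reported as 0.0", stacklevel=2)
            values[f"{metric}_SD"] = 0.0
        else:
            values[f"{metric}_SD"] = float(numeric.std(ddof=1))
    return AggregatedFeatures(
        ligand_id=str(lig[0]), representation_tag=str(tag[0]),
        n_poses=len(rows), values=values,
    )


def aggregate_pose_table(df: pd.DataFrame, min_poses: int = 2) -> pd.DataFrame:
    """Vectorized aggregation of a full pose table into unified instances."""
    missing = [c for c in KEY_COLUMNS + METRICS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose table is missing columns: {missing}")
    for metric in METRICS:
        numeric = pd.to_numeric(df[metric], errors="coerce")
        if numeric.isna().any():
            bad = df.index[numeric.isna()][0]
            raise ValidationError(f"non-numeric value at row {bad}, column {metric!r}")
    grouped = df.groupby(["ligand_id", "representation_tag"], sort=True)
    sizes = grouped.size()
    if (sizes < min_poses).any():
        lig, tag = sizes.index[sizes < min_poses][0]
        raise ValidationError(
            f"ligand {lig!r} ({tag}) has {sizes.min()} poses; minimum is {min_poses}"
        )
    med = grouped[list(METRICS)].median()
    sd = grouped[list(METRICS)].std(ddof=1)
    if min_poses <= 1:
        sd = sd.fillna(0.0)
    out = pd.DataFrame(index=med.index)
    out["n_poses"] = sizes
    for metric in METRICS:
        out[f"{metric}_Med"] = med[metric]
        out[f"{metric}_SD"] = sd[metric]
    return out.reset_index()[list(AGGREGATE_TABLE_COLUMNS)]


def assemble_features(
    agg: AggregatedFeatures,
    desc: Mapping[str, float] | None,
    mode: str,
    maccs: FingerprintBits | None = None,
) -> FeatureVector:
    """Join one ligand's aggregated metrics and descriptors into a vector."""
    names = feature_names(mode)
    desc_map = dict(desc) if desc is not None else None

    def lookup(name: str) -> float:
        if name in agg.values:
            return agg.values[name]
        if name.startswith("MACCS_"):
            if maccs is None:
                raise ValidationError(f"mode {mode!r} requires a MACCS fingerprint")
            return 1.0 if int(name.split("_")[1]) in maccs.bits else 0.0
        if desc_map is None:
            raise ValidationError(f"mode {mode!r} requires ligand descriptors")
        key = ENGINEERED_NAME if name == ENGINEERED_FEATURE else name
        if key not in desc_map:
            raise SchemaError(f"descriptor {key!r} absent for ligand {agg.ligand_id!r}")
        return float(desc_map[key])

    return FeatureVector(
        ligand_id=agg.ligand_id,
        representation_tag=agg.representation_tag,
        mode=mode,
        names=names,
        values=np.array([lookup(n) for n in names], dtype=float),
    )


def assemble_feature_table(
    agg_df: pd.DataFrame,
    desc_df: pd.DataFrame | None,
    mode: str,
    maccs_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Table-level feature assembly: one row per (ligand_id, representation_tag)."""
    names = feature_names(mode)
    out = agg_df[["ligand_id", "representation_tag"]].copy()
    merged = agg_df
    if desc_df is not None and mode != "structure_only" and mode != "maccs_only":
        cols = [c for c in desc_df.columns if c != "representation_tag"]
        merged = merged.merge(desc_df[cols].drop_duplicates("ligand_id"),
                              on="ligand_id", how="left", validate="many_to_one")
    if maccs_df is not None and mode in ("maccs_only", "combined_maccs"):
        merged = merged.merge(maccs_df, on="ligand_id", how="left", validate="many_to_one")
    for name in names:
        col = ENGINEERED_NAME if name == ENGINEERED_FEATURE else name
        if col not in merged.columns:
            raise SchemaError(f"feature source column {col!r} unavailable for mode {mode!r}")
        if merged[col].isna().any():
            lig = merged.loc[merged[col].isna(), "ligand_id"].iloc[0]
            raise MissingValueError(f"feature {name!r} missing for ligand {lig!r}")
        out[name] = merged[col].astype(float).to_numpy()
    return out
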
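"""Data model and I/O for the 19 per-pose structure-based docking metrics.

The scoring functions themselves are external: their values are consumed
from pose tables (or produced by :mod:`ensaff.simulate`).  This module owns
the table schema, the four-score consensus and linear pKa calibration.

Sign conventions are recorded, never altered: raw ``Plants``/``DSX``/
``MedusaScore`` are lower-is-better, the ``*LR``/``XScore``/``AnchKd``/
``AtomeScore`` columns live on a pKa scale (higher is better).  Downstream
learners receive all values unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import MissingValueError, SchemaError, ValidationError

#: The 19 metrics in canonical (table) order.
METRICS: tuple[str, ...] = (
    "PlantsFull", "Plants", "PlantsLR", "MedusaScore", "MedusaLR", "XScore",
    "DSX", "DSXLR", "AtomeScore", "Tanimoto", "AtomSA", "QMean", "AnchKd",
    "AnchorFit", "LigandEnergy", "LPC", "PSim", "CpxQuality", "LPE",
)

#: Columns whose mean defines the consensus score, in fixed order.
CONSENSUS_COMPONENTS: tuple[str, ...] = ("PlantsLR", "XScore", "MedusaLR", "DSXLR")

#: Metrics with a raw (native-unit) form that may be pKa-calibrated.
CALIBRATABLE_METRICS: tuple[str, ...] = ("Plants", "MedusaScore", "DSX")

KEY_COLUMNS: tuple[str, ...] = ("ligand_id", "representation_tag", "template_id")
POSE_TABLE_COLUMNS: tuple[str, ...] = KEY_COLUMNS + METRICS

#: Orientation registry: True where numerically lower scores indicate better
#: poses in the native units of the scoring function.
LOWER_IS_BETTER: Mapping[str, bool] = {
    "PlantsFull": True, "Plants": True, "PlantsLR": False, "MedusaScore": True,
    "MedusaLR": False, "XScore": False, "DSX": True, "DSXLR": False,
    "AtomeScore": False, "Tanimoto": False, "AtomSA": False, "QMean": False,
    "AnchKd": False, "AnchorFit": False, "LigandEnergy": True, "LPC": False,
    "PSim": False, "CpxQuality": False, "LPE": True,
}


@dataclass(frozen=True)
class PoseMetrics:
    """One docking pose of one ligand against one template."""

    ligand_id: str
    representation_tag: str
    template_id: str
    values: dict[str, float]
    extras: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = [m for m in METRICS if m not in self.values]
        if missing:
            raise SchemaError(f"pose is missing metrics: {missing}")
        t = self.values["Tanimoto"]
        if not (0.0 <= t <= 1.0):
            raise ValidationError(f"Tanimoto must lie in [0, 1], got {t}")


@dataclass(frozen=True)
class CalibrationLine:
    """Linear map raw score -> pKa for one calibratable metric."""

    metric_name: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.metric_name not in CALIBRATABLE_METRICS:
            raise ValidationError(
                f"no calibration defined for metric {self.metric_name!r}; "
                f"expected one of {CALIBRATABLE_METRICS}"
            )
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValidationError("calibration slope/intercept must be finite")


def consensus_atome_score(
    plants_lr: float,
    xscore: float,
    medusa_lr: float,
    dsx_lr: float,
    allow_partial: bool = False,
) -> float:
    """Arithmetic mean of the four pKa-scale scores.

    Strict by default: a missing (None/NaN) component raises.  With
    ``allow_partial`` the mean of the available components is returned.
    """
    comps = [plants_lr, xscore, medusa_lr, dsx_lr]
    finite = [c for c in comps if c is not None and math.isfinite(c)]
    if len(finite) < 4 and not allow_partial:
        raise MissingValueError(
            f"consensus requires all four components; got {4 - len(finite)} missing"
        )
    if not finite:
        raise MissingValueError("consensus has no available components")
    return float(sum(finite) / len(finite))


def calibrate_score(raw, line: CalibrationLine):
    """Apply ``slope * raw + intercept``; accepts scalars or arrays."""
    if line is None:
        raise MissingValueError("no calibration line supplied")
    return line.slope * np.asarray(raw, dtype=float) + line.intercept if not np.isscalar(raw) \
        else line.slope * float(raw) + line.intercept


def uncalibrate_score(pka, line: CalibrationLine):
    """Inverse of :func:`calibrate_score` (pKa back to raw units)."""
    if line.slope == 0:
        raise ValidationError("cannot invert a calibration with zero slope")
    return (np.asarray(pka, dtype=float) - line.intercept) / line.slope


def fit_calibration(pairs: Sequence[tuple[float, float]], metric_name: str = "Plants") -> CalibrationLine:
    """Ordinary least squares fit of pKa on raw score over (raw, pKa) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError("fit_calibration needs >= 2 (raw, pKa) pairs")
    raw, pka = arr[:, 0], arr[:, 1]
    if np.ptp(raw) == 0:
        raise ValidationError("raw scores have zero variance; calibration is undetermined")
    slope, intercept = np.polyfit(raw, pka, 1)
    return CalibrationLine(metric_name=metric_name, slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# Pose-table I/O
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def validate_pose_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in POSE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose table is missing required columns: {missing}")
    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        keys = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
        raise SchemaError(f"duplicate (ligand_id, representation_tag, template_id) key: {keys}")
    tan = pd.to_numeric(df["Tanimoto"], errors="coerce")
    if ((tan < 0) | (tan > 1)).any():
        raise ValidationError("Tanimoto column has values outside [0, 1]")
    return df


def read_pose_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a pose-metric table; unknown columns are preserved."""
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_pose_table(df)


def write_pose_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write with the canonical header first; extra columns trail in input order."""
    validate_pose_table(df)
    extras = [c for c in df.columns if c not in POSE_TABLE_COLUMNS]
    df[list(POSE_TABLE_COLUMNS) + extras].to_csv(path, index=False, sep=_sep_for(path))


def pose_records(df: pd.DataFrame) -> list[PoseMetrics]:
    """Materialize validated rows as :class:`PoseMetrics` records."""
    validate_pose_table(df)
    extras_cols = [c for c in df.columns if c not in POSE_TABLE_COLUMNS]
    out = []
    for _, row in df.iterrows():
        out.append(PoseMetrics(
            ligand_id=str(row["ligand_id"]),
            representation_tag=str(row["representation_tag"]),
            template_id=str(row["template_id"]),
            values={m: float(row[m]) for m in METRICS},
            extras={c: row[c] for c in extras_cols} or None,
        ))
    return out


def recompute_consensus(df: pd.DataFrame, allow_partial: bool = False) -> pd.Series:
    """Recompute the consensus column from its four components, row-wise."""
    comp = df[list(CONSENSUS_COMPONENTS)].astype(float)
    if not allow_partial and comp.isna().any().any():
        bad = comp.columns[comp.isna().any()].tolist()
        raise MissingValueError(f"missing consensus components in columns: {bad}")
    return comp.mean(axis=1, skipna=allow_partial)


def verify_consensus(df: pd.DataFrame, atol: float = 1e-6) -> bool:
    """True iff the stored consensus column matches its recomputation."""
    expected = recompute_consensus(df)
    return bool(np.allclose(df["AtomeScore"].astype(float), expected, atol=atol))


# ---------------------------------------------------------------------------
# Calibration config files
# ---------------------------------------------------------------------------

def load_calibration(path: str | Path) -> dict[str, CalibrationLine]:
    """Read ``{metric: {slope, intercept}}`` mappings from a YAML file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: calibration config must be a mapping")
    out = {}
    for name, entry in data.items():
        try:
            out[name] = CalibrationLine(name, float(entry["slope"]), float(entry["intercept"]))
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: bad calibration entry for {name!r}") from exc
    return out


def save_calibration(lines: Mapping[str, CalibrationLine], path: str | Path) -> None:
    data = {name: {"slope": ln.slope, "intercept": ln.intercept} for name, ln in lines.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
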
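"""Regression evaluation and cross-dataset correlation matrices.

``R2`` is computed against the identity line (residuals of predictions from
the observed values), not against a refitted regression line, so it can be
negative.  RMSE is the root of the mean squared residual.  Argument order is
pinned: predictions first, observations second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .docking import METRICS
from .errors import ValidationError


@dataclass(frozen=True)
class EvaluationReport:
    rP: float
    rS: float
    R2: float
    RMSE: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "rP": self.rP, "rS": self.rS, "R2": self.R2, "RMSE": self.RMSE,
            "n": self.n, "degenerate": self.degenerate,
        }


def evaluate(predicted, observed) -> EvaluationReport:
    """Score predictions against observations (rP, rS, R2 vs identity, RMSE)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValidationError(f"length mismatch: predicted {pred.shape}, observed {obs.shape}")
    if len(pred) < 2:
        raise ValidationError("need at least 2 points to evaluate")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValidationError("evaluate requires finite inputs")
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    degenerate = ss_tot == 0.0 or np.ptp(pred) == 0.0
    if np.ptp(obs) == 0.0:
        warnings.warn("observed values have zero variance; rP/rS undefined", stacklevel=2)
        rp = rs = float("nan")
        r2 = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rp = float(stats.pearsonr(pred, obs)[0]) if np.ptp(pred) > 0 else float("nan")
            rs = float(stats.spearmanr(pred, obs)[0]) if np.ptp(pred) > 0 else float("nan")
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return EvaluationReport(rP=rp, rS=rs, R2=r2, RMSE=rmse, n=len(pred),
                            degenerate=bool(degenerate))


@dataclass
class CrossMatrix:
    """Model x test-set grid of Pearson correlations with full reports."""

    model_labels: tuple[str, ...]
    testset_labels: tuple[str, ...]
    rP: pd.DataFrame
    reports: dict[tuple[str, str], EvaluationReport]
    failures: dict[tuple[str, str], str]


def cross_evaluate(models: Mapping[str, object], testsets: Mapping[str, object]) -> CrossMatrix:
    """Evaluate every model on every test set; failed cells carry a reason."""
    from .learner import predict  # local import to avoid a cycle

    model_labels = tuple(models)
    test_labels = tuple(testsets)
    rp = pd.DataFrame(np.nan, index=list(model_labels), columns=list(test_labels))
    reports: dict[tuple[str, str], EvaluationReport] = {}
    failures: dict[tuple[str, str], str] = {}
    for m_label, model in models.items():
        for t_label, table in testsets.items():
            try:
                pred = predict(model, table)
                report = evaluate(pred, table.labels())
            except Exception as exc:
                failures[(m_label, t_label)] = str(exc)
                continue
            reports[(m_label, t_label)] = report
            rp.loc[m_label, t_label] = report.rP
    return CrossMatrix(model_labels, test_labels, rp, reports, failures)


def median_score_correlation(
    pose_df: pd.DataFrame, affinity_df: pd.DataFrame, metric: str
) -> dict[str, float]:
    """Correlate per-ligand median raw metric values with the affinity label.

    Scores are used as-is (no sign flipping), so lower-is-better metrics
    yield negative correlations by construction.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    from .dataset import affinity_labels

    labels = affinity_df
    if "p_affinity" not in labels.columns:
        labels = affinity_labels(labels)
    med = pose_df.groupby("ligand_id", sort=True)[metric].median().rename("median_score")
    merged = labels[["ligand_id", "p_affinity"]].drop_duplicates("ligand_id").merge(
        med, on="ligand_id", how="inner"
    )
    if len(merged) < 2:
        raise ValidationError("need >= 2 ligands with both poses and labels")
    rp = float(stats.pearsonr(merged["median_score"], merged["p_affinity"])[0])
    rs = float(stats.spearmanr(merged["median_score"], merged["p_affinity"])[0])
    return {"rP": rp, "rS": rs, "n": int(len(merged))}
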
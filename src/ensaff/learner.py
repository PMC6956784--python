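"""Random-forest regression with repeated stratified CV and importance tracking.

The forest has a single tuned hyperparameter: the number of features drawn
at each split (``mtry``).  Candidates are scored by mean CV RMSE over
ligand-grouped stratified folds; the winner is refit on the full table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isqrt
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .dataset import CVSpec, DatasetTable, fold_row_masks, make_cv_folds
from .errors import SchemaError, ValidationError

MODEL_FORMAT = "ensaff-rf-1"


@dataclass
class TrainedModel:
    algorithm: str
    n_trees: int
    mtry: int
    model: RandomForestRegressor
    feature_names: tuple[str, ...]
    label_range: tuple[float, float]
    metadata: dict
    cv_summary: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class ImportanceTable:
    """Features ranked by importance, normalized so the top score is 100."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(s < 0 for s in scores):
            raise ValidationError("importance scores must be >= 0")
        if scores != sorted(scores, reverse=True):
            raise ValidationError("importance entries must be in descending order")

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, n: int) -> tuple[tuple[str, float], ...]:
        return self.entries[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "importance"])


def default_mtry_grid(p: int) -> list[int]:
    """Candidate mtry values: p/3, sqrt(p) and p/2 (deduplicated, >= 1)."""
    return sorted({max(1, p // 3), max(1, isqrt(p)), max(1, p // 2)})


def _check_features(table: DatasetTable) -> tuple[np.ndarray, np.ndarray]:
    X = table.features().to_numpy(dtype=float)
    y = table.labels()
    bad = [name for name, col in zip(table.feature_names, X.T) if not np.isfinite(col).all()]
    if bad:
        raise ValidationError(f"missing/non-finite values in feature columns: {bad}")
    if not np.isfinite(y).all():
        raise ValidationError("missing/non-finite affinity labels")
    if np.unique(y).size < 2:
        raise ValidationError("labels are constant; nothing to learn")
    return X, y


def _forest(n_trees: int, mtry: int, seed: int, bootstrap: bool) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, random_state=seed,
        bootstrap=bootstrap, n_jobs=1,
    )


def train_rf(
    table: DatasetTable,
    cv: CVSpec | None = None,
    mtry_grid: Sequence[int] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    bootstrap: bool = True,
) -> TrainedModel:
    """Fit a random forest, selecting mtry by repeated stratified CV.

    With ``cv=None`` the grid must contain a single value, which is used
    directly (no CV pass).  Training is deterministic for a fixed seed.
    """
    X, y = _check_features(table)
    p = X.shape[1]
    grid = sorted(set(int(m) for m in (mtry_grid or default_mtry_grid(p))))
    if any(m < 1 or m > p for m in grid):
        raise ValidationError(f"mtry candidates must lie in [1, {p}], got {grid}")
    cv_summary: list[dict] = []
    if cv is None:
        if len(grid) != 1:
            raise ValidationError("cv spec required to select among multiple mtry candidates")
        best_mtry = grid[0]
    else:
        assignments = make_cv_folds(table, cv)
        lig = table.ligand_ids
        scores: dict[int, list[tuple[float, float]]] = {m: [] for m in grid}
        for assignment in assignments:
            for fold in range(cv.k):
                train_mask, val_mask = fold_row_masks(table, assignment, fold)
                if not val_mask.any():
                    continue
                # leakage guard: a fold's ligands must be absent from the fit rows
                overlap = set(lig[train_mask]) & set(lig[val_mask])
                if overlap:
                    raise AssertionError(f"CV leakage: ligands straddle a fold: {sorted(overlap)[:3]}")
                for m in grid:
                    forest = _forest(n_trees, m, seed, bootstrap)
                    forest.fit(X[train_mask], y[train_mask])
                    pred = forest.predict(X[val_mask])
                    resid = y[val_mask] - pred
                    rmse = float(np.sqrt(np.mean(resid**2)))
                    ss_tot = float(np.sum((y[val_mask] - y[val_mask].mean()) ** 2))
                    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
                    scores[m].append((rmse, r2))
        for m in grid:
            rmses = np.array([s[0] for s in scores[m]])
            r2s = np.array([s[1] for s in scores[m]])
            cv_summary.append({
                "mtry": m,
                "rmse_mean": float(rmses.mean()), "rmse_sd": float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
                "r2_mean": float(np.nanmean(r2s)), "r2_sd": float(np.nanstd(r2s, ddof=1)) if len(r2s) > 1 else 0.0,
            })
        best_mtry = min(cv_summary, key=lambda s: (s["rmse_mean"], s["mtry"]))["mtry"]
    forest = _forest(n_trees, best_mtry, seed, bootstrap)
    forest.fit(X, y)
    return TrainedModel(
        algorithm="random_forest",
        n_trees=n_trees,
        mtry=best_mtry,
        model=forest,
        feature_names=tuple(table.feature_names),
        label_range=(float(y.min()), float(y.max())),
        metadata={
            "dataset_label": table.grouping_label,
            "cv": None if cv is None else vars(cv).copy(),
            "seed": seed,
            "n_rows": len(table),
            "n_ligands": table.n_ligands,
        },
        cv_summary=cv_summary,
    )


def predict(model: TrainedModel, data) -> np.ndarray:
    """Predict p-affinity for each row of a DatasetTable or feature DataFrame."""
    df = data.df if isinstance(data, DatasetTable) else data
    expected = set(model.feature_names)
    ignorable = {"ligand_id", "representation_tag", "p_affinity"}
    present = set(df.columns) - ignorable
    missing = sorted(expected - present)
    unexpected = sorted(present - expected)
    if missing or unexpected:
        raise SchemaError(
            f"feature schema mismatch: missing={missing[:5]}, unexpected={unexpected[:5]}"
        )
    X = df[list(model.feature_names)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("prediction input contains missing/non-finite values")
    return model.model.predict(X)


def variable_importance(
    model: TrainedModel,
    method: str = "impurity",
    data: DatasetTable | None = None,
    seed: int = 0,
) -> ImportanceTable:
    """Per-feature importance, descending, normalized to max = 100.

    ``impurity``: mean decrease in impurity from the fitted ensemble.
    ``permutation``: permutation importance; requires ``data``.
    """
    if not hasattr(model.model, "estimators_") or not model.model.estimators_:
        raise ValidationError("model is not fitted")
    if method == "impurity":
        raw = np.asarray(model.model.feature_importances_, dtype=float)
    elif method == "permutation":
        if data is None:
            raise ValidationError("permutation importance requires a dataset")
        result = permutation_importance(
            model.model, data.features().to_numpy(dtype=float), data.labels(),
            n_repeats=10, random_state=seed,
        )
        raw = np.clip(result.importances_mean, 0.0, None)
    else:
        raise ValidationError(f"unknown importance method {method!r}")
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else raw
    order = sorted(range(len(scaled)), key=lambda i: (-scaled[i], i))
    entries = tuple((model.feature_names[i], float(scaled[i])) for i in order)
    return ImportanceTable(entries=entries)


def save_model(model: TrainedModel, path) -> None:
    """Serialize to a single versioned archive."""
    joblib.dump({
        "format": MODEL_FORMAT,
        "algorithm": model.algorithm,
        "n_trees": model.n_trees,
        "mtry": model.mtry,
        "model": model.model,
        "feature_names": model.feature_names,
        "label_range": model.label_range,
        "metadata": model.metadata,
        "cv_summary": model.cv_summary,
    }, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format") != MODEL_FORMAT:
        raise SchemaError(f"unsupported model archive format: {payload.get('format')!r}")
    return TrainedModel(
        algorithm=payload["algorithm"], n_trees=payload["n_trees"], mtry=payload["mtry"],
        model=payload["model"], feature_names=tuple(payload["feature_names"]),
        label_range=tuple(payload["label_range"]), metadata=payload["metadata"],
        cv_summary=payload["cv_summary"],
    )
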
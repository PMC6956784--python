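"""Synthetic docking studies with controlled signal structure.

The generator stands in for the external docking/rescoring stack: it emits
per-ligand ensembles of pose-metric rows whose pKa-scale scores track a
latent affinity with configurable noise, plus descriptor tables and affinity
labels, all in the exact CSV schemas consumed by the other modules.

Signal model for the four pKa-scale scoring metrics of ligand *i* docked
into template *j*::

    m_ij = a_m * (theta * T_ij + (1 - theta)) * pKa_i + b_m
           + Normal(0, sigma_m) + Normal(0, tau)

where ``T_ij`` is the ligand/anchor Tanimoto similarity, ``theta`` couples
metric quality to template similarity, ``sigma_m`` is per-metric noise and
``tau`` a shared per-pose jitter.  Raw-scale scores are obtained through the
inverse of the default calibration lines; the consensus column is always the
exact mean of its four components.  Each representation tag redraws all
noise (a conformer/charge-variation proxy) while the latent pKa is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    CVSpec,
    DatasetTable,
    SplitSpec,
    build_dataset,
    stratified_holdout,
)
from .docking import (
    CALIBRATABLE_METRICS,
    CONSENSUS_COMPONENTS,
    METRICS,
    POSE_TABLE_COLUMNS,
    CalibrationLine,
    uncalibrate_score,
    validate_pose_table,
)
from .chem import DESCRIPTOR_NAMES, DESCRIPTOR_TABLE_COLUMNS, ENGINEERED_NAME
from .ensemble import aggregate_pose_table, assemble_feature_table
from .errors import ValidationError
from .evaluation import EvaluationReport, evaluate
from .learner import ImportanceTable, predict, train_rf, variable_importance

#: Calibration lines used to invert pKa-scale scores into native raw units.
DEFAULT_CALIBRATION: dict[str, CalibrationLine] = {
    "Plants": CalibrationLine("Plants", slope=-0.08, intercept=0.0),
    "MedusaScore": CalibrationLine("MedusaScore", slope=-0.12, intercept=1.0),
    "DSX": CalibrationLine("DSX", slope=-0.05, intercept=0.5),
}

_RAW_FROM_LR = {"Plants": "PlantsLR", "MedusaScore": "MedusaLR", "DSX": "DSXLR"}

#: Continuous descriptors eligible to carry independent affinity signal,
#: in the order they are recruited.
_SIGNAL_DESCRIPTORS = ("XLogP", "MW", "TPSA", "VABC")

#: Real small-molecule SMILES shipped in-code as chemistry fixtures.
FIXTURE_SMILES: tuple[tuple[str, str], ...] = (
    ("benzene", "c1ccccc1"),
    ("ethanol", "CCO"),
    ("n-pentane", "CCCCC"),
    ("phenol", "Oc1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("cyclohexane", "C1CCCCC1"),
    ("caffeine", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("acetaminophen", "CC(=O)Nc1ccc(O)cc1"),
    ("nicotine", "CN1CCC[C@H]1c1cccnc1"),
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("estradiol", "C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc34)[C@@H]1CC[C@@H]2O"),
    ("bisphenol-a", "CC(C)(c1ccc(O)cc1)c1ccc(O)cc1"),
    ("diethylstilbestrol", "CC/C(=C(\\CC)c1ccc(O)cc1)c1ccc(O)cc1"),
    ("genistein", "C1=CC(=CC=C1C2=COC3=CC(=CC(=C3C2=O)O)O)O"),
    ("tamoxifen", "CC/C(=C(\\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1"),
    ("4-octylphenol", "CCCCCCCCc1ccc(O)cc1"),
    ("resveratrol", "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1"),
)


@dataclass
class SimulationConfig:
    n_ligands: int = 100
    n_templates_library: int = 60
    n_templates_selected: int = 20
    p_affinity_range: tuple[float, float] = (4.0, 14.0)
    metric_slope: float = 1.0          # a_m, shared over signal metrics
    metric_intercept: float = 0.0      # b_m
    metric_noise: float = 0.5          # sigma_m
    pose_jitter: float = 0.25          # tau
    tanimoto_coupling: float = 0.0     # theta in [0, 1]
    tags: tuple[str, ...] = ("BDB",)
    n_signal_descriptors: int = 2
    descriptor_signal: float = 0.5     # slope (descriptor units per pKa unit)
    descriptor_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 1 or self.n_templates_library < 1 or self.n_templates_selected < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_templates_selected > self.n_templates_library:
            raise ValidationError("cannot select more templates than the library holds")
        lo, hi = self.p_affinity_range
        if not lo < hi:
            raise ValidationError("p_affinity_range must be a non-empty interval")
        if self.metric_noise < 0 or self.pose_jitter < 0 or self.descriptor_noise < 0:
            raise ValidationError("noise levels must be >= 0")
        if not 0.0 <= self.tanimoto_coupling <= 1.0:
            raise ValidationError("tanimoto_coupling must lie in [0, 1]")
        if not self.tags:
            raise ValidationError("at least one representation tag is required")
        if not 0 <= self.n_signal_descriptors <= len(_SIGNAL_DESCRIPTORS):
            raise ValidationError(
                f"n_signal_descriptors must lie in [0, {len(_SIGNAL_DESCRIPTORS)}]"
            )


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    affinity: pd.DataFrame
    poses: dict[str, pd.DataFrame]
    descriptors: pd.DataFrame
    ground_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.affinity.to_csv(out / "affinity.csv", index=False)
        self.descriptors.to_csv(out / "descriptors.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        for tag, df in self.poses.items():
            df.to_csv(out / f"poses_{tag}.csv", index=False)


def _normal(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    # rng.normal(scale=0) is valid and returns zeros; keep one code path
    return rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete, referentially consistent synthetic study."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_ligands, cfg.n_templates_selected
    lo, hi = cfg.p_affinity_range

    ligand_ids = np.array([f"L{i:04d}" for i in range(1, n + 1)])
    template_ids = np.array([f"T{j:03d}" for j in range(1, cfg.n_templates_library + 1)])
    pka = rng.uniform(lo, hi, n)
    anchor_pka = rng.uniform(lo, hi, cfg.n_templates_library)
    qmean_template = rng.normal(0.75, 0.05, cfg.n_templates_library)

    # ligand x library anchor similarities; keep the k most similar templates
    T_full = rng.uniform(0.05, 1.0, (n, cfg.n_templates_library))
    sel = np.argsort(-T_full, axis=1, kind="stable")[:, :k]
    T_sel = np.take_along_axis(T_full, sel, axis=1)

    gain = cfg.tanimoto_coupling * T_sel + (1.0 - cfg.tanimoto_coupling)

    poses: dict[str, pd.DataFrame] = {}
    for tag in cfg.tags:
        shape = (n, k)
        cols: dict[str, np.ndarray] = {}
        for metric in CONSENSUS_COMPONENTS:
            cols[metric] = (
                cfg.metric_slope * gain * pka[:, None]
                + cfg.metric_intercept
                + _normal(rng, cfg.metric_noise, shape)
                + _normal(rng, cfg.pose_jitter, shape)
            )
        cols["AtomeScore"] = np.mean([cols[m] for m in CONSENSUS_COMPONENTS], axis=0)
        for raw_name in CALIBRATABLE_METRICS:
            cols[raw_name] = uncalibrate_score(
                cols[_RAW_FROM_LR[raw_name]], DEFAULT_CALIBRATION[raw_name]
            )
        cols["Tanimoto"] = T_sel
        cols["AnchKd"] = anchor_pka[sel] + _normal(rng, 0.1, shape)
        cols["AnchorFit"] = np.clip(0.4 + 0.4 * T_sel + _normal(rng, 0.1, shape), 0.0, 1.5)
        cols["PlantsFull"] = cols["Plants"] - 3.0 * cols["AnchorFit"]
        cols["AtomSA"] = rng.normal(0.7, 0.1, shape)
        cols["QMean"] = qmean_template[sel] + _normal(rng, 0.02, shape)
        cols["LigandEnergy"] = rng.normal(40.0, 15.0, (n, 1)) + _normal(rng, 3.0, shape)
        cols["LPC"] = rng.normal(3.0, 1.0, shape)
        cols["PSim"] = rng.uniform(0.0, 1.0, shape)
        cols["CpxQuality"] = rng.normal(0.8, 0.08, shape)
        cols["LPE"] = np.abs(rng.normal(1.2, 0.6, shape))

        df = pd.DataFrame({
            "ligand_id": np.repeat(ligand_ids, k),
            "representation_tag": tag,
            "template_id": template_ids[sel].ravel(),
        })
        for metric in METRICS:
            df[metric] = cols[metric].ravel()
        poses[tag] = validate_pose_table(df[list(POSE_TABLE_COLUMNS)])

    descriptors = _descriptor_table(cfg, rng, ligand_ids, pka)
    affinity = pd.DataFrame({
        "ligand_id": ligand_ids,
        "measure_kind": "Ki",
        "value": np.power(10.0, 9.0 - pka),  # nM, so 9 - log10(value) == pka
        "units": "nM",
    })
    ground_truth = pd.DataFrame({"ligand_id": ligand_ids, "p_affinity": pka})
    return SyntheticStudy(cfg, affinity, poses, descriptors, ground_truth)


def _descriptor_table(
    cfg: SimulationConfig, rng: np.random.Generator,
    ligand_ids: np.ndarray, pka: np.ndarray,
) -> pd.DataFrame:
    """Plausible descriptor values; selected columns carry affinity signal.

    Descriptors are molecule properties, hence identical across tags; one row
    per (ligand, tag) keeps the schema of real descriptor tables.
    """
    n = cfg.n_ligands
    centered = pka - pka.mean()
    signal = set(_SIGNAL_DESCRIPTORS[: cfg.n_signal_descriptors])

    def with_signal(base: np.ndarray, name: str, scale: float) -> np.ndarray:
        if name in signal:
            return base + scale * cfg.descriptor_signal * centered \
                + scale * _normal(rng, cfg.descriptor_noise, n)
        return base

    n_bond = rng.integers(8, 45, n)
    n_rot = rng.binomial(n_bond, 0.25)
    values = {
        "MW": np.clip(with_signal(rng.uniform(150.0, 500.0, n), "MW", 25.0), 60.0, None),
        "VABC": np.clip(with_signal(rng.uniform(100.0, 450.0, n), "VABC", 20.0), 50.0, None),
        "nAtom": n_bond + rng.integers(6, 30, n),
        "nBond": n_bond,
        "nRotBond": n_rot,
        "nAromBond": rng.integers(0, 13, n),
        "nHBDon": rng.integers(0, 5, n),
        "nHBAcc": rng.integers(0, 9, n),
        "TPSA": np.clip(with_signal(rng.uniform(0.0, 140.0, n), "TPSA", 10.0), 0.0, None),
        "XLogP": with_signal(rng.uniform(0.0, 6.0, n), "XLogP", 1.0),
        "HybRatio": rng.uniform(0.0, 1.0, n),
        ENGINEERED_NAME: n_rot / n_bond,
    }
    rows = []
    for tag in cfg.tags:
        df = pd.DataFrame({"ligand_id": ligand_ids, "representation_tag": tag})
        for name in (*DESCRIPTOR_NAMES, ENGINEERED_NAME):
            df[name] = values[name]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)[list(DESCRIPTOR_TABLE_COLUMNS)]


# ---------------------------------------------------------------------------
# Presets (frozen after the pilot run; see scripts/pilot.py)
# ---------------------------------------------------------------------------

def preset_low_noise(n_ligands: int = 400, seed: int = 0, **overrides) -> SimulationConfig:
    """Low-noise regime: metric medians closely track the latent affinity."""
    params = dict(
        n_ligands=n_ligands, metric_noise=0.3, pose_jitter=0.2,
        tanimoto_coupling=0.2, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def preset_structure_dominant(n_ligands: int = 300, seed: int = 0, **overrides) -> SimulationConfig:
    """Structure metrics carry strong signal; descriptors only weak signal."""
    params = dict(
        n_ligands=n_ligands, metric_noise=1.0, pose_jitter=0.3,
        tanimoto_coupling=0.2, n_signal_descriptors=2,
        descriptor_signal=0.25, descriptor_noise=1.0, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def preset_noise_free(n_ligands: int = 600, seed: int = 0, **overrides) -> SimulationConfig:
    """Oracle limit: metric medians equal the latent affinity exactly."""
    params = dict(
        n_ligands=n_ligands, metric_noise=0.0, pose_jitter=0.0,
        tanimoto_coupling=0.0, metric_slope=1.0, metric_intercept=0.0, seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# End-to-end recovery experiment
# ---------------------------------------------------------------------------

def build_study_dataset(
    study: SyntheticStudy, mode: str = "combined", min_poses: int = 2
) -> DatasetTable:
    """Aggregate + assemble + label a study into one DatasetTable (all tags)."""
    frames = []
    for tag in study.config.tags:
        agg = aggregate_pose_table(study.poses[tag], min_poses=min_poses)
        desc = study.descriptors[study.descriptors["representation_tag"] == tag]
        frames.append(assemble_feature_table(agg, desc, mode))
    feats = pd.concat(frames, ignore_index=True)
    names = tuple(c for c in feats.columns if c not in ("ligand_id", "representation_tag"))
    return build_dataset(feats, study.affinity, names)


def recovery_experiment(
    config: SimulationConfig,
    mode: str = "combined",
    test_fraction: float = 0.2,
    n_bins: int = 5,
    n_trees: int = 200,
    mtry: int | None = None,
    cv: CVSpec | None = None,
    seed: int | None = None,
    permute_labels: bool = False,
) -> tuple[EvaluationReport, ImportanceTable]:
    """Run generate -> aggregate -> assemble -> split -> train -> evaluate.

    ``permute_labels`` shuffles the per-ligand labels before splitting, which
    serves as the null control: any apparent skill is then leakage.
    """
    seed = config.seed if seed is None else seed
    study = generate_study(config)
    table = build_study_dataset(study, mode=mode)
    if permute_labels:
        rng = np.random.default_rng(seed + 7_919)
        ligs = np.sort(table.df["ligand_id"].unique())
        per = table.df.groupby("ligand_id")["p_affinity"].first().loc[ligs]
        permuted = dict(zip(ligs, rng.permutation(per.to_numpy())))
        df = table.df.copy()
        df["p_affinity"] = df["ligand_id"].map(permuted)
        table = DatasetTable(df, table.feature_names, table.grouping_label)
    train, test = stratified_holdout(
        table, SplitSpec(test_fraction=test_fraction, n_bins=n_bins, seed=seed)
    )
    p = len(table.feature_names)
    grid = [mtry if mtry is not None else max(1, p // 3)]
    model = train_rf(train, cv=cv, mtry_grid=grid, n_trees=n_trees, seed=seed)
    report = evaluate(predict(model, test), test.labels())
    return report, variable_importance(model)
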
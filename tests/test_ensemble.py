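import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensaff.chem import FingerprintBits
from ensaff.docking import METRICS
from ensaff.ensemble import (
    AGGREGATE_TABLE_COLUMNS,
    DockingProtocolConfig,
    TemplateRecord,
    aggregate_metrics,
    aggregate_pose_table,
    assemble_feature_table,
    assemble_features,
    cluster_poses,
    feature_names,
    pose_rmsd,
    rank_templates,
    select_best_pose,
    select_templates,
)
from ensaff.errors import MissingValueError, SchemaError, ValidationError

from conftest import random_pose_table


def _fp(*bits):
    return FingerprintBits(frozenset(bits))


def _library(sims):
    """Templates whose anchor similarity to candidate {1..10} is hand-set.

    candidate has 10 bits; an anchor sharing m of them and adding nothing else
    has tanimoto m/10 exactly when |anchor| = m.
    """
    lib = []
    for i, sim in enumerate(sims):
        m = int(round(sim * 10))
        lib.append(TemplateRecord(f"T{i:02d}", _fp(*range(1, m + 1))))
    return lib


CANDIDATE = _fp(*range(1, 11))


class TestSelectTemplates:
    def test_k_equals_library(self):
        lib = _library([0.5] * 20)
        assert len(select_templates(CANDIDATE, lib, k=20)) == 20

    def test_identical_anchor_ranked_first(self):
        lib = _library([0.3, 1.0, 0.5])
        ranked = rank_templates(CANDIDATE, lib)
        assert ranked[0] == ("T01", 1.0)

    def test_brute_force_sort_oracle(self):
        sims = [0.9, 0.7, 0.7, 0.2, 0.1]
        lib = _library(sims)
        result = select_templates(CANDIDATE, lib, k=3)
        # oracle: exhaustive sort by (-sim, id)
        oracle = [t.template_id for t in sorted(
            lib, key=lambda t: (-len(t.anchor_fingerprint.bits) / 10, t.template_id))][:3]
        assert result == oracle == ["T00", "T01", "T02"]

    def test_k_larger_than_library_warns(self):
        lib = _library([0.5, 0.4])
        with pytest.warns(UserWarning):
            assert len(select_templates(CANDIDATE, lib, k=5)) == 2

    def test_empty_library_errors(self):
        with pytest.raises(ValidationError):
            select_templates(CANDIDATE, [], k=1)

    def test_prefix_stability(self, rng):
        sims = rng.uniform(0, 1, 30).round(1)
        lib = _library(sims)
        prev = select_templates(CANDIDATE, lib, k=1)
        for k in range(2, len(lib) + 1):
            cur = select_templates(CANDIDATE, lib, k=k)
            assert cur[: k - 1] == prev
            prev = cur


class TestClusterPoses:
    def test_identical_poses_one_cluster(self, rng):
        pose = rng.normal(0, 1, (8, 3))
        clusters = cluster_poses([pose.copy() for _ in range(20)], 2.0)
        assert clusters == [list(range(20))]

    def test_two_translated_groups(self, rng):
        base = rng.normal(0, 0.3, (10, 3))
        group_a = [base + rng.normal(0, 0.05, base.shape) for _ in range(6)]
        group_b = [base + 50.0 + rng.normal(0, 0.05, base.shape) for _ in range(4)]
        clusters = cluster_poses(group_a + group_b, 2.0)
        assert len(clusters) == 2
        assert sorted(map(len, clusters)) == [4, 6]

    def test_self_rmsd_zero(self, rng):
        pose = rng.normal(0, 1, (5, 3))
        assert pose_rmsd(pose, pose) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            cluster_poses([], 2.0)

    def test_mismatched_atom_counts_error(self, rng):
        with pytest.raises(ValidationError):
            cluster_poses([rng.normal(0, 1, (5, 3)), rng.normal(0, 1, (6, 3))], 2.0)

    def test_partition_property(self, rng):
        poses = [rng.normal(0, 5, (6, 3)) for _ in range(15)]
        clusters = cluster_poses(poses, 3.0)
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(15))

    def test_threshold_monotonicity(self, rng):
        # lowering the threshold only refines: clusters at t_low nest in t_high
        poses = [rng.normal(0, 4, (6, 3)) for _ in range(12)]
        for t_low, t_high in [(1.0, 2.0), (2.0, 4.0), (4.0, 8.0)]:
            fine = cluster_poses(poses, t_low)
            coarse = cluster_poses(poses, t_high)
            coarse_sets = [set(c) for c in coarse]
            for c in fine:
                assert any(set(c) <= cs for cs in coarse_sets)


class TestSelectBestPose:
    def test_single_cluster_best_member(self):
        assert select_best_pose([[0, 1, 2]], [5.0, 9.0, 7.0]) == 1

    def test_largest_cluster_wins(self):
        clusters = [list(range(12)), list(range(12, 20))]
        scores = {i: 5.0 for i in range(12)}
        scores.update({i: 9.0 for i in range(12, 20)})  # global best in small cluster
        assert select_best_pose(clusters, scores) in clusters[0]

    def test_size_tie_broken_by_mean_score(self):
        clusters = [[0, 1], [2, 3]]
        scores = [7.0, 7.2, 6.8, 7.0]  # means 7.1 vs 6.9
        assert select_best_pose(clusters, scores) == 1

    def test_missing_score_errors(self):
        with pytest.raises(MissingValueError):
            select_best_pose([[0, 1]], {0: 5.0})

    def test_protocol_config_defaults(self):
        cfg = DockingProtocolConfig()
        assert (cfg.n_templates, cfg.shape_restraint_weight, cfg.site_cutoff,
                cfg.poses_per_template) == (20, -3.0, 8.0, 1)
        with pytest.raises(ValidationError):
            DockingProtocolConfig(n_templates=0)


class TestAggregateMetrics:
    def test_constant_metric(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=20)
        df["XScore"] = 5.0
        agg = aggregate_metrics(df)
        assert agg.values["XScore_Med"] == 5.0
        assert agg.values["XScore_SD"] == 0.0
        assert agg.n_poses == 20

    def test_median_and_sample_sd_of_1_to_20(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=20)
        df["DSX"] = np.arange(1.0, 21.0)
        agg = aggregate_metrics(df)
        assert agg.values["DSX_Med"] == 10.5
        # direct formula: sqrt(sum((x - 10.5)^2) / 19)
        expected_sd = np.sqrt(np.sum((np.arange(1, 21) - 10.5) ** 2) / 19)
        assert agg.values["DSX_SD"] == pytest.approx(expected_sd)
        assert agg.values["DSX_SD"] == pytest.approx(5.9161, abs=1e-4)

    def test_minimum_poses_enforced(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=1)
        with pytest.raises(ValidationError):
            aggregate_metrics(df, min_poses=2)
        with pytest.warns(UserWarning):
            agg = aggregate_metrics(df, min_poses=1)
        assert all(agg.values[f"{m}_SD"] == 0.0 for m in METRICS)

    def test_non_numeric_cell_named(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=3)
        df["QMean"] = df["QMean"].astype(object)
        df.loc[1, "QMean"] = "oops"
        with pytest.raises(ValidationError, match="QMean"):
            aggregate_metrics(df)

    def test_mixed_ligands_rejected(self, rng):
        df = random_pose_table(rng, n_ligands=2, n_poses=3)
        with pytest.raises(ValidationError):
            aggregate_metrics(df)

    def test_table_aggregation_matches_per_group(self, rng):
        df = random_pose_table(rng, n_ligands=6, n_poses=7)
        table = aggregate_pose_table(df)
        assert list(table.columns) == list(AGGREGATE_TABLE_COLUMNS)
        for lig, rows in df.groupby("ligand_id"):
            agg = aggregate_metrics(rows)
            got = table[table["ligand_id"] == lig].iloc[0]
            for key, val in agg.values.items():
                assert got[key] == pytest.approx(val)

    def test_order_invariance(self, rng):
        df = random_pose_table(rng, n_ligands=4, n_poses=9)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = aggregate_pose_table(df)
        b = aggregate_pose_table(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_median_within_range_sd_zero_iff_constant(self, rng):
        for _ in range(5):
            df = random_pose_table(rng, n_ligands=3, n_poses=8)
            table = aggregate_pose_table(df)
            for lig, rows in df.groupby("ligand_id"):
                got = table[table["ligand_id"] == lig].iloc[0]
                for m in METRICS:
                    vals = rows[m].astype(float)
                    assert vals.min() <= got[f"{m}_Med"] <= vals.max()
                    assert (got[f"{m}_SD"] == 0.0) == (vals.nunique() == 1)


class TestAssembleFeatures:
    @pytest.mark.parametrize("mode,length", [
        ("structure_only", 38),
        ("ligand_only", 11),
        ("combined", 49),
        ("combined_engineered", 48),
        ("maccs_only", 166),
        ("combined_maccs", 215),
    ])
    def test_mode_lengths(self, mode, length):
        assert len(feature_names(mode)) == length

    def test_combined_names(self):
        names = feature_names("combined")
        assert names[0] == "PlantsFull_Med"
        assert names[1] == "PlantsFull_SD"
        assert all(n.endswith(("_Med", "_SD")) for n in names[:38])

    def test_engineered_replaces_counts(self):
        names = feature_names("combined_engineered")
        assert "nRotB.nB" in names
        assert "nRotBond" not in names
        assert "nBond" not in names

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            feature_names("bogus")

    def test_assemble_vector(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=5)
        agg = aggregate_metrics(df)
        desc = {"MW": 180.0, "VABC": 150.0, "nAtom": 21, "nBond": 13, "nRotBond": 3,
                "nAromBond": 6, "nHBDon": 1, "nHBAcc": 2, "TPSA": 40.0, "XLogP": 2.1,
                "HybRatio": 0.4, "nRotB_nB": 3 / 13}
        vec = assemble_features(agg, desc, "combined_engineered")
        assert len(vec) == 48
        assert vec.values[vec.names.index("nRotB.nB")] == pytest.approx(3 / 13)
        assert vec.values[vec.names.index("MW")] == 180.0

    def test_structure_only_needs_no_descriptors(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=5)
        vec = assemble_features(aggregate_metrics(df), None, "structure_only")
        assert len(vec) == 38

    def test_maccs_mode_requires_fingerprint(self, rng):
        df = random_pose_table(rng, n_ligands=1, n_poses=5)
        agg = aggregate_metrics(df)
        with pytest.raises(ValidationError):
            assemble_features(agg, None, "maccs_only")
        vec = assemble_features(agg, None, "maccs_only", maccs=_fp(1, 50, 166))
        assert len(vec) == 166
        assert vec.values.sum() == 3.0

    def test_table_assembly(self, small_study):
        from ensaff.ensemble import aggregate_pose_table
        agg = aggregate_pose_table(small_study.poses["BDB"])
        feats = assemble_feature_table(agg, small_study.descriptors, "combined")
        assert len(feats) == 25
        assert len(feats.columns) == 2 + 49
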
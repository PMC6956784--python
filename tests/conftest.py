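import numpy as np
import pandas as pd
import pytest

from ensaff.chem import Molecule
from ensaff.docking import METRICS, POSE_TABLE_COLUMNS, CONSENSUS_COMPONENTS
from ensaff.simulate import FIXTURE_SMILES, SimulationConfig, generate_study


@pytest.fixture(scope="session")
def fixture_molecules():
    return {name: Molecule.from_smiles(smi, name) for name, smi in FIXTURE_SMILES}


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SimulationConfig(n_ligands=25, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_pose_table(rng, n_ligands=5, n_poses=6, tag="BDB"):
    """A schema-valid random pose table with an exact consensus column."""
    rows = []
    for i in range(n_ligands):
        for j in range(n_poses):
            row = {
                "ligand_id": f"L{i:03d}",
                "representation_tag": tag,
                "template_id": f"T{j:03d}",
            }
            for m in METRICS:
                row[m] = float(rng.normal(5, 2))
            row["Tanimoto"] = float(rng.uniform(0, 1))
            row["AtomeScore"] = float(np.mean([row[c] for c in CONSENSUS_COMPONENTS]))
            rows.append(row)
    return pd.DataFrame(rows, columns=list(POSE_TABLE_COLUMNS))
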
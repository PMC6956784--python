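"""Ligand-based molecular descriptors, MACCS fingerprints and Tanimoto similarity.

Conventions (frozen here and pinned by the test suite):

* ``nAtom`` counts **all** atoms including implicit hydrogens.
* ``nBond`` counts heavy-atom-heavy-atom bonds only.
* Rotatable bonds are non-ring single bonds between two heavy atoms that each
  have at least two heavy-atom neighbours, excluding amide C-N bonds.  SMARTS
  equivalent: ``[!D1]-&!@[!D1]`` minus ``[NX3][CX3](=[OX1])``.
* ``HybRatio`` is nSP3 / (nSP2 + nSP3) over **carbon** atoms, defined as 0
  when the denominator is 0.
* ``VABC`` is the additive van der Waals volume (atomic increments corrected
  for bond and ring counts); hydrogens are counted explicitly.
* ``XLogP`` is delegated to the toolkit's Crippen log P implementation and
  ``TPSA`` to its topological polar surface area implementation; both are
  regression features, not contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem import MACCSkeys
from rdkit import RDLogger

from .errors import DegenerateInputError, ParseError, ValidationError

RDLogger.DisableLog("rdApp.*")

#: Table of the 11 ligand descriptors, in canonical column order.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MW",
    "VABC",
    "nAtom",
    "nBond",
    "nRotBond",
    "nAromBond",
    "nHBDon",
    "nHBAcc",
    "TPSA",
    "XLogP",
    "HybRatio",
)

#: Engineered flexibility ratio; stored as ``nRotB_nB`` in CSV headers and
#: named ``nRotB.nB`` inside feature vectors.
ENGINEERED_NAME = "nRotB_nB"
ENGINEERED_FEATURE = "nRotB.nB"

DESCRIPTOR_TABLE_COLUMNS: tuple[str, ...] = (
    "ligand_id",
    "representation_tag",
    *DESCRIPTOR_NAMES,
    ENGINEERED_NAME,
)

N_MACCS_BITS = 166

# Atomic van der Waals volume increments (A^3) for the additive VABC scheme.
_VABC_ATOM_VOLUME = {
    "H": 7.24, "B": 40.48, "C": 20.58, "N": 15.60, "O": 14.71, "F": 13.31,
    "Cl": 22.45, "Br": 26.52, "I": 32.52, "P": 24.43, "S": 24.43,
    "As": 26.52, "Se": 28.73, "Si": 38.79, "Te": 36.62, "Ge": 31.06,
    "Sn": 45.83,
}


@dataclass(frozen=True)
class Molecule:
    """A ligand: identifier, parsed structure and provenance tag."""

    ligand_id: str
    mol: Chem.Mol
    representation_tag: str = "BDB"

    def __post_init__(self) -> None:
        if self.mol is None:
            raise ParseError(f"ligand {self.ligand_id!r}: structure failed to parse")
        if self.mol.GetNumHeavyAtoms() < 1:
            raise ValidationError(f"ligand {self.ligand_id!r}: no heavy atoms")

    @classmethod
    def from_smiles(cls, smiles: str, ligand_id: str, representation_tag: str = "BDB") -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"ligand {ligand_id!r}: unparseable SMILES {smiles!r}")
        return cls(ligand_id=ligand_id, mol=mol, representation_tag=representation_tag)


@dataclass(frozen=True)
class DescriptorSet:
    """The 11 ligand descriptors plus the engineered flexibility ratio."""

    MW: float
    VABC: float
    nAtom: int
    nBond: int
    nRotBond: int
    nAromBond: int
    nHBDon: int
    nHBAcc: int
    TPSA: float
    XLogP: float
    HybRatio: float
    nRotB_nB: float

    def __post_init__(self) -> None:
        for name in ("nAtom", "nBond", "nRotBond", "nAromBond", "nHBDon", "nHBAcc"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.MW <= 0:
            raise ValidationError("MW must be > 0")
        if not 0.0 <= self.HybRatio <= 1.0:
            raise ValidationError("HybRatio must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in (*DESCRIPTOR_NAMES, ENGINEERED_NAME)}


@dataclass(frozen=True)
class FingerprintBits:
    """A MACCS key set: indices of set bits, 1-based in [1, 166]."""

    bits: frozenset[int]

    def __post_init__(self) -> None:
        bad = [b for b in self.bits if not 1 <= b <= N_MACCS_BITS]
        if bad:
            raise ValidationError(f"fingerprint bits out of range [1, {N_MACCS_BITS}]: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bits)


def flexibility_ratio(n_rot_bond: int, n_bond: int) -> float:
    """Ratio of rotatable bonds to heavy-atom bonds, in [0, 1]."""
    if n_bond == 0:
        raise DegenerateInputError("flexibility ratio undefined for nBond = 0")
    if n_bond < 0 or n_rot_bond < 0 or n_rot_bond > n_bond:
        raise ValidationError(
            f"require 0 <= nRotBond <= nBond, got nRotBond={n_rot_bond}, nBond={n_bond}"
        )
    return n_rot_bond / n_bond


def _is_amide_bond(bond: Chem.Bond) -> bool:
    for a, b in ((bond.GetBeginAtom(), bond.GetEndAtom()),
                 (bond.GetEndAtom(), bond.GetBeginAtom())):
        if a.GetSymbol() == "C" and b.GetSymbol() == "N":
            for nbr_bond in a.GetBonds():
                other = nbr_bond.GetOtherAtom(a)
                if other.GetSymbol() == "O" and nbr_bond.GetBondType() == Chem.BondType.DOUBLE:
                    return True
    return False


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Non-ring single bonds between heavy atoms of heavy-degree >= 2, amides excluded."""
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:  # degree over heavy neighbours
            continue
        if _is_amide_bond(bond):
            continue
        n += 1
    return n


def vabc_volume(mol: Chem.Mol) -> float:
    """Additive van der Waals volume (A^3) with explicit hydrogens."""
    mol_h = Chem.AddHs(mol)
    total = 0.0
    table = Chem.GetPeriodicTable()
    for atom in mol_h.GetAtoms():
        sym = atom.GetSymbol()
        if sym in _VABC_ATOM_VOLUME:
            total += _VABC_ATOM_VOLUME[sym]
        else:
            # fallback: sphere volume from the tabulated vdW radius
            r = table.GetRvdw(atom.GetAtomicNum())
            total += 4.0 / 3.0 * 3.141592653589793 * r ** 3
    n_bonds = mol_h.GetNumBonds()
    ring_info = mol.GetRingInfo()
    n_arom = 0
    n_nonarom = 0
    for ring in ring_info.BondRings():
        if all(mol.GetBondWithIdx(i).GetIsAromatic() for i in ring):
            n_arom += 1
        else:
            n_nonarom += 1
    return total - 5.92 * n_bonds - 14.7 * n_arom - 3.8 * n_nonarom


def hybridization_ratio(mol: Chem.Mol) -> float:
    n_sp3 = sum(
        1 for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetHybridization() == Chem.HybridizationType.SP3
    )
    n_sp2 = sum(
        1 for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetHybridization() == Chem.HybridizationType.SP2
    )
    denom = n_sp2 + n_sp3
    return n_sp3 / denom if denom else 0.0


def compute_descriptors(molecule: Molecule) -> DescriptorSet:
    """Compute the full descriptor set for one ligand.

    Values are invariant to atom input order: everything is derived from the
    sanitized molecular graph, not from file ordering.
    """
    mol = molecule.mol
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises subclasses of Exception
        raise ValidationError(f"ligand {molecule.ligand_id!r}: {exc}") from exc
    mol_h = Chem.AddHs(mol)
    n_bond = mol.GetNumBonds()
    n_rot = count_rotatable_bonds(mol)
    return DescriptorSet(
        MW=Descriptors.MolWt(mol),
        VABC=vabc_volume(mol),
        nAtom=mol_h.GetNumAtoms(),
        nBond=n_bond,
        nRotBond=n_rot,
        nAromBond=sum(1 for b in mol.GetBonds() if b.GetIsAromatic()),
        nHBDon=rdMolDescriptors.CalcNumHBD(mol),
        nHBAcc=rdMolDescriptors.CalcNumHBA(mol),
        TPSA=rdMolDescriptors.CalcTPSA(mol),
        XLogP=Crippen.MolLogP(mol),
        HybRatio=hybridization_ratio(mol),
        nRotB_nB=(n_rot / n_bond) if n_bond > 0 else 0.0,
    )


def maccs_fingerprint(molecule: Molecule) -> FingerprintBits:
    """166-bit MACCS key fingerprint (bit indices 1..166)."""
    fp = MACCSkeys.GenMACCSKeys(molecule.mol)
    return FingerprintBits(bits=frozenset(b for b in fp.GetOnBits() if b >= 1))


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    """Tanimoto similarity |A&B| / |A|B| of two bit sets; 0 for empty/empty."""
    union = a.bits | b.bits
    if not union:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0", stacklevel=2)
        return 0.0
    return len(a.bits & b.bits) / len(union)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path, representation_tag: str = "BDB") -> list[Molecule]:
    """Read a SMILES file: one molecule per line, optional whitespace-separated id."""
    mols: list[Molecule] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        ligand_id = parts[1] if len(parts) > 1 else f"L{i:04d}"
        mols.append(Molecule.from_smiles(smiles, ligand_id, representation_tag))
    return mols


def read_sdf_file(path: str | Path, representation_tag: str = "BDB") -> list[Molecule]:
    mols: list[Molecule] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ParseError(f"{path}: record {i} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"L{i:04d}"
        mols.append(Molecule(ligand_id=name, mol=mol, representation_tag=representation_tag))
    return mols


def read_mol2_file(path: str | Path, representation_tag: str = "BDB") -> list[Molecule]:
    text = Path(path).read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    if not blocks:
        raise ParseError(f"{path}: no MOL2 molecule records found")
    mols = []
    for i, block in enumerate(blocks, start=1):
        mol = Chem.MolFromMol2Block(block, removeHs=True)
        if mol is None:
            raise ParseError(f"{path}: MOL2 record {i} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"L{i:04d}"
        mols.append(Molecule(ligand_id=name, mol=mol, representation_tag=representation_tag))
    return mols


def read_ligands(path: str | Path, representation_tag: str = "BDB") -> list[Molecule]:
    """Dispatch on file extension: .smi/.smiles, .sdf, .mol2."""
    suffix = Path(path).suffix.lower()
    if suffix in (".smi", ".smiles", ".txt"):
        return read_smiles_file(path, representation_tag)
    if suffix == ".sdf":
        return read_sdf_file(path, representation_tag)
    if suffix == ".mol2":
        return read_mol2_file(path, representation_tag)
    raise ParseError(f"unsupported ligand file extension: {suffix!r}")


def descriptor_table(molecules: Iterable[Molecule]) -> pd.DataFrame:
    """Descriptor table with the canonical column order for a set of ligands."""
    rows = []
    seen: set[tuple[str, str]] = set()
    for m in molecules:
        key = (m.ligand_id, m.representation_tag)
        if key in seen:
            raise ValidationError(f"duplicate ligand_id {m.ligand_id!r} for tag {m.representation_tag!r}")
        seen.add(key)
        row = {"ligand_id": m.ligand_id, "representation_tag": m.representation_tag}
        row.update(compute_descriptors(m).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DESCRIPTOR_TABLE_COLUMNS))


def write_descriptor_table(molecules: Iterable[Molecule], path: str | Path) -> pd.DataFrame:
    df = descriptor_table(molecules)
    df.to_csv(path, index=False)
    return df


def maccs_table(molecules: Iterable[Molecule]) -> pd.DataFrame:
    """One row per ligand: ligand_id then MACCS_1 .. MACCS_166 as 0/1 ints."""
    rows = []
    for m in molecules:
        fp = maccs_fingerprint(m)
        row: dict[str, object] = {"ligand_id": m.ligand_id}
        for i in range(1, N_MACCS_BITS + 1):
            row[f"MACCS_{i}"] = 1 if i in fp.bits else 0
        rows.append(row)
    return pd.DataFrame(rows)
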
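"""SMILES parsing into molecular graphs and property-dataset I/O.

Atom feature layout (length ``ATOM_FEATURE_DIM``):

===========================  ======
element one-hot              100
degree one-hot (0..5, 6+)    7
formal charge one-hot        5  (-2, -1, 0, +1, +2; clipped)
aromatic flag                1
attached-H count (0..4, 5+)  6
===========================  ======

Bond feature layout (length ``BOND_FEATURE_DIM``): bond-order one-hot
(single, double, triple, aromatic), in-ring flag, conjugation flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit's own stderr chatter; we log drops ourselves

logger = logging.getLogger(__name__)

# fixed 100-symbol element table for the one-hot block; index 99 = "other"
ELEMENT_SYMBOLS: tuple[str, ...] = tuple(
    Chem.GetPeriodicTable().GetElementSymbol(z) for z in range(1, 100)
) + ("*",)
_ELEMENT_INDEX = {s: i for i, s in enumerate(ELEMENT_SYMBOLS)}

_DEGREES = 7
_CHARGES = 5
_HCOUNTS = 6
ATOM_FEATURE_DIM = len(ELEMENT_SYMBOLS) + _DEGREES + _CHARGES + 1 + _HCOUNTS
BOND_FEATURE_DIM = 6

_BOND_ORDER_INDEX = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class AtomNode:
    index: int
    symbol: str
    features: np.ndarray


@dataclass(frozen=True)
class BondEdge:
    i: int
    j: int
    features: np.ndarray


@dataclass
class MolecularGraph:
    """Heavy-atom (optionally explicit-H) graph of one molecule.

    Every chemical bond contributes two directed edge records with
    identical feature vectors; node indices are 0-based and contiguous.
    """

    nodes: list[AtomNode]
    edges: list[BondEdge]
    smiles: str
    explicit_h: bool = False
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def num_atoms(self) -> int:
        return len(self.nodes)

    @property
    def num_bonds(self) -> int:
        return len(self.edges) // 2

    def atom_features(self) -> np.ndarray:
        return np.stack([n.features for n in self.nodes])

    def edge_index(self) -> np.ndarray:
        """(2, E) array of directed (source, target) pairs."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        return np.array([[e.i for e in self.edges], [e.j for e in self.edges]], dtype=np.int64)

    def edge_features(self) -> np.ndarray:
        if not self.edges:
            return np.zeros((0, BOND_FEATURE_DIM))
        return np.stack([e.features for e in self.edges])

    def rdkit_mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = _mol_from_smiles(self.smiles, self.explicit_h)
        return self._mol

    def to_json(self) -> str:
        return json.dumps(
            {
                "smiles": self.smiles,
                "explicit_h": self.explicit_h,
                "atoms": [{"index": n.index, "symbol": n.symbol} for n in self.nodes],
                "edges": [[e.i, e.j] for e in self.edges],
            }
        )


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM)
    off = 0
    vec[_ELEMENT_INDEX.get(atom.GetSymbol(), len(ELEMENT_SYMBOLS) - 1)] = 1.0
    off += len(ELEMENT_SYMBOLS)
    vec[off + min(atom.GetDegree(), _DEGREES - 1)] = 1.0
    off += _DEGREES
    vec[off + int(np.clip(atom.GetFormalCharge(), -2, 2)) + 2] = 1.0
    off += _CHARGES
    vec[off] = 1.0 if atom.GetIsAromatic() else 0.0
    off += 1
    vec[off + min(atom.GetTotalNumHs(), _HCOUNTS - 1)] = 1.0
    return vec


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    vec = np.zeros(BOND_FEATURE_DIM)
    vec[_BOND_ORDER_INDEX.get(bond.GetBondType(), 0)] = 1.0
    vec[4] = 1.0 if bond.IsInRing() else 0.0
    vec[5] = 1.0 if bond.GetIsConjugated() else 0.0
    return vec


def _mol_from_smiles(smiles: str, add_hydrogens: bool) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if add_hydrogens:
        mol = Chem.AddHs(mol)
    return mol


def parse_smiles(smiles: str, add_hydrogens: bool = False) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Parameters
    ----------
    smiles
        Non-empty SMILES string. The source string is kept verbatim on the
        graph (the sequence branch tokenizes the input, not a canonical form).
    add_hydrogens
        Include explicit hydrogen nodes. Needed when downstream
        functional-group matching must reference hydrogen atoms.
    """
    if not smiles:
        raise SmilesParseError(smiles)
    mol = _mol_from_smiles(smiles, add_hydrogens)
    nodes = [AtomNode(a.GetIdx(), a.GetSymbol(), _atom_features(a)) for a in mol.GetAtoms()]
    edges: list[BondEdge] = []
    for bond in mol.GetBonds():
        f = _bond_features(bond)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append(BondEdge(i, j, f))
        edges.append(BondEdge(j, i, f))
    if not nodes:
        raise SmilesParseError(smiles)
    return MolecularGraph(nodes=nodes, edges=edges, smiles=smiles, explicit_h=add_hydrogens, _mol=mol)


@dataclass
class PropertyDataset:
    """SMILES records with (possibly partially missing) task labels."""

    records: list[tuple[str, np.ndarray, np.ndarray]]  # (smiles, labels, mask)
    task_names: list[str]
    task_type: Literal["classification", "regression"]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    @property
    def smiles(self) -> list[str]:
        return [r[0] for r in self.records]

    def labels(self) -> np.ndarray:
        return np.stack([r[1] for r in self.records])

    def masks(self) -> np.ndarray:
        return np.stack([r[2] for r in self.records])

    def subset(self, indices: Sequence[int]) -> "PropertyDataset":
        return PropertyDataset(
            records=[self.records[i] for i in indices],
            task_names=list(self.task_names),
            task_type=self.task_type,
        )

    def to_csv(self, path: str | Path, smiles_column: str = "smiles") -> None:
        rows = {smiles_column: self.smiles}
        y, m = self.labels(), self.masks()
        for t, name in enumerate(self.task_names):
            col = y[:, t].astype(object)
            col[~m[:, t]] = None
            rows[name] = col
        pd.DataFrame(rows).to_csv(path, index=False)


class DatasetError(ValueError):
    pass


def load_dataset(
    path: str | Path,
    smiles_column: str = "smiles",
    task_columns: Sequence[str] | None = None,
    task_type: Literal["classification", "regression"] = "classification",
) -> PropertyDataset:
    """Load a CSV of SMILES plus label columns.

    Rows whose SMILES do not parse are dropped (count logged); empty label
    cells become masked entries that never enter a loss.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise DatasetError(f"missing SMILES column {smiles_column!r} in {path}")
    if task_columns is None:
        task_columns = [c for c in df.columns if c != smiles_column]
    missing = [c for c in task_columns if c not in df.columns]
    if missing:
        raise DatasetError(f"missing task columns {missing} in {path}")

    records = []
    dropped = 0
    for _, row in df.iterrows():
        smi = row[smiles_column]
        if not isinstance(smi, str) or Chem.MolFromSmiles(smi) is None:
            dropped += 1
            continue
        raw = np.array([row[c] for c in task_columns], dtype=np.float64)
        mask = ~np.isnan(raw)
        labels = np.where(mask, raw, 0.0)
        if task_type == "classification":
            bad = mask & ~np.isin(labels, (0.0, 1.0))
            if bad.any():
                raise DatasetError(f"non-binary classification label in row for {smi!r}")
        records.append((smi, labels, mask))
    if dropped:
        logger.warning("dropped %d rows with unparsable SMILES from %s", dropped, path)
    return PropertyDataset(records=records, task_names=list(task_columns), task_type=task_type)
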
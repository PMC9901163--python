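"""Molecule I/O: SMILES tables, conformer embedding, atom featurization and
structure-file readers (SDF / PDB / mol2).

All records are heavy-atom only; coordinates are in Angstrom and all indices
are 0-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from . import constants
from .errors import ConfigurationError, EmbeddingError, EmptyStructureError, ParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "read_smiles_table",
    "embed_conformer",
    "featurize_atoms",
    "read_structure_file",
    "write_sdf",
]


@dataclass
class MoleculeRecord:
    """A heavy-atom molecule with features, 3D positions and labels.

    Attributes
    ----------
    mol_id : str
        Identifier (SMILES, file stem, or user supplied).
    atom_features : (n_atoms, F) float array
        Fixed-width per-atom feature rows (see :mod:`ffinet.constants`).
    positions : (n_atoms, 3) float array
        Cartesian coordinates in Angstrom.
    bonds : list of (i, j)
        Unordered heavy-atom bond pairs, i < j.
    labels : (n_tasks,) float array
        Task values; entries where ``label_mask`` is False are missing.
    label_mask : (n_tasks,) bool array
    mol : rdkit Mol or None
        The underlying heavy-atom RDKit molecule (kept for SDF round trips).
    """

    mol_id: str
    atom_features: np.ndarray
    positions: np.ndarray
    bonds: list[tuple[int, int]]
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0))
    label_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[0])

    def validate(self) -> None:
        n = self.n_atoms
        if self.atom_features.shape[0] != n:
            raise ValueError("atom_features row count != n_atoms")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        seen = set()
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range: ({i}, {j})")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)


def _one_hot(value, vocab: Sequence) -> list[float]:
    """One-hot over ``vocab`` with a trailing "other" bucket."""
    row = [0.0] * (len(vocab) + 1)
    try:
        row[vocab.index(value)] = 1.0
    except ValueError:
        row[-1] = 1.0
    return row


_DONOR = Chem.MolFromSmarts(constants.HBOND_DONOR_SMARTS)
_ACCEPTOR = Chem.MolFromSmarts(constants.HBOND_ACCEPTOR_SMARTS)


def featurize_atoms(mol: Chem.Mol) -> np.ndarray:
    """Encode the eight atom-feature families into a fixed-width matrix.

    Parameters
    ----------
    mol : rdkit Mol
        A sanitized heavy-atom molecule (ring/aromaticity perception done).

    Returns
    -------
    (n_atoms, F) float array with F = ``constants.N_FEATURES``.
    """
    donors = {a[0] for a in mol.GetSubstructMatches(_DONOR)}
    acceptors = {a[0] for a in mol.GetSubstructMatches(_ACCEPTOR)}
    rows = []
    for atom in mol.GetAtoms():
        row: list[float] = []
        row += _one_hot(atom.GetAtomicNum(), constants.ATOMIC_NUMBERS)
        row += _one_hot(atom.GetFormalCharge(), constants.FORMAL_CHARGES)
        row += _one_hot(atom.GetChiralTag(), constants.CHIRAL_TAGS)
        row += _one_hot(atom.GetTotalNumHs(), constants.NUM_HYDROGENS)
        row += _one_hot(atom.GetHybridization(), constants.HYBRIDIZATIONS)
        row.append(1.0 if atom.GetIsAromatic() else 0.0)
        row.append(atom.GetMass() / constants.MASS_SCALE)
        row.append(1.0 if atom.GetIdx() in donors else 0.0)
        row.append(1.0 if atom.GetIdx() in acceptors else 0.0)
        rows.append(row)
    out = np.asarray(rows, dtype=float)
    assert out.shape[1] == constants.N_FEATURES
    return out


def _bonds_of(mol: Chem.Mol) -> list[tuple[int, int]]:
    return [
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    ]


def _record_from_mol(
    mol: Chem.Mol,
    mol_id: str,
    labels: np.ndarray | None = None,
    label_mask: np.ndarray | None = None,
) -> MoleculeRecord:
    conf = mol.GetConformer()
    pos = np.array(conf.GetPositions(), dtype=float)
    rec = MoleculeRecord(
        mol_id=mol_id,
        atom_features=featurize_atoms(mol),
        positions=pos,
        bonds=_bonds_of(mol),
        labels=np.zeros(0) if labels is None else np.asarray(labels, dtype=float),
        label_mask=(
            np.zeros(0, dtype=bool) if label_mask is None else np.asarray(label_mask, dtype=bool)
        ),
        mol=mol,
    )
    rec.validate()
    return rec


def embed_conformer(smiles: str, seed: int = 0) -> MoleculeRecord:
    """Parse a SMILES and generate one 3D conformer with seeded ETKDG.

    Hydrogens are used during embedding and then removed; the returned record
    is heavy-atom only.  Embedding falls back once to random-coordinate
    initialisation; if that also fails an :class:`EmbeddingError` is raised.
    The output is a pure function of ``(smiles, seed)``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(molh, params) != 0:
        logger.warning("ETKDG failed for %r; retrying with random coordinates", smiles)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            raise EmbeddingError(f"conformer embedding failed for {smiles!r}")
    heavy = Chem.RemoveHs(molh)
    return _record_from_mol(heavy, mol_id=smiles)


def read_smiles_table(
    path: str | os.PathLike,
    smiles_column: str,
    label_columns: Iterable[str],
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Read a delimited table of SMILES and numeric labels.

    Returns a list of ``(smiles, labels, label_mask)``; empty label cells get
    a False mask entry.  Rows with unparseable SMILES are skipped with a
    logged warning carrying the row index.
    """
    label_columns = list(label_columns)
    with open(path) as fh:
        header = fh.readline()
    # sniff the delimiter from the header (csv.Sniffer mangles 1-column files)
    sep = "\t" if "\t" in header else ("," if "," in header else (";" if ";" in header else r"\s+"))
    df = pd.read_csv(path, sep=sep, engine="python" if sep == r"\s+" else "c")
    missing = [c for c in [smiles_column, *label_columns] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing column(s) {missing} in {path}")
    out = []
    for idx, row in df.iterrows():
        smi = row[smiles_column]
        if not isinstance(smi, str) or Chem.MolFromSmiles(smi) is None:
            logger.warning("skipping row %d: unparseable SMILES %r", idx, smi)
            continue
        vals = pd.to_numeric(row[label_columns], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(vals)
        vals = np.where(mask, vals, 0.0)
        out.append((smi, vals, mask))
    return out


def read_structure_file(path: str | os.PathLike, format: str | None = None) -> MoleculeRecord:
    """Read a single structure (SDF / PDB / mol2) with its file coordinates.

    Bonds come from file connectivity; for PDB files without CONECT records
    RDKit perceives bonds from interatomic distances and a warning is logged.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(path, removeHs=False)
        mol = next((m for m in supplier if m is not None), None)
    elif fmt == "pdb":
        with open(path) as fh:
            has_conect = any(line.startswith("CONECT") for line in fh)
        if not has_conect:
            logger.warning("%s has no CONECT records; perceiving bonds from distances", path)
        mol = Chem.MolFromPDBFile(path, removeHs=False, proximityBonding=not has_conect)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(path, removeHs=False)
    else:
        raise ConfigurationError(f"unsupported structure format: {fmt!r}")
    if mol is None:
        raise IOError(f"unreadable {fmt} file: {path}")
    if mol.GetNumConformers() == 0:
        raise IOError(f"no coordinates in {path}")
    mol = Chem.RemoveHs(mol, sanitize=False)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # Pocket files routinely trip valence checks; fall back to the
        # minimal perception needed for featurization.
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
            | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
            | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION
            | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
            catchErrors=True,
        )
    if mol.GetNumAtoms() == 0:
        raise EmptyStructureError(f"zero atoms in {path}")
    stem = os.path.splitext(os.path.basename(path))[0]
    return _record_from_mol(mol, mol_id=stem)


def write_sdf(records: MoleculeRecord | Iterable[MoleculeRecord], path: str | os.PathLike) -> None:
    """Write record(s) to a V2000 SDF file (positions + connectivity)."""
    if isinstance(records, MoleculeRecord):
        records = [records]
    writer = Chem.SDWriter(os.fspath(path))
    try:
        for rec in records:
            if rec.mol is None:
                raise ValueError(f"record {rec.mol_id} has no underlying Mol to write")
            mol = Chem.Mol(rec.mol)
            conf = mol.GetConformer()
            for i in range(mol.GetNumAtoms()):
                x, y, z = rec.positions[i]
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.SetProp("_Name", rec.mol_id)
            writer.write(mol)
    finally:
        writer.close()
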
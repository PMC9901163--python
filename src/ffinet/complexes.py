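"""Protein-ligand complex graphs.

The bonded graphs of protein (pocket) and ligand are preserved unchanged and
merged; intermolecular atom pairs closer than a cutoff (default 5 Angstrom,
strict inequality) are added as typed nonbonded 1-hop edges.  2-/3-hop chains
are built over the bonded edges only — angle and torsion terms are defined
over bonded chains — so deleting the nonbonded edges recovers the disjoint
union of the inputs exactly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError
from .geometry import BasisScaler, assemble_basis, nonbonded_basis
from .khop import build_khop_index
from .model import EDGE_BONDED, EDGE_NONBONDED_INTER, HOP1_WIDTH, GraphData
from .molio import MoleculeRecord, read_structure_file

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CUTOFF",
    "ComplexGraph",
    "intermolecular_pairs",
    "merge_complex",
    "graph_from_complex",
    "read_pdbbind_index",
    "load_pdbbind_complex",
]

DEFAULT_CUTOFF = 5.0  # Angstrom


@dataclass
class ComplexGraph:
    """Merged protein+ligand graph (protein atoms first, ligand offset).

    ``nonbonded_pairs`` are directed (target, source) index pairs crossing
    the protein/ligand boundary; ``bonds`` are the union of the two bonded
    graphs with ligand indices offset by ``n_protein_atoms``.
    """

    atom_features: np.ndarray
    positions: np.ndarray
    bonds: list[tuple[int, int]]
    nonbonded_pairs: np.ndarray  # (P, 2) directed
    n_protein_atoms: int
    affinity: float = float("nan")
    complex_id: str = ""

    @property
    def n_atoms(self) -> int:
        return int(self.positions.shape[0])

    # labelled-record interface used by train.fit / train.evaluate
    @property
    def labels(self) -> np.ndarray:
        return np.array([self.affinity])

    @property
    def label_mask(self) -> np.ndarray:
        return np.array([np.isfinite(self.affinity)])


def intermolecular_pairs(
    pos_a: np.ndarray, pos_b: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> list[tuple[int, int]]:
    """All (a, b) with ||pos_a[a] - pos_b[b]|| strictly below ``cutoff``."""
    if cutoff <= 0:
        return []
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    if pos_a.shape[0] == 0 or pos_b.shape[0] == 0:
        return []
    tree = cKDTree(pos_b)
    out = []
    for a, hits in enumerate(tree.query_ball_point(pos_a, r=cutoff)):
        for b in hits:
            if np.linalg.norm(pos_a[a] - pos_b[b]) < cutoff:  # enforce strict <
                out.append((a, int(b)))
    return sorted(out)


def merge_complex(
    protein: MoleculeRecord,
    ligand: MoleculeRecord,
    cutoff: float = DEFAULT_CUTOFF,
    affinity: float = float("nan"),
    complex_id: str = "",
    pocket_radius: float | None = None,
) -> ComplexGraph:
    """Merge two records into a complex graph with typed nonbonded edges.

    ``pocket_radius``, if given, prunes protein atoms farther than that
    radius from every ligand atom (bonds among pruned atoms are dropped).
    """
    if protein.n_atoms == 0 or ligand.n_atoms == 0:
        raise EmptyStructureError("empty protein or ligand")

    p_pos, p_feat, p_bonds = protein.positions, protein.atom_features, protein.bonds
    if pocket_radius is not None:
        tree = cKDTree(ligand.positions)
        dmin, _ = tree.query(p_pos)
        keep = np.nonzero(dmin <= pocket_radius)[0]
        if keep.size == 0:
            raise EmptyStructureError("pocket_radius pruned every protein atom")
        remap = {int(old): new for new, old in enumerate(keep)}
        p_pos = p_pos[keep]
        p_feat = p_feat[keep]
        p_bonds = [
            (remap[i], remap[j]) for i, j in p_bonds if i in remap and j in remap
        ]

    n_p = p_pos.shape[0]
    bonds = list(p_bonds) + [(i + n_p, j + n_p) for i, j in ligand.bonds]
    inter = intermolecular_pairs(p_pos, ligand.positions, cutoff)
    directed = []
    for a, b in inter:
        directed.append((a, b + n_p))
        directed.append((b + n_p, a))
    nb = (
        np.array(sorted(directed), dtype=np.int64)
        if directed
        else np.zeros((0, 2), dtype=np.int64)
    )
    return ComplexGraph(
        atom_features=np.concatenate([p_feat, ligand.atom_features], axis=0),
        positions=np.concatenate([p_pos, ligand.positions], axis=0),
        bonds=bonds,
        nonbonded_pairs=nb,
        n_protein_atoms=n_p,
        affinity=affinity,
        complex_id=complex_id,
    )


def graph_from_complex(cg: ComplexGraph, scaler: BasisScaler | None = None) -> GraphData:
    """Build model input: bonded hop-1/2/3 index plus nonbonded hop-1 rows.

    Nonbonded rows carry the nonbonded basis of their distance in the
    width-5 hop-1 layout; when a scaler is present their columns reuse the
    hop-2 nonbonded statistics (same functional family and range).
    """
    index = build_khop_index(cg.bonds, cg.n_atoms)
    sb = assemble_basis(cg.positions, index)
    if scaler is not None:
        sb_scaled = scaler.transform(sb)
    else:
        sb_scaled = sb

    n_b = index.hop1.shape[0]
    n_nb = cg.nonbonded_pairs.shape[0]
    m1 = np.zeros((n_b + n_nb, HOP1_WIDTH))
    m1[:n_b, :2] = sb_scaled.m1
    if n_nb:
        d = cg.positions[cg.nonbonded_pairs[:, 0]] - cg.positions[cg.nonbonded_pairs[:, 1]]
        nb = nonbonded_basis(np.linalg.norm(d, axis=1))
        if scaler is not None and scaler.fitted:
            nb = (nb - scaler.mean_[2][2:]) / scaler.std_[2][2:]
        m1[n_b:, 2:] = nb
    paths1 = (
        np.concatenate([index.hop1, cg.nonbonded_pairs], axis=0)
        if n_nb
        else index.hop1
    )
    edge_type = np.concatenate(
        [np.full(n_b, EDGE_BONDED, dtype=np.int64), np.full(n_nb, EDGE_NONBONDED_INTER, dtype=np.int64)]
    )
    return GraphData(
        x=cg.atom_features,
        paths={1: paths1, 2: index.hop2, 3: index.hop3},
        basis={1: m1, 2: sb_scaled.m2, 3: sb_scaled.m3},
        edge_type=edge_type,
        graph_seg=np.zeros(cg.n_atoms, dtype=np.int64),
        n_graphs=1,
    )


def read_pdbbind_index(path: str | os.PathLike, code_col: int = 0, affinity_col: int = 3) -> dict[str, float]:
    """Parse a PDBBind-style index file into {complex code: affinity}.

    Lines starting with ``#`` are comments; columns are whitespace separated
    and the affinity column holds the -log Kd/Ki value.
    """
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                out[parts[code_col]] = float(parts[affinity_col])
            except (IndexError, ValueError):
                logger.warning("skipping malformed index line: %r", line)
    return out


def load_pdbbind_complex(
    root: str | os.PathLike,
    code: str,
    affinity: float = float("nan"),
    cutoff: float = DEFAULT_CUTOFF,
    pocket_radius: float | None = None,
    ligand_suffixes: Sequence[str] = ("_ligand.sdf", "_ligand.mol2"),
    pocket_suffix: str = "_pocket.pdb",
) -> ComplexGraph:
    """Load one complex from a PDBBind-style per-complex directory."""
    cdir = os.path.join(os.fspath(root), code)
    ligand = None
    for suffix in ligand_suffixes:
        lpath = os.path.join(cdir, code + suffix)
        if os.path.exists(lpath):
            ligand = read_structure_file(lpath)
            break
    if ligand is None:
        raise IOError(f"no ligand file for complex {code} under {cdir}")
    pocket = read_structure_file(os.path.join(cdir, code + pocket_suffix))
    return merge_complex(
        pocket, ligand, cutoff=cutoff, affinity=affinity,
        complex_id=code, pocket_radius=pocket_radius,
    )
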
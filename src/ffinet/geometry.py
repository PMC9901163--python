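"""Internal coordinates (distance / angle / signed dihedral) for indexed
paths and their expansion into force-field-functional-form embedding bases.

Basis layout (fixed column order and count):

* hop 1 (bonded):      ``{r, r^2}``                                    (2)
* hop 2 (angle + NB):  ``{theta, theta^2, r^-1, r^-12, r^-6}``         (5)
* hop 3 (torsion+NB):  ``{cos phi, cos 2phi, cos 3phi,
                          sin phi, sin 2phi, sin 3phi,
                          r^-1, r^-12, r^-6}``                         (9)

The nonbonded columns use the end-pair (i...j) distance of the path.  r is in
Angstrom; theta in [0, pi] radians; phi in (-pi, pi] radians, right-handed
two-argument-arctangent sign convention.  Distances entering inverse powers
are clamped to >= ``CLAMP_R`` Angstrom so r^-12 cannot diverge on distorted
conformers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError
from .khop import KHopIndex

logger = logging.getLogger(__name__)

__all__ = [
    "CLAMP_R",
    "SpatialBasis",
    "path_distances",
    "path_angles",
    "path_dihedrals",
    "bonded_basis",
    "angle_basis",
    "torsion_basis",
    "nonbonded_basis",
    "assemble_basis",
    "BasisScaler",
]

CLAMP_R = 0.8  # Angstrom; below any physical heavy-atom separation

BASIS_WIDTHS = {1: 2, 2: 5, 3: 9}


@dataclass
class SpatialBasis:
    """Per-path embedding-basis matrices, row-aligned with a KHopIndex."""

    m1: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    m2: np.ndarray = field(default_factory=lambda: np.zeros((0, 5)))
    m3: np.ndarray = field(default_factory=lambda: np.zeros((0, 9)))

    def hop(self, k: int) -> np.ndarray:
        return (self.m1, self.m2, self.m3)[k - 1]


def path_distances(positions: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Euclidean distances for (i, j) pairs, in Angstrom."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.shape[0] == 0:
        return np.zeros(0)
    d = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    bad = np.nonzero(r < 1e-6)[0]
    if bad.size:
        i, j = pairs[bad[0]]
        raise DegenerateGeometryError(f"coincident atoms in pair ({i}, {j})")
    return r


def path_angles(positions: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angle at the middle atom m of each (i, m, j) triple, in [0, pi]."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    if triples.shape[0] == 0:
        return np.zeros(0)
    u = positions[triples[:, 0]] - positions[triples[:, 1]]
    v = positions[triples[:, 2]] - positions[triples[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = np.nonzero((nu < 1e-6) | (nv < 1e-6))[0]
    if bad.size:
        raise DegenerateGeometryError(f"zero-length ray in triple {tuple(triples[bad[0]])}")
    cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def path_dihedrals(positions: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral of each (i, a, b, j) quad, in (-pi, pi].

    Right-handed convention: phi = atan2(dot(cross(n1, n2), u_b), dot(n1, n2))
    with n1 = b0 x b1, n2 = b1 x b2 the plane normals and u_b the unit central
    bond.  Reversing the quad preserves phi; mirroring coordinates negates it.
    Collinear (i,a,b) or (a,b,j) triples yield phi = 0 with a logged warning.
    """
    quads = np.asarray(quads, dtype=np.int64).reshape(-1, 4)
    if quads.shape[0] == 0:
        return np.zeros(0)
    b0 = positions[quads[:, 1]] - positions[quads[:, 0]]
    b1 = positions[quads[:, 2]] - positions[quads[:, 1]]
    b2 = positions[quads[:, 3]] - positions[quads[:, 2]]
    nb1 = np.linalg.norm(b1, axis=1)
    bad = np.nonzero(nb1 < 1e-6)[0]
    if bad.size:
        raise DegenerateGeometryError(f"degenerate central bond in quad {tuple(quads[bad[0]])}")
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    ln1 = np.linalg.norm(n1, axis=1)
    ln2 = np.linalg.norm(n2, axis=1)
    collinear = (ln1 < 1e-8) | (ln2 < 1e-8)
    if np.any(collinear):
        logger.warning(
            "%d collinear quad(s); dihedral set to 0 (first: %s)",
            int(collinear.sum()),
            tuple(quads[np.nonzero(collinear)[0][0]]),
        )
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b1 / nb1[:, None])
    phi = np.arctan2(y, x)
    phi[collinear] = 0.0
    # map exactly -pi to +pi so the range is (-pi, pi]
    phi[phi == -np.pi] = np.pi
    return phi


def bonded_basis(r) -> np.ndarray:
    """``{r, r^2}`` evaluated elementwise."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    return np.stack([r, r**2], axis=-1)


def angle_basis(theta) -> np.ndarray:
    """``{theta, theta^2}`` evaluated elementwise."""
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    return np.stack([t, t**2], axis=-1)


def torsion_basis(phi) -> np.ndarray:
    """``{cos phi, cos 2phi, cos 3phi, sin phi, sin 2phi, sin 3phi}``."""
    p = np.atleast_1d(np.asarray(phi, dtype=float))
    return np.stack(
        [np.cos(p), np.cos(2 * p), np.cos(3 * p), np.sin(p), np.sin(2 * p), np.sin(3 * p)],
        axis=-1,
    )


def nonbonded_basis(r) -> np.ndarray:
    """``{r^-1, r^-12, r^-6}`` with r clamped to >= CLAMP_R."""
    r = np.maximum(np.atleast_1d(np.asarray(r, dtype=float)), CLAMP_R)
    return np.stack([r**-1, r**-12, r**-6], axis=-1)


def assemble_basis(positions: np.ndarray, index: KHopIndex) -> SpatialBasis:
    """Evaluate the hop-k bases for every indexed path.

    Rows of ``m1/m2/m3`` align 1:1 with ``hop1/hop2/hop3``; nonbonded
    sub-vectors use the end-pair (i...j) distance of each path.
    """
    positions = np.asarray(positions, dtype=float)
    out = SpatialBasis()
    if index.hop1.shape[0]:
        out.m1 = bonded_basis(path_distances(positions, index.hop1))
    if index.hop2.shape[0]:
        theta = path_angles(positions, index.hop2)
        r_end = path_distances(positions, index.hop2[:, [0, 2]])
        out.m2 = np.concatenate([angle_basis(theta), nonbonded_basis(r_end)], axis=1)
    if index.hop3.shape[0]:
        phi = path_dihedrals(positions, index.hop3)
        r_end = path_distances(positions, index.hop3[:, [0, 3]])
        out.m3 = np.concatenate([torsion_basis(phi), nonbonded_basis(r_end)], axis=1)
    return out


class BasisScaler:
    """Per-column z-score standardisation of the hop bases.

    Statistics are frozen from the training split (``fit``) and applied with
    ``transform``; columns with (near-)zero variance get unit scale.  The
    basis columns span orders of magnitude (r^2 vs r^-12), which conditions
    the learnable projections poorly without this.
    """

    STD_FLOOR = 1e-8

    def __init__(self) -> None:
        self.mean_: dict[int, np.ndarray] = {}
        self.std_: dict[int, np.ndarray] = {}

    @property
    def fitted(self) -> bool:
        return bool(self.mean_)

    def fit(self, bases: list[SpatialBasis]) -> "BasisScaler":
        for k in (1, 2, 3):
            rows = [b.hop(k) for b in bases if b.hop(k).shape[0]]
            width = BASIS_WIDTHS[k]
            if rows:
                m = np.concatenate(rows, axis=0)
                mean = m.mean(axis=0)
                std = m.std(axis=0)
                std = np.where(std < self.STD_FLOOR, 1.0, std)
            else:
                mean = np.zeros(width)
                std = np.ones(width)
            self.mean_[k] = mean
            self.std_[k] = std
        return self

    def transform(self, basis: SpatialBasis) -> SpatialBasis:
        if not self.fitted:
            raise RuntimeError("BasisScaler.transform called before fit")
        out = SpatialBasis()
        for k, name in ((1, "m1"), (2, "m2"), (3, "m3")):
            m = basis.hop(k)
            if m.shape[0]:
                setattr(out, name, (m - self.mean_[k]) / self.std_[k])
            else:
                setattr(out, name, m.copy())
        return out

    def to_dict(self) -> dict:
        return {
            "mean": {str(k): v.tolist() for k, v in self.mean_.items()},
            "std": {str(k): v.tolist() for k, v in self.std_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisScaler":
        sc = cls()
        sc.mean_ = {int(k): np.asarray(v, dtype=float) for k, v in d["mean"].items()}
        sc.std_ = {int(k): np.asarray(v, dtype=float) for k, v in d["std"].items()}
        return sc
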
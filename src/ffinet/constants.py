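"""Versioned atom-feature encoding vocabularies.

Eight feature families are encoded per heavy atom: atomic number, formal
charge, chirality, number of bonded hydrogens, hybridization, aromaticity,
atomic mass and hydrogen-bond donor/acceptor flags.  Categorical families are
one-hot with a trailing "other" bucket so the feature width is fixed across
molecules.  Changing any vocabulary requires bumping FEATURE_VERSION.
"""

from rdkit import Chem

FEATURE_VERSION = 1

# Heavy atoms only; hydrogens are folded into the H-count feature.
ATOMIC_NUMBERS = [5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53]

FORMAL_CHARGES = [-2, -1, 0, 1, 2]

CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
]

NUM_HYDROGENS = [0, 1, 2, 3, 4]

HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]

# Mass is divided by this before entering the feature vector.
MASS_SCALE = 100.0

# RDKit-convention hydrogen-bond donor / acceptor definitions.
HBOND_DONOR_SMARTS = (
    "[$([N;!H0;v3]),$([N;!H0;+1;v4]),$([O,S;H1;+0]),$([n;H1;+0])]"
)
HBOND_ACCEPTOR_SMARTS = (
    "[$([O,S;H1;v2]-[!$(*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
    "$([N;v3;!$(N-*=!@[O,N,P,S])]),$([nH0,o,s;+0])]"
)

# one-hot (+other) widths + aromatic flag + mass + donor + acceptor
N_FEATURES = (
    (len(ATOMIC_NUMBERS) + 1)
    + (len(FORMAL_CHARGES) + 1)
    + (len(CHIRAL_TAGS) + 1)
    + (len(NUM_HYDROGENS) + 1)
    + (len(HYBRIDIZATIONS) + 1)
    + 1  # aromaticity
    + 1  # scaled mass
    + 2  # H-bond donor, acceptor
)
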
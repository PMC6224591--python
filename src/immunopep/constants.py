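"""Amino-acid alphabet, background frequencies and physicochemical scales.

The background table is the mean amino-acid composition of the reviewed human
(Swiss-Prot) proteome, the reference against which positional enrichment of
HLA-ligand residues is scored.  The physicochemical table carries the four
per-residue properties used to embed peptides in feature space: average
molecular weight of the free amino acid (Da), Kyte-Doolittle hydropathy index
(unitless), theoretical maximum solvent-accessible surface area (Tien et al.
2013, A^2) and the isoelectric point of the free amino acid (pH units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 20 standard one-letter codes, alphabetical; every positional array in
#: this package is indexed in this order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that may appear in third-party peptide tables but are not part of
#: the 20-letter alphabet (ambiguity codes and rare residues).
NONSTANDARD_LETTERS: frozenset[str] = frozenset("BJOUXZ")

# Mean residue frequencies (%) of the reviewed human Swiss-Prot proteome.
_SWISSPROT_HUMAN_PERCENT = {
    "A": 7.01, "R": 5.64, "N": 3.59, "D": 4.74, "C": 2.30,
    "Q": 4.77, "E": 7.10, "G": 6.58, "H": 2.63, "I": 4.33,
    "L": 9.97, "K": 5.72, "M": 2.13, "F": 3.65, "P": 6.31,
    "S": 8.33, "T": 5.36, "W": 1.22, "Y": 2.66, "V": 5.96,
}


def swissprot_human_frequencies() -> pd.Series:
    """Embedded human Swiss-Prot mean amino-acid frequencies (sum to 1)."""
    s = pd.Series({aa: _SWISSPROT_HUMAN_PERCENT[aa] for aa in AMINO_ACIDS}, dtype=float)
    return s / s.sum()


# residue -> (molecular weight Da, hydropathy, max surface area A^2, pI)
_PROPERTY_ROWS = {
    "A": (89.09, 1.8, 129.0, 6.00),
    "C": (121.16, 2.5, 167.0, 5.07),
    "D": (133.10, -3.5, 193.0, 2.77),
    "E": (147.13, -3.5, 223.0, 3.22),
    "F": (165.19, 2.8, 240.0, 5.48),
    "G": (75.07, -0.4, 104.0, 5.97),
    "H": (155.15, -3.2, 224.0, 7.59),
    "I": (131.17, 4.5, 197.0, 6.02),
    "K": (146.19, -3.9, 236.0, 9.74),
    "L": (131.17, 3.8, 201.0, 5.98),
    "M": (149.21, 1.9, 224.0, 5.74),
    "N": (132.12, -3.5, 195.0, 5.41),
    "P": (115.13, -1.6, 159.0, 6.30),
    "Q": (146.15, -3.5, 225.0, 5.65),
    "R": (174.20, -4.5, 274.0, 10.76),
    "S": (105.09, -0.8, 155.0, 5.68),
    "T": (119.12, -0.7, 172.0, 5.60),
    "V": (117.15, 4.2, 174.0, 5.96),
    "W": (204.23, -0.9, 285.0, 5.89),
    "Y": (181.19, -1.3, 263.0, 5.66),
}

PROPERTY_NAMES = ("mol_weight", "hydropathy", "surface_area", "isoelectric_point")


def default_property_table() -> pd.DataFrame:
    """Default per-residue physicochemical table (rows indexed by residue).

    Any complete replacement with the same shape/index is accepted by the
    feature encoder, so alternative scales can be swapped in via config.
    """
    df = pd.DataFrame.from_dict(_PROPERTY_ROWS, orient="index", columns=list(PROPERTY_NAMES))
    return df.loc[list(AMINO_ACIDS)].astype(float)


def validate_property_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a property table covers the 20 residues with finite values."""
    missing = set(AMINO_ACIDS) - set(table.index)
    if missing:
        raise ValueError(f"property table missing residues: {sorted(missing)}")
    sub = table.loc[list(AMINO_ACIDS)].astype(float)
    if not np.isfinite(sub.to_numpy()).all():
        raise ValueError("property table contains non-finite values")
    return sub
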
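"""Packaged per-amino-acid constant tables.

All tables are keyed by one-letter amino-acid code and cover exactly the 20
standard residues.  Sources:

* ``PHYSICOCHEMICAL`` — ten scalar properties per residue assembled from the
  AAindex collection and standard references: heavy-atom count, formal
  side-chain charge, potential hydrogen-bond count, monoisotopic residue mass
  (FASG760101), Kyte–Doolittle hydropathy (KYTJ820101), Hopp–Woods
  hydrophilicity (HOPT810101), Grantham polarity (GRAR740102), Charton–Charton
  polarizability (CHAM820101), Chou–Fasman helix propensity (CHOP780201) and
  mean accessible surface area in folded proteins (ROSM880102-like).
* ``PKA`` — alpha-carboxyl and alpha-amino pKa values (Nelson & Cox,
  *Lehninger Principles of Biochemistry*).
* ``MAX_ASA`` — maximum solvent accessibility per residue type
  (Rost & Sander, 1994), used to turn absolute ASA into relative ASA.
* ``VDW_RADII`` — per-element van der Waals radii for the sphere-sampling
  accessibility calculation.
* ``LSE_PROPENSITY`` — constructed 8-state secondary-structure propensity
  table used by the local-structural-entropy feature (an in-package
  approximation; see docs/methods.md).
* ``synthetic_pair_potentials`` — a synthetic stand-in residue-pair contact
  potential (210 unordered pairs) built from a hydrophobicity-product model.
"""

from __future__ import annotations

import numpy as np

AA1: str = "ACDEFGHIKLMNPQRSTVWY"
AA_LIST = list(AA1)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

RNA_CODES = ("A", "U", "G", "C")
RNA_RESNAMES = {"A": "A", "U": "U", "G": "G", "C": "C",
                "RA": "A", "RU": "U", "RG": "G", "RC": "C",
                "ADE": "A", "URA": "U", "GUA": "G", "CYT": "C"}

# columns: n_heavy_atoms, charge, h_bonds, mass, hydropathy, hydrophilicity,
#          polarity, polarizability, helix_propensity, avg_asa
PHYSICOCHEMICAL: dict[str, tuple[float, ...]] = {
    "A": (5, 0.0, 0, 71.08, 1.8, -0.5, 8.1, 0.046, 1.42, 31.5),
    "R": (11, 1.0, 4, 156.19, -4.5, 3.0, 10.5, 0.291, 0.98, 93.8),
    "N": (8, 0.0, 4, 114.10, -3.5, 0.2, 11.6, 0.134, 0.67, 62.2),
    "D": (8, -1.0, 4, 115.09, -3.5, 3.0, 13.0, 0.105, 1.01, 60.9),
    "C": (6, 0.0, 1, 103.14, 2.5, -1.0, 5.5, 0.128, 0.70, 13.9),
    "Q": (9, 0.0, 4, 128.13, -3.5, 0.2, 10.5, 0.180, 1.11, 74.0),
    "E": (9, -1.0, 4, 129.12, -3.5, 3.0, 12.3, 0.151, 1.51, 72.3),
    "G": (4, 0.0, 0, 57.05, -0.4, 0.0, 9.0, 0.000, 0.57, 25.2),
    "H": (10, 0.1, 2, 137.14, -3.2, -0.5, 10.4, 0.230, 1.00, 46.7),
    "I": (8, 0.0, 0, 113.16, 4.5, -1.8, 5.2, 0.186, 1.08, 23.0),
    "L": (8, 0.0, 0, 113.16, 3.8, -1.8, 4.9, 0.186, 1.21, 29.0),
    "K": (9, 1.0, 2, 128.17, -3.9, 3.0, 11.3, 0.219, 1.16, 110.3),
    "M": (8, 0.0, 0, 131.19, 1.9, -1.3, 5.7, 0.221, 1.45, 30.5),
    "F": (11, 0.0, 0, 147.18, 2.8, -2.5, 5.2, 0.290, 1.13, 28.7),
    "P": (7, 0.0, 0, 97.12, -1.6, 0.0, 8.0, 0.131, 0.57, 53.7),
    "S": (6, 0.0, 2, 87.08, -0.8, 0.3, 9.2, 0.062, 0.77, 44.2),
    "T": (7, 0.0, 2, 101.10, -0.7, -0.4, 8.6, 0.108, 0.83, 46.0),
    "W": (14, 0.0, 1, 186.21, -0.9, -3.4, 5.4, 0.409, 1.08, 41.7),
    "Y": (12, 0.0, 2, 163.18, -1.3, -2.3, 6.2, 0.298, 0.69, 59.1),
    "V": (7, 0.0, 0, 99.13, 4.2, -1.5, 5.9, 0.140, 1.06, 23.5),
}

# (pK1 alpha-COOH, pK2 alpha-NH3+)
PKA: dict[str, tuple[float, float]] = {
    "A": (2.34, 9.69), "R": (2.17, 9.04), "N": (2.02, 8.80),
    "D": (1.88, 9.60), "C": (1.96, 10.28), "Q": (2.17, 9.13),
    "E": (2.19, 9.67), "G": (2.34, 9.60), "H": (1.82, 9.17),
    "I": (2.36, 9.68), "L": (2.36, 9.60), "K": (2.18, 8.95),
    "M": (2.28, 9.21), "F": (1.83, 9.13), "P": (1.99, 10.96),
    "S": (2.21, 9.15), "T": (2.11, 9.62), "W": (2.38, 9.39),
    "Y": (2.20, 9.11), "V": (2.32, 9.62),
}

MAX_ASA: dict[str, float] = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "D": 1.20, "SE": 1.90,
}
DEFAULT_VDW = 1.70

# PSI-BLAST PSSM column order.
PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"

# 8-state labels in the order used by the LSE propensity table.
LSE_STATES = ("B", "E", "G", "H", "I", "S", "T", "C")


def _lse_table() -> dict[str, np.ndarray]:
    """Constructed 8-state propensity table for the local-structural-entropy
    feature.  The helix (H/G/I) and sheet (E/B) weights come from the
    Chou-Fasman helix/sheet propensities; the remainder is spread over the
    coil-like states.  Rows are normalised to probability vectors."""
    sheet = {"A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
             "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
             "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
             "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70}
    out = {}
    for aa in AA_LIST:
        helix = PHYSICOCHEMICAL[aa][8]
        e = sheet[aa]
        coil = max(2.0 - 0.5 * (helix + e), 0.2)
        w = np.array([
            0.15 * e,        # B
            0.85 * e,        # E
            0.12 * helix,    # G
            0.85 * helix,    # H
            0.03 * helix,    # I
            0.35 * coil,     # S
            0.35 * coil,     # T
            0.30 * coil,     # C
        ], dtype=float)
        out[aa] = w / w.sum()
    return out


LSE_PROPENSITY: dict[str, np.ndarray] = _lse_table()


def synthetic_pair_potentials(scale: float = 0.2) -> dict[frozenset, float]:
    """Synthetic residue-pair contact-potential table (210 unordered pairs).

    Stand-in for a published knowledge-based contact potential: pair energy
    is modelled as ``-scale * h_i * h_j / 10`` with ``h`` the Kyte-Doolittle
    hydropathy, so hydrophobic-hydrophobic pairs are favourable (negative).
    Values are synthetic; the pair-potential feature accepts any 210-entry
    table should a published one be supplied.
    """
    table: dict[frozenset, float] = {}
    for i, a in enumerate(AA_LIST):
        for b in AA_LIST[i:]:
            ha = PHYSICOCHEMICAL[a][4]
            hb = PHYSICOCHEMICAL[b][4]
            table[frozenset((a, b))] = round(-scale * ha * hb / 10.0, 4)
    return table


def blosum62_row(aa: str) -> np.ndarray:
    """BLOSUM62 substitution scores for ``aa`` in PSI-BLAST column order.

    Used as the PSSM fallback when no precomputed profile is supplied.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    if aa not in mat.alphabet:
        aa = "X" if "X" in mat.alphabet else "A"
    return np.array([mat[aa, b] for b in PSSM_ORDER], dtype=float)
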
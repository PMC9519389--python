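"""Amino-acid alphabet, background frequencies and substitution profiles.

Background amino-acid frequencies are the BLOSUM62 marginal frequencies; they
are used (i) as the background residue distribution of the synthetic
generators, (ii) to fill feature blocks at positions without profile
information, and (iii) as the reference distribution q in relative-entropy
computations. Substitution-conditional probabilities P(b | a) are
reconstructed from the BLOSUM62 log-odds matrix via the implied target
frequencies q_ab = p_a * p_b * 2**(s_ab / 2) and used for profile-based
pseudocounts.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetically ordered. This ordering is the
#: feature ordering contract of the whole package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Residues additionally accepted in input sequences ('X' = unknown).
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

#: Hydrophobic residue class used by the 'b' symbol of consensus patterns.
HYDROPHOBIC = frozenset("AVLIMFWYC")

# BLOSUM62 marginal background frequencies (order = AMINO_ACIDS).
_BG_RAW = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

BACKGROUND = np.array([_BG_RAW[a] for a in AMINO_ACIDS], dtype=np.float64)
BACKGROUND /= BACKGROUND.sum()


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as int8 indices into AMINO_ACIDS; 'X' -> -1."""
    out = np.full(len(residues), -1, dtype=np.int8)
    for i, ch in enumerate(residues):
        idx = AA_INDEX.get(ch)
        if idx is not None:
            out[i] = idx
    return out


def _build_blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    s = np.zeros((20, 20), dtype=np.float64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = mat[a][b]
    return s


#: BLOSUM62 substitution scores in its native half-bit integer units.
BLOSUM62 = _build_blosum62()


def _build_conditional() -> np.ndarray:
    q = BACKGROUND[:, None] * BACKGROUND[None, :] * np.exp2(BLOSUM62 / 2.0)
    q /= q.sum(axis=1, keepdims=True)
    return q


#: COND[a, b] = P(observe b | aligned to a), from BLOSUM62 target frequencies.
COND = _build_conditional()
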
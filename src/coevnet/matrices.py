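"""Amino-acid alphabets, background frequencies and substitution matrices.

Every alignment column is encoded over the 20 standard amino acids plus a
gap state; ``X`` (unknown residue) carries no residue identity and is
treated as a gap in all frequency computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical residue order used for all encoded matrices.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: Integer code of the gap/unknown state in encoded alignments.
GAP_CODE = len(AMINO_ACIDS)  # 20
#: Number of states in an encoded column (20 residues + gap).
N_STATES = GAP_CODE + 1

N_AA = len(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}

# S. cerevisiae proteome amino-acid composition (fraction of residues),
# the standard published values; normalised exactly at load time.
_YEAST_FREQS = {
    "A": 0.0550, "C": 0.0132, "D": 0.0585, "E": 0.0656, "F": 0.0441,
    "G": 0.0498, "H": 0.0217, "I": 0.0655, "K": 0.0730, "L": 0.0957,
    "M": 0.0207, "N": 0.0613, "P": 0.0438, "Q": 0.0394, "R": 0.0445,
    "S": 0.0900, "T": 0.0592, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
}


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background residue frequencies q(x) used by relative entropy.

    ``freqs`` is indexed in :data:`AMINO_ACIDS` order, strictly positive
    and normalised to sum to 1.
    """

    freqs: np.ndarray
    source: str = "yeast"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (len(AMINO_ACIDS),):
            raise ValueError(f"expected {len(AMINO_ACIDS)} frequencies, got {f.shape}")
        if np.any(f <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "freqs", f)

    def __getitem__(self, aa: str) -> float:
        return float(self.freqs[AA_INDEX[aa]])

    @classmethod
    def yeast(cls) -> "BackgroundFrequencies":
        """Yeast-proteome composition, the default conservation reference."""
        raw = np.array([_YEAST_FREQS[aa] for aa in AMINO_ACIDS])
        return cls(raw / raw.sum(), source="yeast")

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        """Uniform 1/20 background, convenient for closed-form checks."""
        return cls(np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS)), source="uniform")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Residue-similarity matrix for correlation-based coupling scores.

    ``scores`` is a dense (N_STATES x N_STATES) array in :data:`AMINO_ACIDS`
    order with the gap state appended; any pair involving a gap scores 0.
    """

    scores: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected {N_STATES}x{N_STATES} matrix, got {s.shape}")
        if not np.allclose(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(s[GAP_CODE, :] != 0) or np.any(s[:, GAP_CODE] != 0):
            raise ValueError("gap row/column must be zero")
        object.__setattr__(self, "scores", s)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        ia = GAP_CODE if a in (GAP, UNKNOWN) else AA_INDEX[a]
        ib = GAP_CODE if b in (GAP, UNKNOWN) else AA_INDEX[b]
        return float(self.scores[ia, ib])

    @classmethod
    def mclachlan(cls) -> "SubstitutionMatrix":
        """McLachlan (1972) chemical-similarity matrix (via Biopython)."""
        m = substitution_matrices.load("MCLACHLAN")
        s = np.zeros((N_STATES, N_STATES))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                s[i, j] = m[a, b]
        return cls(s, name="mclachlan")

    @classmethod
    def identity(cls) -> "SubstitutionMatrix":
        """1 for identical residues, 0 otherwise; used in worked examples."""
        s = np.zeros((N_STATES, N_STATES))
        s[np.arange(GAP_CODE), np.arange(GAP_CODE)] = 1.0
        return cls(s, name="identity")
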
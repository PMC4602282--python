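"""Protein scoring schemes for local similarity search.

The default scheme is BLOSUM62 with affine gap costs in the NCBI
convention: a gap of length ``k`` costs ``gap_open + k * gap_extend``
(default ``11 + k``).  Residues outside the 20 canonical amino acids
(X, B, Z, U, O, J, ``*``) are collapsed to a neutral symbol ``X`` that
scores -1 against everything, since predicted proteomes routinely
contain them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

#: The 20 canonical amino acids, in the order used throughout the package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Background amino-acid frequencies of the BLOSUM62 data set.  Used for
#: decoy sequence generation and for the substitution exchange kernel.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_ALPHABET = AMINO_ACIDS + "X"

_NONCANONICAL = str.maketrans({c: "X" for c in "BZUOJ*"})


def sanitize(sequence: str) -> str:
    """Upper-case a protein sequence and collapse non-canonical residues to X.

    Raises ``ValueError`` on characters that are not amino-acid codes.
    """
    seq = sequence.upper().translate(_NONCANONICAL)
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise ValueError(f"non amino-acid characters in sequence: {sorted(bad)}")
    return seq


def _blosum62_with_neutral() -> substitution_matrices.Array:
    """BLOSUM62 over the 20 canonical residues plus a neutral X at -1."""
    b62 = substitution_matrices.load("BLOSUM62")
    mat = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            mat[a, b] = b62[a, b]
    for a in _ALPHABET:
        mat[a, "X"] = -1.0
        mat["X", a] = -1.0
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` and ``gap_extend`` are positive costs; a gap of length k
    costs ``gap_open + k * gap_extend``.
    """

    matrix: substitution_matrices.Array = field(default_factory=_blosum62_with_neutral)
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        arr = np.asarray(self.matrix)
        if not np.allclose(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    def aligner(self) -> Align.PairwiseAligner:
        """A local-mode affine-gap aligner realizing this scheme."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # PairwiseAligner charges open_gap_score for the first gap residue
        # and extend_gap_score for each further one; fold the per-residue
        # extension of the first position into the opening score.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def score(self, a: str, b: str) -> float:
        return self.matrix[a, b]


@lru_cache(maxsize=1)
def default_scheme() -> ScoringScheme:
    """The package-wide default: BLOSUM62, gap open 11, gap extend 1."""
    return ScoringScheme()


@lru_cache(maxsize=1)
def exchange_distribution() -> np.ndarray:
    """Conditional replacement probabilities P(b | a) for substitutions.

    Derived from BLOSUM62: P(b|a) is proportional to pi_b * 2^(S(a,b)/2)
    over b != a, where pi is the background distribution and S the
    log-odds matrix in half-bits.  Rows are indexed by AMINO_ACIDS order.
    """
    scheme = default_scheme()
    n = len(AMINO_ACIDS)
    probs = np.zeros((n, n))
    pi = np.array([BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i == j:
                continue
            probs[i, j] = pi[j] * 2.0 ** (scheme.score(a, b) / 2.0)
        probs[i] /= probs[i].sum()
    return probs


def background_probabilities() -> np.ndarray:
    """Background amino-acid frequencies as a normalized vector."""
    pi = np.array([BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
    return pi / pi.sum()
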
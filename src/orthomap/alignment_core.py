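"""Deterministic pairwise scoring primitives.

Two scorers drive the ortholog cascade:

* Needleman–Wunsch global alignment with affine gap penalties, over either
  the published BLOSUM50 amino-acid matrix or an IUPAC-ambiguity-aware
  nucleotide matrix built from match/mismatch parameters.  A gap of length
  ``L`` costs ``gap_open + L * gap_extend``.
* Levenshtein edit distance between gene symbols (case-sensitive).

Scores are raw (not length-normalised) by default — candidates are ranked by
highest alignment score, and the normalisation switch exists only as an
explicit option on the cascade configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError

#: IUPAC nucleotide ambiguity sets.  'U' is mapped to 'T' before scoring.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric symbol-pair scores over an explicit alphabet."""

    alphabet: tuple[str, ...]
    _array: Align.substitution_matrices.Array
    nucleotide: bool = False

    def score(self, a: str, b: str) -> float:
        return float(self._array[a, b])

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.alphabet


@lru_cache(maxsize=1)
def blosum50() -> SubstitutionMatrix:
    """The published 24-symbol BLOSUM50 amino-acid substitution matrix."""
    arr = substitution_matrices.load("BLOSUM50")
    return SubstitutionMatrix(alphabet=tuple(arr.alphabet), _array=arr)


def iupac_nucleotide_matrix(
    match: float = 1.0, mismatch: float = -1.0
) -> SubstitutionMatrix:
    """IUPAC-ambiguity-aware nucleotide matrix from match/mismatch scores.

    For ambiguity sets ``S_a`` and ``S_b`` the score is
    ``p * match + (1 - p) * mismatch`` with ``p = |S_a ∩ S_b| / (|S_a|·|S_b|)``,
    so exact codes reduce to plain match/mismatch scoring.
    """
    if not match > mismatch:
        raise ConfigurationError(
            f"match ({match}) must exceed mismatch ({mismatch})"
        )
    alphabet = "".join(IUPAC_SETS)
    arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a, sa in IUPAC_SETS.items():
        for b, sb in IUPAC_SETS.items():
            p = len(sa & sb) / (len(sa) * len(sb))
            arr[a, b] = p * match + (1.0 - p) * mismatch
    return SubstitutionMatrix(alphabet=tuple(alphabet), _array=arr, nucleotide=True)


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    length_a: int
    length_b: int


def _prepare(seq: str, matrix: SubstitutionMatrix, which: str) -> str:
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    seq = seq.upper()
    if matrix.nucleotide:
        seq = seq.replace("U", "T")
    for pos, sym in enumerate(seq):
        if sym not in matrix:
            raise ValueError(
                f"symbol {sym!r} at position {pos} of sequence {which} is not in "
                f"the substitution-matrix alphabet"
            )
    return seq


def global_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gap_open: float = 10.0,
    gap_extend: float = 4.0,
) -> AlignmentResult:
    """Optimal Needleman–Wunsch global alignment score with affine gaps.

    Opening a gap costs ``gap_open + gap_extend``; each further gapped
    position costs ``gap_extend``.  The score is symmetric in its arguments
    for a symmetric matrix.
    """
    if gap_open < 0 or gap_extend < 0:
        raise ConfigurationError("gap penalties must be non-negative")
    sa = _prepare(a, matrix, "a")
    sb = _prepare(b, matrix, "b")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix._array
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    score = aligner.score(sa, sb)
    return AlignmentResult(score=float(score), length_a=len(sa), length_b=len(sb))


def levenshtein(a: str, b: str) -> int:
    """Case-sensitive Levenshtein edit distance (empty strings allowed)."""
    if not a or not b:
        return max(len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="distance")
    dist = res["editDistance"]
    if dist < 0:  # pragma: no cover - edlib returns -1 only with bounded k
        raise RuntimeError("edit distance computation failed")
    return int(dist)


def normalized_similarity(result: AlignmentResult) -> float:
    """Length-normalised alignment score (score per aligned-length unit)."""
    return result.score / max(result.length_a, result.length_b)
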
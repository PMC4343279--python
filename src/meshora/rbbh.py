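"""Reciprocal best hits between two protein sets.

Orthologs between a well-annotated and a poorly annotated organism are
approximated by reciprocal best hits: a pair (a, b) is reported when b
is a's unique best-scoring partner in the other set and vice versa.
Scoring is optimal Smith-Waterman local alignment under BLOSUM62 with
affine gaps (a gap of length L costs open + L*extend, the BLAST
convention; defaults open=11, extend=1), computed by Biopython's
PairwiseAligner. The heuristic search engine of BLAST is deliberately
not reproduced — the best-hit logic, not the search heuristics, is the
method.

The default ``min_score`` of 0 keeps every positive-scoring hit,
mirroring the extremely permissive E-value cutoff the original
large-scale runs used; :func:`evalue_proxy` offers a Karlin-Altschul
style significance proxy for callers who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from ._errors import ValidationError

#: The 20 standard amino acids plus the ambiguity letter X.
AA_ALPHABET: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence with its gene identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"sequence for {self.id!r} must be non-empty")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"invalid residue(s) {sorted(bad)} in sequence {self.id!r}; "
                f"allowed: 20 amino-acid letters plus X"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class AlignScoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class RbbhPair:
    """A reciprocal best hit between sets A and B, with both scores
    (equal under a symmetric substitution matrix)."""

    id_a: str
    id_b: str
    score_ab: float = 0.0
    score_ba: float = 0.0


@lru_cache(maxsize=8)
def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    # Biopython charges open_gap_score for the first gap position, so the
    # BLAST-style cost open + L*extend maps to open+extend for position 1.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


DEFAULT_SCORING = AlignScoring()


def align_score(
    a: ProteinSeq, b: ProteinSeq, scoring: AlignScoring = DEFAULT_SCORING
) -> float:
    """Optimal Smith-Waterman local alignment score of two proteins.

    Symmetric in its arguments for a symmetric substitution matrix.
    """
    return float(_aligner(scoring).score(a.sequence, b.sequence))


def evalue_proxy(
    score: float, len_a: int, len_b: int, lam: float = 0.267, K: float = 0.041
) -> float:
    """Karlin-Altschul style expected-hit-count proxy K*m*n*exp(-lam*S).

    Default parameters are the classic gapped BLOSUM62 (11,1) constants.
    A monotone proxy only: no edge-effect or database-size correction.
    """
    return K * len_a * len_b * math.exp(-lam * score)


def _score_matrix(
    A: Iterable[ProteinSeq], B: Iterable[ProteinSeq], scoring: AlignScoring
) -> tuple[list[ProteinSeq], list[ProteinSeq], list[list[float]]]:
    A, B = list(A), list(B)
    for seqs in (A, B):
        ids = [s.id for s in seqs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sequence ids within a set")
    aligner = _aligner(scoring)
    matrix = [[float(aligner.score(a.sequence, b.sequence)) for b in B] for a in A]
    return A, B, matrix


def _best_of(
    scores: Mapping[str, float], min_score: float
) -> str | None:
    """Best-scoring subject id; ties broken by lexicographically smallest
    id. Hits must score > 0 and >= min_score."""
    eligible = {
        sid: s for sid, s in scores.items() if s > 0 and s >= min_score
    }
    if not eligible:
        return None
    return min(eligible, key=lambda sid: (-eligible[sid], sid))


def best_hits(
    A: Iterable[ProteinSeq],
    B: Iterable[ProteinSeq],
    scoring: AlignScoring = DEFAULT_SCORING,
    min_score: float = 0.0,
) -> dict[str, str]:
    """Map each query in A to its best-scoring subject in B.

    Queries with no hit scoring > 0 and >= ``min_score`` are omitted;
    score ties resolve to the lexicographically smallest subject id.
    """
    A, B, matrix = _score_matrix(A, B, scoring)
    out: dict[str, str] = {}
    for i, a in enumerate(A):
        best = _best_of({b.id: matrix[i][j] for j, b in enumerate(B)}, min_score)
        if best is not None:
            out[a.id] = best
    return out


def reciprocal_best_hits(
    A: Iterable[ProteinSeq],
    B: Iterable[ProteinSeq],
    scoring: AlignScoring = DEFAULT_SCORING,
    min_score: float = 0.0,
) -> set[RbbhPair]:
    """Pairs (a, b) where b is a's best hit in B and a is b's best hit in A.

    Equivalent to intersecting ``best_hits(A, B)`` with the inverse of
    ``best_hits(B, A)``; the score matrix is computed once and reused for
    both directions. Swapping A and B yields the same pairs with
    orientation reversed.
    """
    A, B, matrix = _score_matrix(A, B, scoring)
    fwd: dict[str, str] = {}
    for i, a in enumerate(A):
        best = _best_of({b.id: matrix[i][j] for j, b in enumerate(B)}, min_score)
        if best is not None:
            fwd[a.id] = best
    rev: dict[str, str] = {}
    for j, b in enumerate(B):
        best = _best_of({a.id: matrix[i][j] for i, a in enumerate(A)}, min_score)
        if best is not None:
            rev[b.id] = best

    idx_a = {a.id: i for i, a in enumerate(A)}
    idx_b = {b.id: j for j, b in enumerate(B)}
    pairs = set()
    for a_id, b_id in fwd.items():
        if rev.get(b_id) == a_id:
            s = matrix[idx_a[a_id]][idx_b[b_id]]
            pairs.add(RbbhPair(id_a=a_id, id_b=b_id, score_ab=s, score_ba=s))
    return pairs


def plan_comparisons(n_minor: int, n_major: int) -> int:
    """Number of directed all-vs-all alignment runs for an RBBH sweep:
    2 * n_minor * n_major (each organism pair is searched both ways)."""
    if n_minor <= 0 or n_major <= 0:
        raise ValidationError("organism counts must be positive")
    return 2 * n_minor * n_major
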
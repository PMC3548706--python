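"""Local pairwise protein alignment with BLAST-style scoring and statistics.

Ortholog detection in this package rests on optimal Smith–Waterman local
alignment under BLOSUM62 with affine gap penalties, scored and filtered the
way a BLASTP search would be: a Karlin–Altschul expectation value computed
from the raw score and the search-space size, plus query/subject coverage
fractions.  The gap convention is BLAST's: a gap of length ``k`` costs
``gap_open + k * gap_extend`` (default ``11 + k``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "align_local",
    "evalue",
    "bit_score",
    "sanitize_sequence",
]

# 20 standard residues; anything else is mapped to X before alignment.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(STANDARD_AA) | {"X"}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and Gumbel parameters.

    ``gap_open``/``gap_extend`` follow the BLAST convention (gap of length k
    costs ``gap_open + k*gap_extend``).  ``lam`` and ``K`` are the gapped
    Karlin–Altschul parameters used for E-values and bit scores; the defaults
    are the published values for BLOSUM62 with gap penalties 11/1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters lambda and K must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        return _make_aligner(
            self.matrix_name, float(self.gap_open), float(self.gap_extend)
        )


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each further one; BLAST charges open + k*extend
    # for a gap of length k.  Shifting the open score reconciles the two.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment of a query/subject pair with BLAST-like stats.

    Spans are half-open ``[start, end)`` intervals on the unaligned
    sequences; coverages are span length over full sequence length.
    """

    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_coverage: float
    subject_coverage: float
    identity: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.query_coverage <= 1.0
        assert 0.0 <= self.subject_coverage <= 1.0
        assert self.evalue >= 0.0


def sanitize_sequence(seq: str) -> str:
    """Uppercase and map any non-standard residue letter to ``X``."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "X" for c in seq)


def evalue(
    raw_score: float,
    query_len: int,
    subject_db_len: int,
    lam: float = 0.267,
    K: float = 0.041,
) -> float:
    """Karlin–Altschul expectation value ``E = K * m * n * exp(-lambda * S)``.

    ``m`` is the query length and ``n`` the total residue count of the
    searched database (here: one proteome).  E decreases strictly with the
    raw score and scales linearly with both lengths.
    """
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    if query_len < 1 or subject_db_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * query_len * subject_db_len * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float = 0.267, K: float = 0.041) -> float:
    """Normalised score in bits, ``S' = (lambda*S - ln K) / ln 2``."""
    if lam <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return (lam * raw_score - math.log(K)) / math.log(2)


def align_local(
    query: str,
    subject: str,
    scoring: ScoringScheme | None = None,
    db_len: int | None = None,
) -> AlignmentResult | None:
    """Optimal Smith–Waterman local alignment of two protein sequences.

    Parameters
    ----------
    query, subject
        Amino-acid strings (20 standard residues; others become ``X``).
    scoring
        Substitution matrix, gap penalties and Gumbel parameters.
    db_len
        Effective database length ``n`` for the E-value.  Defaults to the
        subject length (single-sequence search space).

    Returns
    -------
    AlignmentResult, or None when no local alignment scores above zero
    (there is "no hit").

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or ScoringScheme()
    q = sanitize_sequence(query)
    s = sanitize_sequence(subject)
    aligner = scoring.aligner()
    score = aligner.score(q, s)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(q, s)))
    qblocks, sblocks = aln.aligned
    q_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    s_span = (int(sblocks[0][0]), int(sblocks[-1][1]))
    n_id = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        for i in range(qb - qa):
            if q[qa + i] == s[sa + i]:
                n_id += 1
    aligned_cols = sum(int(qb - qa) for qa, qb in qblocks)
    n = db_len if db_len is not None else len(s)
    return AlignmentResult(
        raw_score=float(score),
        bit_score=bit_score(score, scoring.lam, scoring.K),
        evalue=evalue(score, len(q), n, scoring.lam, scoring.K),
        query_span=q_span,
        subject_span=s_span,
        query_coverage=(q_span[1] - q_span[0]) / len(q),
        subject_coverage=(s_span[1] - s_span[0]) / len(s),
        identity=n_id / aligned_cols if aligned_cols else 0.0,
    )
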
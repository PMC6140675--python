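"""Local protein alignment with BLAST-style bitscore and E-value statistics.

This module is the computational core of the homology screen: an optimal
Smith-Waterman local aligner under affine gap penalties (a gap of length L
costs ``gap_open + L * gap_extend``), with raw scores converted to bits via
the Karlin-Altschul parameters (lambda, K) and expectation values computed
as E = m * n * 2**(-S'), where m is the query length and n the total number
of residues in the searched database.

It deliberately omits BLAST's heuristics (word seeding, two-hit extension,
edge-effect length corrections, composition-based statistics): every
alignment reported here is the exact dynamic-programming optimum, and
E-values use the raw search-space product m*n. Bitscores therefore track
blastp closely while E-values are consistent but not bit-identical to NCBI
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

#: Residue alphabet used internally. ``X`` is the catch-all unknown; any
#: non-standard input residue (B, Z, J, U, O, *) is mapped onto it and it
#: scores the matrix minimum against everything, so unknowns never help.
ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_X = _AA_INDEX["X"]

LN2 = math.log(2.0)


def encode_peptide(seq: str) -> np.ndarray:
    """Map a peptide string onto integer indices over :data:`ALPHABET`."""
    return np.array(
        [_AA_INDEX.get(aa, _X) for aa in seq.upper()], dtype=np.int64
    )


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Build the 21x21 integer score matrix for :data:`ALPHABET`.

    The 20 standard residues take their scores from the named substitution
    matrix; the X row/column is set to the minimum of the standard 20x20
    block so unknown residues are maximally penalised.
    """
    src = substitution_matrices.load(name)
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int64)
    standard = ALPHABET[:-1]
    lowest = min(int(src[a, b]) for a in standard for b in standard)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = lowest
            else:
                mat[i, j] = int(src[a, b])
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul stats.

    Defaults are the blastp gapped defaults: BLOSUM62 with gap open 11 and
    extend 1, for which lambda = 0.267 nats per score unit and K = 0.041.
    """

    matrix: np.ndarray = field(default_factory=load_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")


@dataclass
class AlignmentHit:
    """One local alignment, carrying the columns the study's table reports."""

    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    evalue: float | None
    pct_identity: float
    match_length: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str


@njit(cache=False)
def _gotoh_fill(q, s, mat, gap_open, gap_extend):  # pragma: no cover - jit
    """Fill Gotoh matrices; returns (H, E, F, best, best_i, best_j).

    H holds the best local score ending at (i, j); E ends in a gap in the
    query (moving left), F in a gap in the subject (moving up). Opening a
    gap costs gap_open + gap_extend so that a length-L gap totals
    gap_open + L * gap_extend. The first maximal cell in row-major order is
    recorded, making the traceback start deterministic.
    """
    n = q.shape[0]
    m = s.shape[0]
    NEG = np.int64(-(10**12))
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = np.int64(0)
    bi = np.int64(0)
    bj = np.int64(0)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open - gap_extend
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open - gap_extend
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(q, s, mat, gap_open, gap_extend, H, E, F, i, j):
    """Recover one optimal path from (i, j), preferring diagonal > up > left."""
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]:
                aq.append(ALPHABET[q[i - 1]])
                asub.append(ALPHABET[s[j - 1]])
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject, consume query (up)
            aq.append(ALPHABET[q[i - 1]])
            asub.append("-")
            closed = F[i, j] == H[i - 1, j] - gap_open - gap_extend
            i -= 1
            if closed:
                state = "H"
        else:  # state == "E": gap in query, consume subject (left)
            aq.append("-")
            asub.append(ALPHABET[s[j - 1]])
            closed = E[i, j] == H[i, j - 1] - gap_open - gap_extend
            j -= 1
            if closed:
                state = "H"
    return "".join(reversed(aq)), "".join(reversed(asub)), i, j


def smith_waterman(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal affine-gap local alignment of two peptides.

    Raises ``ValueError`` on an empty sequence. If every attainable score is
    negative the result is the empty alignment with raw score 0.
    """
    if not query or not subject:
        raise ValueError("peptides must be non-empty")
    scheme = scheme or default_scheme()
    q = encode_peptide(query)
    s = encode_peptide(subject)
    H, E, F, best, bi, bj = _gotoh_fill(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            raw_score=0,
            bitscore=bitscore(0, scheme),
            evalue=None,
            pct_identity=0.0,
            match_length=0,
            query_span=(0, 0),
            subject_span=(0, 0),
            aligned_query="",
            aligned_subject="",
        )
    aq, asub, qi0, sj0 = _traceback(
        q, s, scheme.matrix, scheme.gap_open, scheme.gap_extend,
        H, E, F, int(bi), int(bj),
    )
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(best),
        bitscore=bitscore(int(best), scheme),
        evalue=None,
        pct_identity=percent_identity(aq, asub),
        match_length=len(aq),
        query_span=(qi0, int(bi)),
        subject_span=(sj0, int(bj)),
        aligned_query=aq,
        aligned_subject=asub,
    )


def bitscore(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalised score in bits: S' = (lambda * S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    return (scheme.lam * raw_score - math.log(scheme.K)) / LN2


def evalue(bits: float, query_len: int, db_residues: int) -> float:
    """Expected chance hits of >= this bitscore: E = m * n * 2**(-S')."""
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("search-space lengths must be positive")
    return float(query_len) * float(db_residues) * 2.0 ** (-bits)


def percent_identity(aligned_query: str, aligned_subject: str) -> float:
    """100 x identical columns / all alignment columns (gaps included)."""
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned strings must have equal length")
    if not aligned_query:
        return 0.0
    ident = sum(
        1
        for a, b in zip(aligned_query, aligned_subject)
        if a == b and a != "-"
    )
    return 100.0 * ident / len(aligned_query)


_DEFAULT_SCHEME: ScoringScheme | None = None


def default_scheme() -> ScoringScheme:
    """The shared blastp-default scheme (matrix built once per process)."""
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = ScoringScheme()
    return _DEFAULT_SCHEME
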
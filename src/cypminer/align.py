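"""Pairwise protein alignment and percent identity.

Family/subfamily assignment here rests on optimal global alignment identity
with gap columns counted in the denominator: identity = 100 * identical
columns / alignment columns. The aligner is an affine-gap Needleman-Wunsch
(Gotoh) with a fixed traceback preference (diagonal, then up, then left) so
that results are bit-reproducible across runs and platforms. An optional
local (Smith-Waterman) identity mode is provided for sensitivity analysis.

Gap convention: a gap of length k costs gap_open + (k - 1) * gap_extend,
i.e. the first gap residue pays the opening penalty (EMBOSS convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices
from numba import njit

__all__ = ["ScoringScheme", "AlignmentResult", "global_align", "local_align",
           "percent_identity", "identity_between"]

_NEG = -1e30

# traceback op codes
_DIAG, _UP, _LEFT = 0, 1, 2


@lru_cache(maxsize=8)
def _submatrix_26(matrix_name: str) -> np.ndarray:
    """26x26 substitution score lookup over A-Z.

    Letters absent from the named matrix (e.g. J, O, U in BLOSUM62) score as
    the matrix's 'X' (any residue) entries.
    """
    mat = substitution_matrices.load(matrix_name)
    alpha = mat.alphabet
    out = np.zeros((26, 26), dtype=np.float64)
    letters = [chr(ord("A") + i) for i in range(26)]
    for i, a in enumerate(letters):
        ra = a if a in alpha else "X"
        for j, b in enumerate(letters):
            rb = b if b in alpha else "X"
            out[i, j] = mat[ra, rb]
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (penalties are positive)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        sub = _submatrix_26(self.matrix_name)
        if not np.array_equal(sub, sub.T):
            raise ValueError(f"substitution matrix {self.matrix_name!r} is not symmetric")

    @property
    def submatrix(self) -> np.ndarray:
        return _submatrix_26(self.matrix_name)


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment: gapped strings plus column/identity counts."""

    aligned_query: str
    aligned_ref: str
    n_columns: int
    n_identical: int
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings differ in length")
        if self.n_identical > self.n_columns:
            raise ValueError("n_identical exceeds n_columns")


@njit(cache=True)
def _gotoh_global(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)  # gap in ref (consumes query, "up")
    Y = np.full((m + 1, n + 1), _NEG)  # gap in query (consumes ref, "left")
    pM = np.zeros((m + 1, n + 1), np.int8)
    pX = np.zeros((m + 1, n + 1), np.int8)
    pY = np.zeros((m + 1, n + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, n + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            # diagonal state; ties prefer predecessor M > X > Y
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            # up state (gap in ref)
            best = M[i - 1, j] - gap_open
            p = 0
            v = X[i - 1, j] - gap_extend
            if v > best:
                best = v
                p = 1
            v = Y[i - 1, j] - gap_open
            if v > best:
                best = v
                p = 2
            X[i, j] = best
            pX[i, j] = p
            # left state (gap in query)
            best = M[i, j - 1] - gap_open
            p = 0
            v = X[i, j - 1] - gap_open
            if v > best:
                best = v
                p = 1
            v = Y[i, j - 1] - gap_extend
            if v > best:
                best = v
                p = 2
            Y[i, j] = best
            pY[i, j] = p
    state = 0
    score = M[m, n]
    if X[m, n] > score:
        score = X[m, n]
        state = 1
    if Y[m, n] > score:
        score = Y[m, n]
        state = 2
    ops = np.empty(m + n, np.int8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = pY[i, j]
            j -= 1
        k += 1
    return ops[:k][::-1].copy(), score


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - ord("A")
    if arr.size and (arr.min() < 0 or arr.max() > 25):
        raise ValueError("sequence contains characters outside A-Z")
    return arr


def _result_from_ops(a: str, b: str, ops: np.ndarray, score: float) -> AlignmentResult:
    qa: list[str] = []
    qb: list[str] = []
    i = j = ident = 0
    for op in ops:
        if op == _DIAG:
            qa.append(a[i])
            qb.append(b[j])
            if a[i] == b[j]:
                ident += 1
            i += 1
            j += 1
        elif op == _UP:
            qa.append(a[i])
            qb.append("-")
            i += 1
        else:
            qa.append("-")
            qb.append(b[j])
            j += 1
    return AlignmentResult(
        aligned_query="".join(qa),
        aligned_ref="".join(qb),
        n_columns=len(ops),
        n_identical=ident,
        score=float(score),
    )


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch, affine gap) alignment of two sequences.

    Traceback ties are resolved deterministically: diagonal, then up (gap in
    the second sequence), then left.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ops, score = _gotoh_global(
        _encode(a), _encode(b), scheme.submatrix, float(scheme.gap_open), float(scheme.gap_extend)
    )
    return _result_from_ops(a, b, ops, score)


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment, for identity sensitivity checks.

    Delegates to Biopython's PairwiseAligner; identity is computed over the
    local alignment's columns with the same gaps-in-denominator convention.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -float(scheme.gap_open)
    aligner.extend_gap_score = -float(scheme.gap_extend)
    aln = aligner.align(a, b)[0]
    qa, qb = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
    return AlignmentResult(qa, qb, len(qa), ident, float(aln.score))


def percent_identity(aln: AlignmentResult) -> float:
    """Percent identity of an alignment: 100 * identical / total columns."""
    if aln.n_columns < 1:
        raise ValueError("alignment has zero columns")
    return 100.0 * aln.n_identical / aln.n_columns


def identity_between(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Percent identity of the optimal alignment of two sequences."""
    scheme = scheme or ScoringScheme()
    align = local_align if scheme.mode == "local" else global_align
    return percent_identity(align(a, b, scheme))
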
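"""Pairwise global/local alignment and homolog collection.

Affine-gap Needleman-Wunsch and Smith-Waterman with deterministic
traceback, percent identity, Karlin-Altschul E-values and E-value +
coverage filtered homolog search.  A gap of length k costs
open + (k-1) * extend (the opening penalty includes the first gap
position).  Defaults are BLOSUM62 with gap open 10 / extend 0.5 and the
standard gapped constants lambda = 0.267, K = 0.041 for that matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

from .io import AA20, SequenceRecord

ALPHABET = AA20 + "X"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}
NEG_INF = -1e30


def encode(residues: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in residues], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"cannot align residue {exc.args[0]!r}") from None


def _blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = blosum[a][b]
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and E-value constants."""

    matrix: np.ndarray = field(default_factory=_blosum62)
    gap_open: float = 10.0
    gap_extend: float = 0.5
    lam: float = 0.267  # nats per score unit
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("substitution matrix must cover the 20 residues plus X")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap extend must not exceed gap open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_INDEX[a], _INDEX[b]])

    @classmethod
    def simple(cls, match: float, mismatch: float, gap_open: float, gap_extend: float,
               **kwargs) -> "ScoringScheme":
        mat = np.full((len(ALPHABET), len(ALPHABET)), float(mismatch))
        np.fill_diagonal(mat, float(match))
        return cls(matrix=mat, gap_open=gap_open, gap_extend=gap_extend, **kwargs)


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"
    span_a: tuple[int, int]  # 0-based half-open on input a
    span_b: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")

    def __len__(self) -> int:
        return len(self.aligned_a)


@njit
def _fill(sa, sb, sub, gap_open, gap_extend, local):  # pragma: no cover - jitted
    n, m = len(sa), len(sb)
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a, vertical)
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b, horizontal)
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
        for j in range(1, m + 1):
            Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    else:
        for i in range(n + 1):
            M[i, 0] = 0.0
        for j in range(m + 1):
            M[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[sa[i - 1], sb[j - 1]]
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + s
            if local and M[i, j] < 0.0:
                M[i, j] = 0.0
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)
    return M, Ix, Iy


def _traceback(a, b, M, Ix, Iy, gap_open, gap_extend, sub, sa, sb, i, j, state, local):
    """Deterministic traceback: prefer diagonal (M), then up (Ix), then left (Iy)."""
    tol = 1e-9
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if local and state == 0 and M[i, j] <= tol:
            break
        if state == 0:  # M
            if i == 0 or j == 0:
                # global boundary: remaining prefix is a gap run
                state = 1 if i > 0 else 2
                continue
            s = sub[sa[i - 1], sb[j - 1]]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if local and abs(prev) <= tol and M[i, j] <= tol:
                state = 0
            elif abs(prev - M[i, j]) <= tol:
                state = 0
            elif abs(prev - Ix[i, j]) <= tol:
                state = 1
            elif abs(prev - Iy[i, j]) <= tol:
                state = 2
            else:  # pragma: no cover - numerical safety
                raise RuntimeError("traceback failed in M state")
        elif state == 1:  # Ix: gap in b
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(val - (M[i, j] - gap_open)) <= tol:
                state = 0
            elif abs(val - (Ix[i, j] - gap_extend)) <= tol:
                state = 1
            elif abs(val - (Iy[i, j] - gap_open)) <= tol:
                state = 2
            elif i == 0:
                state = 2
            else:  # pragma: no cover
                raise RuntimeError("traceback failed in Ix state")
        else:  # Iy: gap in a
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(val - (M[i, j] - gap_open)) <= tol:
                state = 0
            elif abs(val - (Iy[i, j] - gap_extend)) <= tol:
                state = 2
            elif abs(val - (Ix[i, j] - gap_open)) <= tol:
                state = 1
            elif j == 0:
                state = 1
            else:  # pragma: no cover
                raise RuntimeError("traceback failed in Iy state")
    out_a.reverse()
    out_b.reverse()
    return "".join(out_a), "".join(out_b), i, j


def _check_inputs(a: SequenceRecord, b: SequenceRecord) -> tuple[str, str]:
    sa, sb = a.ungapped(), b.ungapped()
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    return sa, sb


def global_align(a: SequenceRecord, b: SequenceRecord,
                 s: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment with affine gaps."""
    s = s or ScoringScheme()
    ra, rb = _check_inputs(a, b)
    sa, sb = encode(ra), encode(rb)
    M, Ix, Iy = _fill(sa, sb, s.matrix, s.gap_open, s.gap_extend, False)
    n, m = len(ra), len(rb)
    finals = [M[n, m], Ix[n, m], Iy[n, m]]
    score = max(finals)
    state = int(np.argmax([1 if abs(f - score) <= 1e-9 else 0 for f in finals]))
    # prefer M, then Ix, then Iy on ties
    for k, f in enumerate(finals):
        if abs(f - score) <= 1e-9:
            state = k
            break
    row_a, row_b, _, _ = _traceback(ra, rb, M, Ix, Iy, s.gap_open, s.gap_extend,
                                    s.matrix, sa, sb, n, m, state, False)
    return PairwiseAlignment(row_a, row_b, float(score), "global", (0, n), (0, m))


def local_align(a: SequenceRecord, b: SequenceRecord,
                s: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal local (Smith-Waterman) alignment; empty when nothing scores > 0."""
    s = s or ScoringScheme()
    ra, rb = _check_inputs(a, b)
    sa, sb = encode(ra), encode(rb)
    M, Ix, Iy = _fill(sa, sb, s.matrix, s.gap_open, s.gap_extend, True)
    score = float(M.max())
    if score <= 0.0:
        return PairwiseAlignment("", "", 0.0, "local", (0, 0), (0, 0))
    # earliest (i, j) maximum for determinism
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    row_a, row_b, i0, j0 = _traceback(ra, rb, M, Ix, Iy, s.gap_open, s.gap_extend,
                                      s.matrix, sa, sb, int(i), int(j), 0, True)
    return PairwiseAlignment(row_a, row_b, score, "local", (i0, int(i)), (j0, int(j)))


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical columns / all alignment columns (gaps included), to 0.1%."""
    if len(aln) == 0:
        raise ValueError("cannot compute identity of an empty alignment")
    same = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-")
    return round(100.0 * same / len(aln), 1)


def evalue(score: float, m: int, n: int, s: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    s = s or ScoringScheme()
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return s.K * m * n * math.exp(-s.lam * score)


@dataclass(frozen=True)
class Hit:
    db_id: str
    best_query: str
    score: float
    evalue: float
    coverage: float
    identity: float


def collect_homologs(queries: list[SequenceRecord], database: list[SequenceRecord],
                     e_max: float = 1e-3, cov_min: float = 0.9,
                     s: ScoringScheme | None = None) -> list[Hit]:
    """Local-alignment homolog search with E-value and coverage filters.

    A database entry is kept iff some query aligns to it with
    E < ``e_max`` and the aligned query span covers at least ``cov_min``
    of the query length.  The reported hit is the best passing query by
    E-value (ties: higher score).
    """
    if not queries or not database:
        raise ValueError("queries and database must be non-empty")
    s = s or ScoringScheme()
    hits = []
    for entry in database:
        best = None
        for query in queries:
            aln = local_align(query, entry, s)
            if len(aln) == 0:
                continue
            e = evalue(aln.score, len(query.ungapped()), len(entry.ungapped()), s)
            cov = (aln.span_a[1] - aln.span_a[0]) / len(query.ungapped())
            if e < e_max and cov >= cov_min:
                cand = Hit(entry.id, query.id, aln.score, e, cov, percent_identity(aln))
                if best is None or (cand.evalue, -cand.score) < (best.evalue, -best.score):
                    best = cand
        if best is not None:
            hits.append(best)
    return hits
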
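"""Deterministic pairwise protein alignment with an explicit column map.

Global (Needleman-Wunsch), local (Smith-Waterman) and overlap ("semiglobal")
alignment with affine gap costs (a gap of length L costs
``gap_open + gap_extend * L``). Ties are broken by a fixed state preference
-- match/mismatch over gap-in-query over gap-in-reference -- so results are
bit-stable across platforms. The column map underlies all reference-anchored
feature extraction: it answers "which query residue sits in the column of
reference position p?".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

__all__ = ["AlignmentParams", "Alignment", "pairwise_align", "map_positions", "GAP"]

GAP = "-"
_NEG = float("-inf")

# state codes, in tie-break preference order:
# M (diagonal) > Y (gap in query, reference consumed) > X (gap in reference)
_M, _Y, _X = 0, 1, 2


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters. Penalties are positive magnitudes."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "global"  # global | local | semiglobal

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.mode not in ("global", "local", "semiglobal"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


def _score_fn(matrix):
    alphabet = matrix.alphabet

    def score(a: str, b: str) -> float:
        # X (or any letter outside the matrix) scores the matrix minimum:
        # ambiguity never beats a real residue
        if a not in alphabet or b not in alphabet:
            return float(matrix.min())
        return float(matrix[a, b])

    return score


@dataclass(frozen=True)
class Alignment:
    """A gapped pairwise alignment of a query against a reference.

    ``query_start``/``ref_start`` give the 1-based position of the first
    aligned residue of each input (both 1 except in local mode, where only a
    substring of each sequence takes part).
    """

    aligned_query: str
    aligned_ref: str
    score: float
    query_start: int = 1
    ref_start: int = 1
    _ref_col: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings differ in length")
        # column index of each aligned reference position (1-based -> 0-based col)
        pos = self.ref_start - 1
        for col, ch in enumerate(self.aligned_ref):
            if ch != GAP:
                pos += 1
                self._ref_col[pos] = col

    @property
    def ref_positions(self) -> range:
        return range(self.ref_start, self.ref_start + len(self.aligned_ref.replace(GAP, "")))

    def ref_position_to_column(self, pos: int) -> int:
        """0-based alignment column holding the given 1-based reference position."""
        if pos not in self._ref_col:
            raise IndexError(f"reference position {pos} not covered by this alignment")
        return self._ref_col[pos]

    def column_to_query_position(self, col: int) -> int | None:
        """1-based query position in column ``col``, or None for a query gap."""
        if not 0 <= col < len(self.aligned_query):
            raise IndexError(f"column {col} out of range")
        if self.aligned_query[col] == GAP:
            return None
        return self.query_start - 1 + len(self.aligned_query[: col + 1].replace(GAP, ""))


def pairwise_align(query: str, ref: str, params: AlignmentParams | None = None) -> Alignment:
    """Optimal affine-gap pairwise alignment of ``query`` against ``ref``.

    Returns the single optimal alignment under the deterministic tie-break
    (diagonal preferred over gap-in-query over gap-in-reference, applied both
    to cell-state selection and traceback).
    """
    if params is None:
        params = AlignmentParams()
    if not query or not ref:
        raise ValueError("sequences must be non-empty")
    if params.mode == "local":
        return _align_local(query, ref, params)
    return _align_global(query, ref, params, free_ends=params.mode == "semiglobal")


def map_positions(aln: Alignment, ref_positions: list[int]) -> list[int | None]:
    """Query position (1-based) aligned to each reference position, or None."""
    out: list[int | None] = []
    for p in ref_positions:
        col = aln.ref_position_to_column(p)  # raises IndexError when out of range
        out.append(aln.column_to_query_position(col))
    return out


def _pick(m: float, y: float, x: float) -> tuple[float, int]:
    """Max of the three states with the fixed preference M > Y > X."""
    if m >= y and m >= x:
        return m, _M
    if y >= x:
        return y, _Y
    return x, _X


def _align_global(query: str, ref: str, params: AlignmentParams, free_ends: bool) -> Alignment:
    n, m = len(query), len(ref)
    sc = _score_fn(params.matrix)
    go, ge = params.gap_open, params.gap_extend
    init = 0.0 if free_ends else None

    # DP over (n+1) x (m+1); rows = query prefix, cols = ref prefix
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (query consumed)
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (ref consumed)
    # predecessor state for traceback, parallel to the three matrices
    Mp = [[0] * (m + 1) for _ in range(n + 1)]
    Xp = [[0] * (m + 1) for _ in range(n + 1)]
    Yp = [[0] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = init if init is not None else -(go + ge * i)
        Xp[i][0] = _X
    for j in range(1, m + 1):
        Y[0][j] = init if init is not None else -(go + ge * j)
        Yp[0][j] = _Y

    for i in range(1, n + 1):
        qi = query[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mu, Xu, Yu = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            best, state = _pick(Mu[j - 1], Yu[j - 1], Xu[j - 1])
            if best != _NEG:
                Mi[j] = best + sc(qi, ref[j - 1])
                Mp[i][j] = state
            best, state = _pick(Mu[j] - go - ge, Yu[j] - go - ge, Xu[j] - ge)
            Xi[j] = best
            Xp[i][j] = state
            best, state = _pick(Mi[j - 1] - go - ge, Yi[j - 1] - ge, Xi[j - 1] - go - ge)
            Yi[j] = best
            Yp[i][j] = state

    if free_ends:
        # best over the last row and last column; terminal gaps are free
        end_i, end_j, best, state = n, m, _NEG, _M
        cells = [(n, j) for j in range(m + 1)] + [(i, m) for i in range(n + 1)]
        for ci, cj in cells:
            v, s = _pick(M[ci][cj], Y[ci][cj], X[ci][cj])
            if v > best:
                best, state, end_i, end_j = v, s, ci, cj
    else:
        end_i, end_j = n, m
        best, state = _pick(M[n][m], Y[n][m], X[n][m])

    aq, ar = _traceback_global(query, ref, end_i, end_j, state, Mp, Xp, Yp)
    if free_ends:  # pad the unaligned tails as terminal gap columns
        aq = aq + query[end_i:] + GAP * (m - end_j)
        ar = ar + GAP * (n - end_i) + ref[end_j:]
    return Alignment(aligned_query=aq, aligned_ref=ar, score=best)


def _traceback_global(query, ref, i, j, state, Mp, Xp, Yp):
    aq: list[str] = []
    ar: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            prev = Mp[i][j]
            aq.append(query[i - 1])
            ar.append(ref[j - 1])
            i, j, state = i - 1, j - 1, prev
        elif state == _X:  # gap in reference
            prev = Xp[i][j]
            aq.append(query[i - 1])
            ar.append(GAP)
            i, state = i - 1, prev
        else:  # _Y: gap in query
            prev = Yp[i][j]
            aq.append(GAP)
            ar.append(ref[j - 1])
            j, state = j - 1, prev
    return "".join(reversed(aq)), "".join(reversed(ar))


def _align_local(query: str, ref: str, params: AlignmentParams) -> Alignment:
    n, m = len(query), len(ref)
    sc = _score_fn(params.matrix)
    go, ge = params.gap_open, params.gap_extend

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    # Mp = -1 marks a zero-floored cell: the empty alignment ending there
    Mp = [[-1] * (m + 1) for _ in range(n + 1)]
    Xp = [[0] * (m + 1) for _ in range(n + 1)]
    Yp = [[0] * (m + 1) for _ in range(n + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            v, state = _pick(M[i - 1][j - 1], Y[i - 1][j - 1], X[i - 1][j - 1])
            v += sc(qi, ref[j - 1])
            if v > 0:
                M[i][j], Mp[i][j] = v, state
            v, state = _pick(M[i - 1][j] - go - ge, Y[i - 1][j] - go - ge, X[i - 1][j] - ge)
            X[i][j], Xp[i][j] = v, state
            v, state = _pick(M[i][j - 1] - go - ge, Y[i][j - 1] - ge, X[i][j - 1] - go - ge)
            Y[i][j], Yp[i][j] = v, state
            if M[i][j] > best:  # strictly greater: first maximum wins
                best, bi, bj = M[i][j], i, j

    if best == 0.0:  # no positive-scoring segment
        return Alignment(aligned_query="", aligned_ref="", score=0.0)

    aq: list[str] = []
    ar: list[str] = []
    i, j, state = bi, bj, _M
    while not (state == _M and Mp[i][j] == -1):
        if state == _M:
            prev = Mp[i][j]
            aq.append(query[i - 1])
            ar.append(ref[j - 1])
            i, j, state = i - 1, j - 1, prev
        elif state == _X:
            prev = Xp[i][j]
            aq.append(query[i - 1])
            ar.append(GAP)
            i, state = i - 1, prev
        else:
            prev = Yp[i][j]
            aq.append(GAP)
            ar.append(ref[j - 1])
            j, state = j - 1, prev
    aq_s, ar_s = "".join(reversed(aq)), "".join(reversed(ar))
    qlen, rlen = len(aq_s.replace(GAP, "")), len(ar_s.replace(GAP, ""))
    return Alignment(
        aligned_query=aq_s,
        aligned_ref=ar_s,
        score=best,
        query_start=bi - qlen + 1,
        ref_start=bj - rlen + 1,
    )
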
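"""Multiple alignment of encoded alleles over the motif-symbol alphabet.

Alignment operates on symbols, not nucleotides: the substitution score of
two symbols reflects the similarity of the motifs they encode,

    score(a, b) = round(s_max - (s_max - s_min) * ed(m_a, m_b) / max(|m_a|, |m_b|)),

with ``ed`` the unit-cost edit distance, so similar motifs pair cheaply and
gaps are pushed between dissimilar ones.  The private symbol scores
``s_min`` against everything but itself.  The MSA itself is progressive:
pairwise global alignments give normalized distances, average linkage
builds the guide tree, and profiles are merged with affine-gap Gotoh
alignment ("once a gap, always a gap").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .encode import GAP_SYMBOL, MotifMapping

__all__ = [
    "SymbolScoreMatrix",
    "EncodedAlignment",
    "build_score_matrix",
    "align",
    "pairwise_align",
    "alignment_sp_score",
]


class SymbolScoreMatrix:
    """Symmetric substitution scores over motif symbols, plus gap penalties.

    A gap run of length g costs ``gap_open + (g - 1) * gap_extend``.
    ``gap_open`` must fall below ``s_min - 1`` so that opening a gap is
    always worse than the worst mismatch between two retained symbols.
    """

    def __init__(self, symbols, scores, s_min, s_max, gap_open=-12, gap_extend=-2):
        self.symbols = list(symbols)
        self.s_min = int(s_min)
        self.s_max = int(s_max)
        if self.s_min >= self.s_max:
            raise ValueError("s_min must be < s_max")
        if gap_open >= self.s_min - 1:
            raise ValueError(
                "gap_open must be < s_min - 1 so gaps cost more than the "
                "worst mismatch"
            )
        if gap_extend > 0:
            raise ValueError("gap_extend must be <= 0")
        self.gap_open = int(gap_open)
        self.gap_extend = int(gap_extend)
        self._index = {s: i for i, s in enumerate(self.symbols)}
        mat = np.asarray(scores, dtype=np.int64)
        if mat.shape != (len(self.symbols), len(self.symbols)):
            raise ValueError("score matrix shape does not match symbols")
        if not np.array_equal(mat, mat.T):
            raise ValueError("score matrix must be symmetric")
        for i in range(len(self.symbols)):
            if mat[i, i] != mat[i].max():
                raise ValueError("diagonal must dominate each row")
        self.matrix = mat

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index[a], self._index[b]])

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index_of(self, symbol: str) -> int:
        return self._index[symbol]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_score_matrix(
    mapping: MotifMapping,
    s_min: int = 0,
    s_max: int = 10,
    gap_open: int = -12,
    gap_extend: int = -2,
) -> SymbolScoreMatrix:
    """Derive the symbol substitution matrix from motif similarity.

    Identical symbols score ``s_max``; distinct symbols score ``s_max``
    scaled down by the normalized edit distance of their motifs; the
    private symbol scores ``s_min`` against every other symbol.
    """
    if not mapping.entries and not mapping.has_private:
        raise ValueError("mapping is empty")
    symbols = list(mapping.symbols)
    motifs = {s: m for m, s, _ in mapping.entries}
    if mapping.has_private:
        symbols.append(mapping.private_symbol)
    n = len(symbols)
    mat = np.full((n, n), s_min, dtype=np.int64)
    for i, a in enumerate(symbols):
        for j, b in enumerate(symbols[: i + 1]):
            if a == b:
                sc = s_max
            elif a == mapping.private_symbol or b == mapping.private_symbol:
                sc = s_min
            else:
                ma, mb = motifs[a], motifs[b]
                ed = edlib.align(ma, mb, task="distance")["editDistance"]
                sc = _round_half_up(
                    s_max - (s_max - s_min) * ed / max(len(ma), len(mb))
                )
            mat[i, j] = mat[j, i] = sc
    return SymbolScoreMatrix(symbols, mat, s_min, s_max, gap_open, gap_extend)


@dataclass
class EncodedAlignment:
    """Gap-padded symbol matrix, one row per allele, all rows equal width."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        w = len(self.rows[0][1])
        for rid, r in self.rows:
            if len(r) != w:
                raise ValueError(f"row {rid!r} has width {len(r)}, expected {w}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, allele_id: str) -> str:
        for rid, r in self.rows:
            if rid == allele_id:
                return r
        raise KeyError(allele_id)

    def degapped(self, allele_id: str) -> str:
        return self.row(allele_id).replace(GAP_SYMBOL, "")


_NEG = -(10**9)


def _gotoh(sub: np.ndarray, gap_open: int, gap_extend: int):
    """Affine-gap global alignment over a precomputed wA x wB score matrix.

    Returns (score, path) where path is a list of (i, j) column-index pairs,
    either index being None at a gap.  Traceback prefers diagonal, then a
    gap in the second profile, then in the first (deterministic).
    """
    wa, wb = sub.shape
    M = np.full((wa + 1, wb + 1), _NEG, dtype=np.float64)
    X = np.full_like(M, _NEG)  # gap in B (consumes A columns)
    Y = np.full_like(M, _NEG)  # gap in A (consumes B columns)
    M[0, 0] = 0.0
    for i in range(1, wa + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, wb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, wa + 1):
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        best_prev = np.maximum(np.maximum(Mp, Xp), Yp)
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        X[i] = np.maximum(
            np.maximum(Mp, Yp) + gap_open, Xp + gap_extend
        )
        X[i, 0] = gap_open + (i - 1) * gap_extend
        # Y has an in-row dependency; solve the max-plus chain by running max
        base = np.maximum(M[i], X[i])[:-1] + gap_open - gap_extend
        jj = np.arange(wb)
        Y[i, 1:] = (
            np.maximum.accumulate(base - jj * gap_extend)
            + (jj + 1) * gap_extend
        )
    i, j = wa, wb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    score = float([M[i, j], X[i, j], Y[i, j]][state])
    path: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == 0:  # M: consume one column of each profile
            path.append((i - 1, j - 1))
            target = M[i, j] - sub[i - 1, j - 1]
            state = _pick(
                (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]), target
            )
            i, j = i - 1, j - 1
        elif state == 1:  # X: gap in B, consume an A column
            path.append((i - 1, None))
            if abs(X[i - 1, j] + gap_extend - X[i, j]) < _TOL:
                state = 1
            else:
                state = _pick(
                    (M[i - 1, j], _NEG, Y[i - 1, j]), X[i, j] - gap_open
                )
            i -= 1
        else:  # Y: gap in A, consume a B column
            path.append((None, j - 1))
            if abs(Y[i, j - 1] + gap_extend - Y[i, j]) < _TOL:
                state = 2
            else:
                state = _pick(
                    (M[i, j - 1], X[i, j - 1], _NEG), Y[i, j] - gap_open
                )
            j -= 1
    path.reverse()
    return score, path


_TOL = 1e-6


def _pick(prev, target) -> int:
    for k, v in enumerate(prev):
        if abs(v - target) < _TOL:
            return k
    raise AssertionError("broken alignment traceback")  # pragma: no cover


def _profile_submatrix(cols_a, cols_b, matrix: SymbolScoreMatrix) -> np.ndarray:
    """Mean sum-of-pairs score for every column pair of two profiles.

    Gap characters inside a profile column score ``gap_extend`` against a
    symbol and 0 against another gap.
    """
    n = len(matrix.symbols)
    gap_idx = n
    ext = np.zeros((n + 1, n + 1), dtype=np.float64)
    ext[:n, :n] = matrix.matrix
    ext[gap_idx, :n] = matrix.gap_extend
    ext[:n, gap_idx] = matrix.gap_extend
    ext[gap_idx, gap_idx] = 0.0

    def colidx(cols):
        return [
            np.array(
                [
                    gap_idx if c == GAP_SYMBOL else matrix.index_of(c)
                    for c in col
                ],
                dtype=np.intp,
            )
            for col in cols
        ]

    ia, ib = colidx(cols_a), colidx(cols_b)
    out = np.empty((len(ia), len(ib)), dtype=np.float64)
    for i, ca in enumerate(ia):
        for j, cb in enumerate(ib):
            out[i, j] = ext[np.ix_(ca, cb)].mean()
    return out


def _columns(profile_rows: list[str]) -> list[str]:
    return ["".join(r[k] for r in profile_rows) for k in range(len(profile_rows[0]))]


def _merge_profiles(pa, pb, matrix: SymbolScoreMatrix):
    """Align two gapped profiles column-wise and merge ("once a gap...")."""
    ids_a, rows_a = zip(*pa)
    ids_b, rows_b = zip(*pb)
    sub = _profile_submatrix(_columns(list(rows_a)), _columns(list(rows_b)), matrix)
    _, path = _gotoh(sub, matrix.gap_open, matrix.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in path:
        for k, r in enumerate(rows_a):
            out_a[k] += r[i] if i is not None else GAP_SYMBOL
        for k, r in enumerate(rows_b):
            out_b[k] += r[j] if j is not None else GAP_SYMBOL
    return list(zip(ids_a, out_a)) + list(zip(ids_b, out_b))


def pairwise_align(a: str, b: str, matrix: SymbolScoreMatrix):
    """Global affine-gap alignment of two ungapped symbol strings.

    Returns (score, gapped_a, gapped_b).
    """
    for s in (a, b):
        for c in s:
            if c not in matrix:
                raise ValueError(f"unknown symbol {c!r}")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ia = np.array([matrix.index_of(c) for c in a], dtype=np.intp)
    ib = np.array([matrix.index_of(c) for c in b], dtype=np.intp)
    sub = matrix.matrix[np.ix_(ia, ib)].astype(np.float64)
    score, path = _gotoh(sub, matrix.gap_open, matrix.gap_extend)
    ga = "".join(a[i] if i is not None else GAP_SYMBOL for i, _ in path)
    gb = "".join(b[j] if j is not None else GAP_SYMBOL for _, j in path)
    return score, ga, gb


def alignment_sp_score(rows: list[str], matrix: SymbolScoreMatrix) -> float:
    """Sum-of-pairs score of an alignment, affine gap runs scored
    ``gap_open + (g - 1) * gap_extend``; columns where both rows gap are
    free."""
    total = 0.0
    n = len(rows)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            in_gap = None  # which row is currently gapped
            for ca, cb in zip(a, b):
                if ca == GAP_SYMBOL and cb == GAP_SYMBOL:
                    continue
                if ca == GAP_SYMBOL or cb == GAP_SYMBOL:
                    which = 0 if ca == GAP_SYMBOL else 1
                    if in_gap == which:
                        total += matrix.gap_extend
                    else:
                        total += matrix.gap_open
                    in_gap = which
                else:
                    total += matrix.score(ca, cb)
                    in_gap = None
    return total


def _strip_allgap_columns(rows):
    ids, seqs = zip(*rows)
    keep = [
        k
        for k in range(len(seqs[0]))
        if any(s[k] != GAP_SYMBOL for s in seqs)
    ]
    return [
        (rid, "".join(s[k] for k in keep)) for rid, s in zip(ids, seqs)
    ]


def align(encoded, matrix: SymbolScoreMatrix) -> EncodedAlignment:
    """Progressive multiple alignment of encoded alleles.

    Pairwise global alignments give normalized distances (1 - identical
    aligned columns / alignment length); an average-linkage guide tree sets
    the merge order; profiles merge by affine-gap Gotoh alignment.  Rows of
    the result keep the input order.  Deterministic for a fixed input.
    """
    encoded = list(encoded)
    if not encoded:
        raise ValueError("at least one sequence is required")
    for rid, seq in encoded:
        if not seq:
            raise ValueError(f"sequence {rid!r} is empty")
        for c in seq:
            if c not in matrix:
                raise ValueError(
                    f"unknown symbol {c!r} in sequence {rid!r}"
                )
    n = len(encoded)
    if n == 1:
        return EncodedAlignment(list(encoded))
    if n == 2:
        (ida, sa), (idb, sb) = encoded
        _, ga, gb = pairwise_align(sa, sb, matrix)
        return EncodedAlignment(_strip_allgap_columns([(ida, ga), (idb, gb)]))

    dist = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            _, ga, gb = pairwise_align(encoded[i][1], encoded[j][1], matrix)
            ident = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP_SYMBOL)
            dist[i, j] = dist[j, i] = 1.0 - ident / len(ga)
    Z = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [encoded[i]] for i in range(n)
    }
    for k, (ca, cb, _, _) in enumerate(Z):
        pa = profiles.pop(int(ca))
        pb = profiles.pop(int(cb))
        profiles[n + k] = _merge_profiles(pa, pb, matrix)
    merged = profiles[2 * n - 2]
    by_id = dict(merged)
    ordered = [(rid, by_id[rid]) for rid, _ in encoded]
    return EncodedAlignment(_strip_allgap_columns(ordered))


def write_alignment_fasta(alignment: EncodedAlignment, path) -> None:
    """Write aligned symbol rows as FASTA (gap character '-')."""
    with open(path, "w") as fh:
        for rid, row in alignment.rows:
            fh.write(f">{rid}\n{row}\n")


def read_symbol_fasta(path) -> list[tuple[str, str]]:
    """Read symbol sequences (aligned or not) from a FASTA-like file."""
    rows: list[tuple[str, str]] = []
    rid, buf = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    rows.append((rid, "".join(buf)))
                rid, buf = line[1:].split()[0], []
            elif line:
                buf.append(line)
    if rid is not None:
        rows.append((rid, "".join(buf)))
    if not rows:
        raise ValueError(f"no records in {path}")
    return rows


def read_alignment_fasta(path) -> EncodedAlignment:
    """Read an aligned symbol FASTA written by :func:`write_alignment_fasta`."""
    return EncodedAlignment(read_symbol_fasta(path))
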
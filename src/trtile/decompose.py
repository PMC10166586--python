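"""Optimum-parse decomposition of tandem-repeat alleles into motifs.

A tandem-repeat (TR) allele ``x`` over the DNA alphabet is partitioned into
consecutive substrings ``x(1), x(2), ...`` such that the summed global
alignment score of each substring against its best-matching motif,

    D(x, M) = sum_i max_{m in M} d(x(i), m),

is maximal.  ``d`` is a Needleman-Wunsch global alignment score with
configurable match / mismatch / indel scores (defaults +5 / -4 / -4).  The
optimum parse is found by dynamic programming over states ``D[i, m, j]`` --
the best score of parsing the prefix ``x[1..i]`` with the current segment
aligned up to character ``j`` of motif ``m``.  Completed motifs chain freely:
position ``j = 0`` of every motif may be entered from the completed end state
of any motif, so the allele is tiled by motif-aligned segments.

Segments whose substring differs from every input motif are emitted as
*novel* motifs carrying the literal substring; novel motifs are not fed back
into the motif set (single-pass parsing, no iterative refinement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoringParams",
    "MotifSet",
    "Segment",
    "Decomposition",
    "segment_score",
    "decompose",
    "decompose_all",
]

_DNA = set("ACGT")
_VALID = set("ACGTN")

_NEG = -(10**9)  # -inf sentinel; safe from overflow in int64 arithmetic


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scores used by the decomposition DP.

    match must be positive, mismatch below match, indel negative; the
    defaults (+5, -4, -4) make a single perfect motif copy of length L score
    5*L.
    """

    match: int = 5
    mismatch: int = -4
    indel: int = -4

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be < match score")
        if self.indel >= 0:
            raise ValueError("indel score must be < 0")


def _clean_seq(seq: str, what: str = "sequence") -> str:
    """Upper-case and validate a DNA string; N is allowed but never matches."""
    if not isinstance(seq, str) or not seq:
        raise ValueError(f"{what} must be a non-empty string")
    up = seq.upper()
    bad = set(up) - _VALID
    if bad:
        raise ValueError(
            f"{what} contains invalid characters {sorted(bad)!r}; "
            "allowed: A, C, G, T, N"
        )
    return up


class MotifSet:
    """Ordered collection of motifs, each tagged as user input or novel.

    Motif strings are unique; user order is preserved (it is also the
    tie-break order in the decomposition DP).
    """

    def __init__(self, motifs, origins=None):
        self._motifs: list[str] = []
        self._origin: dict[str, str] = {}
        motifs = list(motifs)
        if origins is None:
            origins = ["input"] * len(motifs)
        for m, o in zip(motifs, origins):
            self.add(m, origin=o)

    def add(self, motif: str, origin: str = "input") -> None:
        if origin not in ("input", "novel"):
            raise ValueError(f"unknown motif origin {origin!r}")
        motif = _clean_seq(motif, "motif")
        if motif in self._origin:
            if origin == "input" and self._origin[motif] == "input":
                raise ValueError(f"duplicate motif {motif!r}")
            return  # re-discovered novel motif: keep first occurrence
        self._motifs.append(motif)
        self._origin[motif] = origin

    @property
    def motifs(self) -> list[str]:
        return list(self._motifs)

    @property
    def input_motifs(self) -> list[str]:
        return [m for m in self._motifs if self._origin[m] == "input"]

    @property
    def novel_motifs(self) -> list[str]:
        return [m for m in self._motifs if self._origin[m] == "novel"]

    def origin(self, motif: str) -> str:
        return self._origin[motif]

    def __contains__(self, motif: str) -> bool:
        return motif in self._origin

    def __len__(self) -> int:
        return len(self._motifs)

    def __iter__(self):
        return iter(self._motifs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotifSet({self._motifs!r})"


def _as_motifset(motifs) -> MotifSet:
    if isinstance(motifs, MotifSet):
        return motifs
    return MotifSet(motifs)


@dataclass(frozen=True)
class Segment:
    """One part of a decomposition: a substring aligned to a motif."""

    substring: str
    aligned_motif: str
    segment_score: int
    is_exact: bool

    @property
    def observed_motif(self) -> str:
        """The motif this segment contributes downstream (its substring)."""
        return self.substring

    @property
    def origin(self) -> str:
        return "input" if self.is_exact else "novel"


@dataclass
class Decomposition:
    allele_id: str
    segments: list[Segment] = field(default_factory=list)
    total_score: int = 0

    @property
    def sequence(self) -> str:
        return "".join(s.substring for s in self.segments)

    @property
    def motif_sequence(self) -> list[str]:
        return [s.observed_motif for s in self.segments]


def segment_score(x: str, m: str, params: ScoringParams | None = None) -> int:
    """Global (Needleman-Wunsch) alignment score of ``x`` against ``m``.

    Linear gap penalty (``params.indel`` per gapped base).  Symmetric in its
    arguments; equals ``params.match * len(x)`` when ``x == m``.
    """
    params = params or ScoringParams()
    x = _clean_seq(x, "sequence")
    m = _clean_seq(m, "motif")
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    ma = np.frombuffer(m.encode(), dtype=np.uint8)
    n_ = ord("N")
    prev = np.arange(len(ma) + 1, dtype=np.int64) * params.indel
    for i in range(1, len(xa) + 1):
        sub = np.where(
            (ma == xa[i - 1]) & (xa[i - 1] != n_), params.match, params.mismatch
        )
        cur = np.empty_like(prev)
        cur[0] = prev[0] + params.indel
        diag = prev[:-1] + sub
        up = prev[1:] + params.indel
        best = np.maximum(diag, up)
        # horizontal chain cur[j] = max(best[j], cur[j-1] + indel), solved as
        # a running max of best[j] - j*indel
        j = np.arange(len(ma) + 1, dtype=np.int64)
        cand = np.concatenate(([cur[0]], best)) - j * params.indel
        cur = np.maximum.accumulate(cand) + j * params.indel
        prev = cur
    return int(prev[-1])


class _DPState:
    """Per-motif DP matrix plus the shared boundary vector B."""

    __slots__ = ("motif", "marr", "mat", "subs")

    def __init__(self, motif: str, n: int, params: ScoringParams):
        self.motif = motif
        self.marr = np.frombuffer(motif.encode(), dtype=np.uint8)
        self.mat = np.full((n + 1, len(motif) + 1), _NEG, dtype=np.int64)
        # substitution score of each query character vs every motif position
        n_ = ord("N")
        self.subs = {}
        for c in "ACGTN":
            hit = (self.marr == ord(c)) & (c != "N")
            self.subs[c] = np.where(hit, params.match, params.mismatch).astype(
                np.int64
            )


def _run_dp(x: str, motif_list: list[str], params: ScoringParams):
    """Fill the chained DP; returns (states, B) with B[i] = best parse of x[:i]."""
    n = len(x)
    indel = params.indel
    states = [_DPState(m, n, params) for m in motif_list]
    B = np.full(n + 1, _NEG, dtype=np.int64)
    B[0] = 0
    for st in states:
        L = len(st.motif)
        j = np.arange(L + 1, dtype=np.int64)
        st.mat[0] = j * indel  # segment starting at 0 with leading deletions
    for i in range(1, n + 1):
        c = x[i - 1]
        for st in states:
            L = len(st.motif)
            prev = st.mat[i - 1]
            diag = prev[:-1] + st.subs[c]
            up = prev[1:] + indel
            best = np.maximum(diag, up)
            col0 = prev[0] + indel  # insertion before the motif starts
            jj = np.arange(L + 1, dtype=np.int64)
            cand = np.concatenate(([col0], best)) - jj * indel
            st.mat[i] = np.maximum.accumulate(cand) + jj * indel
        B[i] = max(int(st.mat[i, -1]) for st in states)
        # segments may start after any parsed prefix: open state gets B[i],
        # then leading deletions propagate rightwards
        for st in states:
            L = len(st.motif)
            row = st.mat[i]
            if B[i] > row[0]:
                row[0] = B[i]
                jj = np.arange(L + 1, dtype=np.int64)
                row[:] = np.maximum.accumulate(row - jj * indel) + jj * indel
    return states, B


def _trace_segment(st: _DPState, x: str, i: int, B, params: ScoringParams):
    """Walk one segment in motif ``st`` back from (i, |m|) to its start row.

    Returns (start_row, substring).  Tie preference: diagonal, then insertion
    (consumes query, yielding longer segments), then deletion; at column 0 an
    insertion is preferred over closing the segment, again favouring longer
    segments.
    """
    mat = st.mat
    motif = st.motif
    indel = params.indel
    j = len(motif)
    row = i
    while True:
        v = mat[row, j]
        if j > 0:
            c = x[row - 1] if row > 0 else ""
            sub = (
                params.match
                if (row > 0 and c == motif[j - 1] and c != "N")
                else params.mismatch
            )
            if row > 0 and mat[row - 1, j - 1] + sub == v:
                row, j = row - 1, j - 1
                continue
            if row > 0 and mat[row - 1, j] + indel == v:
                row -= 1
                continue
            if mat[row, j - 1] + indel == v:
                j -= 1
                continue
            raise AssertionError("broken traceback")  # pragma: no cover
        # j == 0: keep consuming query characters (preferred — yields the
        # longer segment) or close the segment at a parse boundary; a close
        # at row == i would make the segment empty and is never taken
        if row > 0 and mat[row - 1, 0] + indel == v:
            row -= 1
            continue
        if row < i and B[row] == v:
            return row, x[row:i]
        raise AssertionError("broken traceback")  # pragma: no cover


def _backtrack(x: str, states, B, params: ScoringParams) -> list[Segment]:
    """Recover the optimum parse from the filled DP, right to left."""
    segments: list[Segment] = []
    i = len(x)
    match = params.match
    while i > 0:
        chosen = None
        # tie-break 1: prefer an exact segment (substring == motif), checked
        # cheaply via the boundary scores; ties then fall to user motif order
        for st in states:
            L = len(st.motif)
            if (
                i - L >= 0
                and x[i - L : i] == st.motif
                and "N" not in st.motif
                and B[i - L] + match * L == B[i]
                and int(st.mat[i, -1]) == B[i]
            ):
                chosen = st
                seg = Segment(st.motif, st.motif, match * L, True)
                segments.append(seg)
                i -= L
                break
        if chosen is not None:
            continue
        for st in states:
            if int(st.mat[i, -1]) == B[i]:
                start, sub = _trace_segment(st, x, i, B, params)
                score = int(B[i] - B[start])
                segments.append(
                    Segment(sub, st.motif, score, sub == st.motif)
                )
                i = start
                break
        else:  # pragma: no cover
            raise AssertionError("no motif attains the boundary optimum")
    segments.reverse()
    return segments


def decompose(
    x: str,
    motifs,
    params: ScoringParams | None = None,
    allele_id: str = "allele",
) -> Decomposition:
    """Optimally parse allele ``x`` into motif-aligned segments.

    Parameters
    ----------
    x : str
        TR allele sequence over {A,C,G,T} (N allowed, mismatches everything;
        lower case is accepted and upper-cased).
    motifs : MotifSet or iterable of str
        Input motifs; their order is the DP tie-break order.
    params : ScoringParams, optional
        Alignment scores (default +5 match, -4 mismatch, -4 indel).
    allele_id : str
        Identifier stored on the returned Decomposition.

    Returns
    -------
    Decomposition
        Segments concatenating exactly to ``x``; ``total_score`` is the DP
        optimum ``max_m D[|x|, m, |m|]``.
    """
    params = params or ScoringParams()
    x = _clean_seq(x, "allele")
    mset = _as_motifset(motifs)
    motif_list = mset.input_motifs
    if not motif_list:
        raise ValueError("motif set must contain at least one input motif")
    states, B = _run_dp(x, motif_list, params)
    segments = _backtrack(x, states, B, params)
    dec = Decomposition(allele_id, segments, int(B[-1]))
    assert dec.sequence == x, "segments must concatenate to the input"
    return dec


def decompose_all(
    alleles,
    motifs,
    params: ScoringParams | None = None,
) -> tuple[list[Decomposition], MotifSet]:
    """Decompose a batch of ``(id, sequence)`` alleles.

    Input order is preserved; the returned MotifSet is the input set
    augmented with every novel motif discovered across all alleles (novel
    motifs are *not* used for parsing — parsing is single-pass).
    """
    alleles = list(alleles)
    seen: set[str] = set()
    for aid, _ in alleles:
        if aid in seen:
            raise ValueError(f"duplicate allele id {aid!r}")
        seen.add(aid)
    mset = _as_motifset(motifs)
    augmented = MotifSet(mset.input_motifs)
    out = []
    for aid, seq in alleles:
        dec = decompose(seq, mset, params, allele_id=aid)
        for seg in dec.segments:
            if not seg.is_exact:
                augmented.add(seg.substring, origin="novel")
        out.append(dec)
    return out, augmented


def write_decomposition_tsv(decompositions, path) -> None:
    """Write segments as TSV: allele_id, segment_index (0-based), substring,
    aligned_motif, origin, segment_score."""
    with open(path, "w") as fh:
        fh.write(
            "allele_id\tsegment_index\tsubstring\taligned_motif\t"
            "origin\tsegment_score\n"
        )
        for dec in decompositions:
            for k, seg in enumerate(dec.segments):
                fh.write(
                    f"{dec.allele_id}\t{k}\t{seg.substring}\t"
                    f"{seg.aligned_motif}\t{seg.origin}\t{seg.segment_score}\n"
                )
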
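"""Encoding of decomposed motifs as single-character symbols.

Each distinct motif observed across the decompositions is mapped to one
printable character so that encoded alleles can be aligned and drawn as
strings of symbols.  At most 90 motifs receive their own symbol; motifs
below a frequency threshold are collapsed into a shared *private* class
(symbol ``?``, drawn grey downstream).  An ``auto`` threshold picks the
smallest count cut-off that keeps the number of symbols within the cap,
i.e. it maximizes the number of distinct symbols.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "SYMBOL_ALPHABET",
    "GAP_SYMBOL",
    "PRIVATE_SYMBOL",
    "MAX_SYMBOLS",
    "MotifMapping",
    "build_mapping",
    "encode_allele",
    "write_mapping",
    "read_mapping",
]

GAP_SYMBOL = "-"
PRIVATE_SYMBOL = "?"
MAX_SYMBOLS = 90

# Fixed, ordered 90-character symbol alphabet: digits (starting at '1'),
# upper case, lower case, then punctuation; '-' (gap), '?' (private) and
# whitespace are excluded.  Truncated to exactly 90 characters.
_PUNCT = "".join(
    c for c in string.punctuation if c not in (GAP_SYMBOL, PRIVATE_SYMBOL)
)
SYMBOL_ALPHABET = (
    "1234567890" + string.ascii_uppercase + string.ascii_lowercase + _PUNCT
)[:MAX_SYMBOLS]
assert len(SYMBOL_ALPHABET) == MAX_SYMBOLS
assert len(set(SYMBOL_ALPHABET)) == MAX_SYMBOLS


@dataclass
class MotifMapping:
    """Bijection between observed motifs and symbols, plus a private class.

    ``entries`` lists (motif, symbol, count) for motifs with their own
    symbol, in descending count order (count ties broken by lexicographic
    motif order); ``private_motifs`` maps every collapsed motif to its
    count.  ``private_threshold`` is the resolved integer cut-off actually
    applied (motifs with count below it are private).
    """

    entries: list[tuple[str, str, int]] = field(default_factory=list)
    private_motifs: dict[str, int] = field(default_factory=dict)
    private_symbol: str = PRIVATE_SYMBOL
    private_threshold: int = 1

    def __post_init__(self) -> None:
        symbols = [s for _, s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate symbols in mapping")
        if len(symbols) > MAX_SYMBOLS:
            raise ValueError(
                f"{len(symbols)} symbols exceed the cap of {MAX_SYMBOLS}"
            )
        if GAP_SYMBOL in symbols or self.private_symbol in symbols:
            raise ValueError("gap / private characters may not be symbols")

    def symbol_for(self, motif: str) -> str:
        for m, s, _ in self.entries:
            if m == motif:
                return s
        if motif in self.private_motifs:
            return self.private_symbol
        raise KeyError(f"motif {motif!r} not covered by the mapping")

    def motif_for(self, symbol: str) -> str:
        """Motif of a non-private symbol (private symbols are many-to-one)."""
        for m, s, _ in self.entries:
            if s == symbol:
                return m
        raise KeyError(f"unknown symbol {symbol!r}")

    @property
    def symbols(self) -> list[str]:
        return [s for _, s, _ in self.entries]

    @property
    def counts(self) -> dict[str, int]:
        out = {m: c for m, _, c in self.entries}
        out.update(self.private_motifs)
        return out

    @property
    def has_private(self) -> bool:
        return bool(self.private_motifs)

    @property
    def total_segments(self) -> int:
        return sum(self.counts.values())


def _motif_counts(decompositions) -> Counter:
    counts: Counter = Counter()
    for dec in decompositions:
        for seg in dec.segments:
            counts[seg.observed_motif] += 1
    return counts


def _resolve_auto(counts: Counter) -> int:
    """Smallest t >= 1 such that #{motifs with count >= t} <= the cap."""
    t = 1
    while sum(1 for c in counts.values() if c >= t) > MAX_SYMBOLS:
        t += 1
    return t


def build_mapping(decompositions, threshold: int | str = 1) -> MotifMapping:
    """Build the motif -> symbol mapping from decomposed alleles.

    Motifs with count >= ``threshold`` get their own symbol, assigned in
    descending count order (ties: lexicographic motif order) from the fixed
    90-character alphabet; the rest collapse to the private symbol.  With
    ``threshold="auto"`` the smallest threshold keeping the symbol count
    within the 90-symbol cap is chosen, which maximizes the number of
    distinct symbols.

    Raises
    ------
    ValueError
        If an explicit threshold would require more than 90 symbols, with a
        hint to raise it or use ``"auto"``; or if no decompositions are
        given.
    """
    decompositions = list(decompositions)
    if not decompositions:
        raise ValueError("at least one decomposition is required")
    counts = _motif_counts(decompositions)
    if threshold == "auto":
        t = _resolve_auto(counts)
    else:
        t = int(threshold)
        if t < 1:
            raise ValueError("threshold must be >= 1")
    keepers = sorted(
        (m for m, c in counts.items() if c >= t),
        key=lambda m: (-counts[m], m),
    )
    if len(keepers) > MAX_SYMBOLS:
        raise ValueError(
            f"threshold {t} yields {len(keepers)} symbols but only "
            f"{MAX_SYMBOLS} are available; raise the threshold or use 'auto'"
        )
    entries = [
        (m, SYMBOL_ALPHABET[i], counts[m]) for i, m in enumerate(keepers)
    ]
    private = {m: c for m, c in counts.items() if c < t}
    return MotifMapping(entries, private, PRIVATE_SYMBOL, t)


def encode_allele(decomposition, mapping: MotifMapping) -> str:
    """Rewrite one decomposition as a string of motif symbols."""
    out = []
    for seg in decomposition.segments:
        try:
            out.append(mapping.symbol_for(seg.observed_motif))
        except KeyError:
            raise ValueError(
                f"motif {seg.observed_motif!r} of allele "
                f"{decomposition.allele_id!r} is absent from the mapping"
            ) from None
    return "".join(out)


def write_mapping(mapping: MotifMapping, path) -> None:
    """Write the mapping as TSV (symbol, motif, count); private motifs share
    the reserved private symbol, one row each."""
    with open(path, "w") as fh:
        fh.write(f"# private_threshold={mapping.private_threshold}\n")
        fh.write("symbol\tmotif\tcount\n")
        for m, s, c in mapping.entries:
            fh.write(f"{s}\t{m}\t{c}\n")
        for m in sorted(mapping.private_motifs):
            fh.write(f"{mapping.private_symbol}\t{m}\t{mapping.private_motifs[m]}\n")


def read_mapping(path) -> MotifMapping:
    """Read a mapping TSV written by :func:`write_mapping`."""
    entries: list[tuple[str, str, int]] = []
    private: dict[str, int] = {}
    threshold = 1
    seen_symbols: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "private_threshold=" in line:
                    threshold = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if fields == ["symbol", "motif", "count"]:
                continue
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sym, motif, count_s = fields
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: count {count_s!r} is not an integer"
                ) from None
            if sym == PRIVATE_SYMBOL:
                if motif in private:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate private motif {motif!r}"
                    )
                private[motif] = count
            else:
                if sym in seen_symbols:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate symbol {sym!r}"
                    )
                seen_symbols.add(sym)
                entries.append((motif, sym, count))
    return MotifMapping(entries, private, PRIVATE_SYMBOL, threshold)
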
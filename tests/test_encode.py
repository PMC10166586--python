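"""Motif-to-symbol encoding: alphabet, cap, private class, round-trip."""

import pytest

import trtile
from trtile.decompose import Decomposition, Segment
from trtile.encode import MAX_SYMBOLS, PRIVATE_SYMBOL, SYMBOL_ALPHABET


def dec_from_motifs(allele_id, motifs):
    """A synthetic decomposition of exact segments, one per motif."""
    segs = [Segment(m, m, 5 * len(m), True) for m in motifs]
    return Decomposition(allele_id, segs, sum(s.segment_score for s in segs))


def many_motifs(n, length=8):
    """n distinct same-length motifs (base-4 encodings of 0..n-1)."""
    out = []
    for i in range(n):
        digits = []
        v = i
        for _ in range(length):
            digits.append("ACGT"[v % 4])
            v //= 4
        out.append("".join(digits))
    assert len(set(out)) == n
    return out


class TestAlphabet:
    def test_alphabet_size_and_reserved_characters(self):
        assert len(SYMBOL_ALPHABET) == 90
        assert len(set(SYMBOL_ALPHABET)) == 90
        assert "-" not in SYMBOL_ALPHABET
        assert "?" not in SYMBOL_ALPHABET
        assert not any(c.isspace() for c in SYMBOL_ALPHABET)


class TestBuildMapping:
    def test_snippet_counts_and_first_symbol(self, snippet_mapping):
        assert snippet_mapping.entries == [
            ("ACCTTG", "1", 2),
            ("ACCTTTG", "2", 1),
        ]
        assert not snippet_mapping.has_private

    def test_single_motif(self):
        mp = trtile.build_mapping([dec_from_motifs("a", ["ACG"])], 1)
        assert mp.entries == [("ACG", "1", 1)]
        assert not mp.has_private

    def test_counts_sum_to_segments(self, snippet_decomposition):
        mp = trtile.build_mapping([snippet_decomposition], 1)
        assert mp.total_segments == len(snippet_decomposition.segments)

    def test_threshold_collapses_rare_motifs(self, snippet_decomposition):
        mp = trtile.build_mapping([snippet_decomposition], 2)
        assert [m for m, _, _ in mp.entries] == ["ACCTTG"]
        assert mp.private_motifs == {"ACCTTTG": 1}
        assert mp.symbol_for("ACCTTTG") == PRIVATE_SYMBOL

    def test_symbols_follow_descending_count(self):
        decs = [
            dec_from_motifs("a", ["AAAA"] * 1 + ["CCCC"] * 3 + ["GGGG"] * 2)
        ]
        mp = trtile.build_mapping(decs, 1)
        assert [m for m, _, _ in mp.entries] == ["CCCC", "GGGG", "AAAA"]
        assert [s for _, s, _ in mp.entries] == ["1", "2", "3"]

    def test_count_ties_break_lexicographically(self):
        decs = [dec_from_motifs("a", ["TTTT", "AAAA", "GGGG"])]
        mp = trtile.build_mapping(decs, 1)
        assert [m for m, _, _ in mp.entries] == ["AAAA", "GGGG", "TTTT"]

    def test_over_cap_explicit_threshold_errors(self):
        decs = [dec_from_motifs("a", many_motifs(95))]
        with pytest.raises(ValueError, match="auto"):
            trtile.build_mapping(decs, 1)

    def test_auto_never_errors_and_respects_cap(self):
        # 95 singleton motifs: t=1 keeps 95 (> cap), t=2 keeps 0, so auto
        # collapses everything into the private class
        decs = [dec_from_motifs("a", many_motifs(95))]
        mp = trtile.build_mapping(decs, "auto")
        assert len(mp.entries) == 0
        assert len(mp.private_motifs) == 95
        assert mp.private_threshold == 2

    def test_auto_keeps_frequent_motifs(self):
        motifs = many_motifs(95) + many_motifs(5) * 2  # 5 motifs reach count 3
        decs = [dec_from_motifs("a", motifs)]
        mp = trtile.build_mapping(decs, "auto")
        assert len(mp.entries) == 5
        assert all(c == 3 for _, _, c in mp.entries)

    def test_cap_holds_for_any_auto_input(self):
        decs = [dec_from_motifs("a", many_motifs(200))]
        mp = trtile.build_mapping(decs, "auto")
        assert len(mp.entries) <= MAX_SYMBOLS

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trtile.build_mapping([], 1)


class TestEncodeAllele:
    def test_snippet_encodes_112(self, snippet_decomposition, snippet_mapping):
        assert trtile.encode_allele(snippet_decomposition, snippet_mapping) == "112"

    def test_empty_decomposition_encodes_empty(self, snippet_mapping):
        assert trtile.encode_allele(Decomposition("x"), snippet_mapping) == ""

    def test_all_private_segments(self, snippet_decomposition):
        mp = trtile.build_mapping([snippet_decomposition], 99)
        enc = trtile.encode_allele(snippet_decomposition, mp)
        assert enc == PRIVATE_SYMBOL * 3

    def test_unknown_motif_errors_with_name(self, snippet_mapping):
        stray = dec_from_motifs("x", ["TTTTTTT"])
        with pytest.raises(ValueError, match="TTTTTTT"):
            trtile.encode_allele(stray, snippet_mapping)

    def test_decode_inverse_without_privates(
        self, snippet_decomposition, snippet_mapping
    ):
        enc = trtile.encode_allele(snippet_decomposition, snippet_mapping)
        decoded = [snippet_mapping.motif_for(s) for s in enc]
        assert decoded == snippet_decomposition.motif_sequence


class TestMappingRoundTrip:
    def test_round_trip(self, snippet_mapping, tmp_path):
        p = tmp_path / "map.tsv"
        trtile.write_mapping(snippet_mapping, p)
        assert trtile.read_mapping(p) == snippet_mapping

    def test_round_trip_with_privates(self, snippet_decomposition, tmp_path):
        mp = trtile.build_mapping([snippet_decomposition], 2)
        p = tmp_path / "map.tsv"
        trtile.write_mapping(mp, p)
        back = trtile.read_mapping(p)
        assert back == mp
        assert back.private_motifs == {"ACCTTTG": 1}

    def test_private_rows_flagged_with_reserved_symbol(
        self, snippet_decomposition, tmp_path
    ):
        mp = trtile.build_mapping([snippet_decomposition], 2)
        p = tmp_path / "map.tsv"
        trtile.write_mapping(mp, p)
        rows = [
            line.split("\t")
            for line in p.read_text().splitlines()
            if line and not line.startswith("#") and "symbol" not in line
        ]
        assert [r[0] for r in rows] == ["1", PRIVATE_SYMBOL]

    def test_duplicate_symbol_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("symbol\tmotif\tcount\n1\tACG\t2\n1\tTTT\t1\n")
        with pytest.raises(ValueError, match=":3"):
            trtile.read_mapping(p)

    def test_malformed_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("symbol\tmotif\tcount\n1\tACG\n")
        with pytest.raises(ValueError, match=":2"):
            trtile.read_mapping(p)
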
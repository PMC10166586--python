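"""Decomposition DP: scoring, optimum parse, and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trtile
from trtile.decompose import MotifSet, ScoringParams

from conftest import SNIPPET_ALLELE, SNIPPET_MOTIFS, random_instance

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestSegmentScore:
    @pytest.mark.parametrize(
        "x, m, expected",
        [
            ("ACCTTG", "ACCTTG", 30),  # identity: 6 matches x 5
            ("ACCTTTG", "ACCTTG", 26),  # one extra base: 30 - 4
            ("A", "C", -4),  # forced single mismatch
            ("AA", "C", -8),  # mismatch + indel, each -4
        ],
    )
    def test_known_scores(self, x, m, expected):
        assert trtile.segment_score(x, m) == expected

    @given(x=dna, m=dna)
    @settings(max_examples=60, derandomize=True)
    def test_symmetric(self, x, m):
        assert trtile.segment_score(x, m) == trtile.segment_score(m, x)

    @given(x=dna)
    @settings(max_examples=30, derandomize=True)
    def test_identity_scores_match_times_length(self, x):
        assert trtile.segment_score(x, x) == 5 * len(x)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trtile.segment_score("", "ACG")
        with pytest.raises(ValueError):
            trtile.segment_score("ACG", "")

    def test_n_mismatches_everything(self):
        assert trtile.segment_score("N", "A") == -4
        assert trtile.segment_score("N", "N") == -4


class TestScoringParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"match": 0},
            {"match": -1},
            {"mismatch": 5},
            {"mismatch": 6},
            {"indel": 0},
            {"indel": 1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringParams(**kwargs)


class TestDecompose:
    def test_worked_example_segments(self, snippet_decomposition):
        assert [s.substring for s in snippet_decomposition.segments] == [
            "ACCTTG",
            "ACCTTG",
            "ACCTTTG",
        ]

    def test_worked_example_score_and_novelty(self, snippet_decomposition):
        assert snippet_decomposition.total_score == 86  # 30 + 30 + 26
        assert [s.origin for s in snippet_decomposition.segments] == [
            "input",
            "input",
            "novel",
        ]
        assert snippet_decomposition.segments[2].aligned_motif == "ACCTTG"

    @pytest.mark.parametrize(
        "x, motifs, n_segments, score",
        [
            ("ACG", ["ACG"], 1, 15),
            ("ACGACGACG", ["ACG"], 3, 45),
        ],
    )
    def test_perfect_copies(self, x, motifs, n_segments, score):
        d = trtile.decompose(x, motifs)
        assert len(d.segments) == n_segments
        assert d.total_score == score
        assert all(s.is_exact for s in d.segments)

    def test_segment_scores_sum_to_total(self, snippet_decomposition):
        total = sum(s.segment_score for s in snippet_decomposition.segments)
        assert total == snippet_decomposition.total_score

    def test_lowercase_uppercased(self):
        d = trtile.decompose("acgacg", ["ACG"])
        assert d.sequence == "ACGACG"
        assert len(d.segments) == 2

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            trtile.decompose("ACGX", ["ACG"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            trtile.decompose("", ["ACG"])
        with pytest.raises(ValueError):
            trtile.decompose("ACG", [])

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(20260)
        for _ in range(60):
            x, motifs = random_instance(rng)
            dp = trtile.decompose(x, motifs).total_score
            assert dp == trtile.brute_force_decompose(x, motifs), (x, motifs)

    def test_partition_conservation_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            x, motifs = random_instance(rng, max_len=40, max_motif_len=8)
            d = trtile.decompose(x, motifs)
            assert d.sequence == x

    @pytest.mark.parametrize("motif_len, copies", [(1, 30), (7, 13), (20, 30)])
    def test_perfect_repeat_recovery(self, motif_len, copies):
        rng = np.random.default_rng(motif_len * 100 + copies)
        motif = "".join(rng.choice(list("ACGT"), motif_len))
        d = trtile.decompose(motif * copies, [motif])
        assert len(d.segments) == copies
        assert all(s.is_exact for s in d.segments)
        assert d.total_score == 5 * copies * motif_len

    def test_monotone_in_motif_set(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            x, motifs = random_instance(rng)
            extra = "".join(rng.choice(list("ACGT"), 4))
            base = trtile.decompose(x, motifs).total_score
            superset = motifs + [extra] if extra not in motifs else motifs
            assert trtile.decompose(x, superset).total_score >= base

    @pytest.mark.parametrize("match", [1, 5, 12])
    def test_all_match_score_linear_in_match(self, match):
        params = ScoringParams(match=match)
        d = trtile.decompose("ACGACGACG", ["ACG"], params)
        assert d.total_score == match * 9


class TestDecomposeAll:
    def test_batch_preserves_order(self):
        decs, _ = trtile.decompose_all(
            [("a", "ACGACG"), ("b", "ACGACG")], ["ACG"]
        )
        assert [d.allele_id for d in decs] == ["a", "b"]
        assert all(len(d.segments) == 2 for d in decs)

    def test_novel_motifs_augment_set(self):
        decs, mset = trtile.decompose_all(
            [("demo", SNIPPET_ALLELE)], SNIPPET_MOTIFS
        )
        assert mset.novel_motifs == ["ACCTTTG"]
        assert mset.input_motifs == ["ACCTTG"]

    def test_empty_batch(self):
        decs, mset = trtile.decompose_all([], ["ACG"])
        assert decs == []
        assert len(mset) == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="dup1"):
            trtile.decompose_all(
                [("dup1", "ACG"), ("dup1", "ACG")], ["ACG"]
            )


class TestMotifSet:
    def test_duplicate_input_motifs_rejected(self):
        with pytest.raises(ValueError):
            MotifSet(["ACG", "ACG"])

    def test_novel_motifs_deduplicated(self):
        ms = MotifSet(["ACG"])
        ms.add("TTT", origin="novel")
        ms.add("TTT", origin="novel")
        assert ms.novel_motifs == ["TTT"]
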
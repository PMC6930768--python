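"""k-mer index construction and greedy longest-match parsing.

The brute-force oracle here re-derives the greedy parse by scanning every
reference position directly (no hash index): at each target position the
longest common extension of length >= k wins, smallest reference
position on ties, everything else accumulates as literal.  The matcher
must agree with it exactly on small random instances.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refcomp import (
    MatchedEntity,
    build_kmer_index,
    decode_first_level,
    kmer_value,
    match_first_level,
)
from refcomp.firstlevel import CorruptStreamError, InvalidAlphabetError

from conftest import B_ROWS, ENTITY_ROWS, R1


def greedy_oracle(target, ref, k):
    """Index-free greedy longest-match parse with smallest-position ties."""
    entities = []
    cur = (0, 0)
    literal = ""
    i = 0
    while i < len(target):
        best_len, best_pos = 0, -1
        for p in range(len(ref) - k + 1):
            length = 0
            while (
                p + length < len(ref)
                and i + length < len(target)
                and ref[p + length] == target[i + length]
            ):
                length += 1
            if length >= k and length > best_len:
                best_len, best_pos = length, p
        if best_len:
            if cur[1] or literal:
                entities.append(MatchedEntity(cur[0], cur[1], literal))
            cur, literal = (best_pos + 1, best_len), ""
            i += best_len
        else:
            literal += target[i]
            i += 1
    entities.append(MatchedEntity(cur[0], cur[1], literal))
    return entities


class TestKmerValue:
    @pytest.mark.parametrize(
        "kmer,k,value",
        [("A", 1, 0), ("AC", 2, 1), ("TTTT", 4, 255), ("CG", 2, 6), ("GT", 2, 11)],
    )
    def test_positional_base4_values(self, kmer, k, value):
        assert kmer_value(kmer, k) == value

    def test_injective_over_all_3mers(self):
        values = {kmer_value(a + b + c, 3)
                  for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        assert len(values) == 64

    def test_non_acgt_rejected(self):
        with pytest.raises(InvalidAlphabetError):
            kmer_value("AN", 2)


class TestKmerIndex:
    def test_repeated_kmer_chain(self):
        idx = build_kmer_index("AAAA", 2)
        assert idx.H[0] == 2
        assert idx.L.tolist() == [-1, 0, 1]
        assert idx.chain(0) == [2, 1, 0]

    def test_unique_kmers(self):
        idx = build_kmer_index("ACGT", 2)
        hits = {v: idx.H[v] for v in range(16) if idx.H[v] != -1}
        assert hits == {1: 0, 6: 1, 11: 2}
        assert all(v == -1 for v in idx.L)

    def test_table_size_is_4_to_the_k(self):
        for k in (1, 3, 5):
            assert len(build_kmer_index("ACGTACGTAC", k).H) == 4**k

    def test_short_reference_gives_empty_index(self):
        with pytest.warns(UserWarning):
            idx = build_kmer_index("", 2)
        assert idx.empty
        assert match_first_level("ACGT", idx) == [MatchedEntity(0, 0, "ACGT")]

    @given(st.text(alphabet="ACGT", min_size=2, max_size=60), st.integers(1, 4))
    @settings(derandomize=True, max_examples=150)
    def test_chain_completeness_vs_dictionary_oracle(self, ref, k):
        """Every k-mer start position must be reachable from H through L."""
        if len(ref) < k:
            return
        idx = build_kmer_index(ref, k)
        positions = {}
        for i in range(len(ref) - k + 1):
            positions.setdefault(ref[i : i + k], []).append(i)
        for kmer, starts in positions.items():
            assert idx.chain(kmer_value(kmer, k)) == starts[::-1]


class TestMatching:
    def test_self_match_single_entity(self):
        idx = build_kmer_index("ACGTACGT", 2)
        assert match_first_level("ACGTACGT", idx) == [MatchedEntity(1, 8, "")]

    def test_snp_parse(self):
        idx = build_kmer_index("ACGTACGT", 2)
        assert match_first_level("ACGTTCGT", idx) == [
            MatchedEntity(1, 4, "T"),
            MatchedEntity(2, 3, ""),
        ]

    def test_no_shared_kmer_pure_literal(self):
        idx = build_kmer_index("AAAA", 2)
        assert match_first_level("CCCC", idx) == [MatchedEntity(0, 0, "CCCC")]

    def test_trailing_short_tail_is_literal(self):
        idx = build_kmer_index("ACGTACGTAC", 4)
        entities = match_first_level("ACGTACGTACG", idx)
        assert decode_first_level(entities, "ACGTACGTAC") == "ACGTACGTACG"
        assert entities[-1].mismatch.endswith("G")

    def test_every_match_has_substring_equality(self):
        rng = np.random.default_rng(7)
        ref = "".join(rng.choice(list("ACGT"), 300))
        target = "".join(
            c if rng.random() > 0.05 else rng.choice(list("ACGT"))
            for c in ref
        )
        idx = build_kmer_index(ref, 4)
        cursor = 0
        for e in match_first_level(target, idx):
            if e.length:
                assert e.length >= 4
                covered = target[cursor : cursor + e.length]
                assert ref[e.position - 1 : e.position - 1 + e.length] == covered
            cursor += e.length + len(e.mismatch)

    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=50),
        st.text(alphabet="ACGT", min_size=0, max_size=50),
        st.integers(2, 4),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_oracle(self, ref, target, k):
        if len(ref) < k:
            return
        idx = build_kmer_index(ref, k)
        assert match_first_level(target, idx) == greedy_oracle(target, ref, k)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_lossless_parse_on_mutated_targets(self, seed):
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), 200))
        target = "".join(
            rng.choice(list("ACGT")) if rng.random() < 0.1 else c for c in ref
        )
        idx = build_kmer_index(ref, 3)
        assert decode_first_level(match_first_level(target, idx), ref) == target


class TestDecode:
    def test_printed_entity_rows_decode_to_printed_b_rows(self):
        for name, row in ENTITY_ROWS.items():
            entities = [MatchedEntity(*e) for e in row]
            assert decode_first_level(entities, R1) == B_ROWS[name]

    def test_full_reference_copy(self):
        assert decode_first_level([MatchedEntity(1, 20, "")], R1) == R1

    def test_literal_only_stream(self):
        assert decode_first_level([MatchedEntity(0, 0, "CCCC")], R1) == "CCCC"

    def test_out_of_bounds_entity_rejected(self):
        with pytest.raises(CorruptStreamError):
            decode_first_level([MatchedEntity(15, 10, "")], R1)
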
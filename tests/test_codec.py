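"""Stream codecs: predictive positions, RLE, entropy coding, backends, archive."""

import pytest
from hypothesis import given, settings, strategies as st

from refcomp import MatchedEntity, Run, SpecialChar, compression_gain
from refcomp.codec import (
    Archive,
    TargetSection,
    UnsupportedBackendError,
    backend_compress,
    backend_decompress,
    deserialize_archive,
    entropy_decode_specials,
    entropy_encode_specials,
    predictive_decode_positions,
    predictive_encode_positions,
    rle_decode,
    rle_encode,
    serialize_archive,
    zigzag_decode,
    zigzag_encode,
)
from refcomp.lowercase import LowercaseMatchResult


class TestPredictivePositions:
    def test_gap_after_mismatch(self):
        entities = [MatchedEntity(1, 4, "T"), MatchedEntity(6, 3, "")]
        deltas, lengths, mismatches = predictive_encode_positions(entities)
        assert deltas == [1, 0]
        assert predictive_decode_positions(deltas, lengths, mismatches) == entities

    def test_snp_only_parse_is_all_zero_after_first(self):
        entities = [MatchedEntity(1, 10, "A"), MatchedEntity(12, 8, "")]
        assert predictive_encode_positions(entities)[0] == [1, 0]

    def test_single_entity_delta_is_position(self):
        assert predictive_encode_positions([MatchedEntity(7, 3, "")])[0] == [7]

    @given(st.lists(
        st.builds(MatchedEntity, st.integers(0, 50), st.integers(0, 20),
                  st.text(alphabet="ACGT", max_size=3)),
        max_size=20,
    ))
    @settings(derandomize=True)
    def test_inverse_pair_property(self, entities):
        assert predictive_decode_positions(
            *predictive_encode_positions(entities)
        ) == entities


class TestRle:
    @pytest.mark.parametrize(
        "values,expected",
        [([25, 25, 25, 24], [(25, 3), (24, 1)]), ([], []), ([7], [(7, 1)])],
    )
    def test_classic_rle(self, values, expected):
        assert rle_encode(values) == expected
        assert rle_decode(expected) == values

    @given(st.lists(st.integers(0, 3), max_size=50))
    @settings(derandomize=True)
    def test_inverse_pair_property(self, values):
        assert rle_decode(rle_encode(values)) == values


class TestEntropyCoding:
    def test_single_symbol_alphabet_one_bit_each(self):
        specials = [SpecialChar(22, "X"), SpecialChar(0, "X"), SpecialChar(0, "X")]
        lengths, n_bits, stream, gaps = entropy_encode_specials(specials)
        assert lengths == {"X": 1}
        assert n_bits == 3
        assert gaps == [22, 0, 0]
        assert entropy_decode_specials(lengths, n_bits, stream, gaps) == specials

    def test_empty_stream(self):
        assert entropy_encode_specials([]) == ({}, 0, b"", [])

    def test_frequent_symbol_gets_shorter_code(self):
        specials = [SpecialChar(0, s) for s in "RYRR"]
        lengths, *_ = entropy_encode_specials(specials)
        assert lengths["R"] <= lengths["Y"]

    @given(st.lists(
        st.builds(SpecialChar, st.integers(0, 30), st.sampled_from("RYKMSWX-")),
        max_size=40,
    ))
    @settings(derandomize=True, max_examples=150)
    def test_inverse_pair_property(self, specials):
        lengths, n_bits, stream, gaps = entropy_encode_specials(specials)
        assert entropy_decode_specials(lengths, n_bits, stream, gaps) == specials


class TestBackends:
    @pytest.mark.parametrize("backend", ["store", "lzma", "zlib", "bz2"])
    def test_roundtrip(self, backend):
        import os
        data = os.urandom(500)
        assert backend_decompress(backend_compress(data, backend), backend) == data
        assert backend_decompress(backend_compress(b"", backend), backend) == b""

    def test_repetitive_input_shrinks(self):
        data = b"ACGT" * 1000
        assert len(backend_compress(data, "lzma")) < len(data)

    def test_unknown_backend_rejected(self):
        with pytest.raises(UnsupportedBackendError):
            backend_compress(b"x", "ppmd")


class TestZigzag:
    @given(st.integers(-(2**40), 2**40))
    @settings(derandomize=True)
    def test_roundtrip_and_non_negative(self, value):
        encoded = zigzag_encode(value)
        assert encoded >= 0
        assert zigzag_decode(encoded) == value


class TestGain:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (80.13, 103.62, 22.67),  # batch archive vs best single-genome tool
            (75.38, 96.73, 22.07),
            (10.0, 10.0, 0.0),
        ],
    )
    def test_percent_reduction(self, a, b, expected):
        assert compression_gain(a, b) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compression_gain(1.0, 0.0)


def _section():
    return TargetSection(
        identifier="chr1 test",
        line_widths=[60] * 5 + [33],
        lowercase=LowercaseMatchResult([True, False], [(2, 1)], [Run(3, 4)]),
        n_runs=[],
        specials=[SpecialChar(5, "R")],
        tokens=[MatchedEntity(1, 100, "ACG"), MatchedEntity(110, 50, "")],
    )


class TestArchive:
    def test_roundtrip_bit_exact(self):
        archive = Archive(k=14, p=10.0, mode="batch", backend="lzma",
                          ref_checksum=12345, targets=[_section()])
        data = serialize_archive(archive)
        back = deserialize_archive(data)
        assert back.k == 14 and back.p == 10.0 and back.mode == "batch"
        assert back.ref_checksum == 12345
        assert back.targets == archive.targets

    def test_determinism(self):
        archive = Archive(k=8, p=50.0, mode="single", backend="zlib",
                          ref_checksum=1, targets=[_section()])
        assert serialize_archive(archive) == serialize_archive(archive)
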
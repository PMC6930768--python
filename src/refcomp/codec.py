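"""Stream encoding and the archive container.

Every stream produced by extraction and matching is serialized with a
scheme fitted to its statistics:

* matched-entity positions — predictive incremental encoding: the next
  position is predicted as previous position + length + mismatch-literal
  length, and only the (usually zero, for SNP-dominated targets) signed
  difference is stored, zigzag-mapped and varint-coded;
* identifiers and line widths — run-length encoding;
* special characters — a canonical static prefix (Huffman) code built
  from symbol frequencies, plus a varint gap stream;
* everything else — varints.

The concatenated sections are then passed through a pluggable
general-purpose backend compressor (LZMA by default) and wrapped in a
small container with magic, version, backend id and a reference
checksum.
"""

from __future__ import annotations

import bz2
import heapq
import lzma
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .fasta import Run, SpecialChar, TargetInfo
from .firstlevel import MatchedEntity
from .lowercase import LowercaseMatchResult
from .secondlevel import RunTriple, SecondLevelToken

MAGIC = b"RGCA"
VERSION = 1


class CorruptArchiveError(ValueError):
    """Archive bytes are truncated or internally inconsistent."""


class UnsupportedBackendError(ValueError):
    """Archive names a backend compressor this build does not provide."""


# ---------------------------------------------------------------------------
# varint / zigzag primitives


def zigzag_encode(value: int) -> int:
    return (value << 1) ^ (value >> 63) if value < 0 else value << 1


def zigzag_decode(value: int) -> int:
    return (value >> 1) ^ -(value & 1)


class ByteWriter:
    def __init__(self) -> None:
        self.buf = bytearray()

    def u8(self, value: int) -> None:
        self.buf.append(value & 0xFF)

    def varint(self, value: int) -> None:
        if value < 0:
            raise ValueError("varint requires a non-negative integer")
        while True:
            byte = value & 0x7F
            value >>= 7
            if value:
                self.buf.append(byte | 0x80)
            else:
                self.buf.append(byte)
                return

    def svarint(self, value: int) -> None:
        self.varint(zigzag_encode(value))

    def raw(self, data: bytes) -> None:
        self.buf.extend(data)

    def text(self, s: str) -> None:
        data = s.encode("utf-8")
        self.varint(len(data))
        self.raw(data)

    def getvalue(self) -> bytes:
        return bytes(self.buf)


class ByteReader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def u8(self) -> int:
        if self.pos >= len(self.data):
            raise CorruptArchiveError("unexpected end of archive")
        b = self.data[self.pos]
        self.pos += 1
        return b

    def varint(self) -> int:
        shift = 0
        value = 0
        while True:
            b = self.u8()
            value |= (b & 0x7F) << shift
            if not b & 0x80:
                return value
            shift += 7
            if shift > 70:
                raise CorruptArchiveError("varint overflow")

    def svarint(self) -> int:
        return zigzag_decode(self.varint())

    def raw(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise CorruptArchiveError("unexpected end of archive")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def text(self) -> str:
        return self.raw(self.varint()).decode("utf-8")


# ---------------------------------------------------------------------------
# predictive position encoding


def predictive_encode_positions(
    entities: Sequence[MatchedEntity],
) -> Tuple[List[int], List[int], List[str]]:
    """Split entities into (position deltas, lengths, mismatch literals).

    The i-th position is predicted as position_{i-1} + length_{i-1} +
    |mismatch_{i-1}| (0 before the first entity); the delta is the real
    position minus the prediction, so an SNP-only target encodes to all
    zeros.  Inverse: :func:`predictive_decode_positions`.
    """
    deltas: List[int] = []
    lengths: List[int] = []
    mismatches: List[str] = []
    predicted = 0
    for e in entities:
        deltas.append(e.position - predicted)
        lengths.append(e.length)
        mismatches.append(e.mismatch)
        predicted = e.position + e.length + len(e.mismatch)
    return deltas, lengths, mismatches


def predictive_decode_positions(
    deltas: Sequence[int], lengths: Sequence[int], mismatches: Sequence[str]
) -> List[MatchedEntity]:
    entities: List[MatchedEntity] = []
    predicted = 0
    for d, length, mm in zip(deltas, lengths, mismatches):
        position = predicted + d
        entities.append(MatchedEntity(position, length, mm))
        predicted = position + length + len(mm)
    return entities


# ---------------------------------------------------------------------------
# run-length encoding


def rle_encode(values: Sequence) -> List[Tuple[object, int]]:
    """Classic RLE: maximal runs of equal values as (value, count) pairs."""
    out: List[Tuple[object, int]] = []
    for v in values:
        if out and out[-1][0] == v:
            out[-1] = (v, out[-1][1] + 1)
        else:
            out.append((v, 1))
    return out


def rle_decode(pairs: Sequence[Tuple[object, int]]) -> List:
    out: List = []
    for v, count in pairs:
        out.extend([v] * count)
    return out


# ---------------------------------------------------------------------------
# static entropy coding (canonical prefix code)


def _code_lengths(freqs: Dict[str, int]) -> Dict[str, int]:
    if not freqs:
        return {}
    if len(freqs) == 1:
        return {next(iter(freqs)): 1}
    heap = [(f, i, sym) for i, (sym, f) in enumerate(sorted(freqs.items()))]
    heapq.heapify(heap)
    lengths = {sym: 0 for sym in freqs}
    members: Dict[int, List[str]] = {i: [s] for _, i, s in heap}
    counter = len(heap)
    heap = [(f, i) for f, i, _ in heap]
    heapq.heapify(heap)
    while len(heap) > 1:
        f1, i1 = heapq.heappop(heap)
        f2, i2 = heapq.heappop(heap)
        merged = members[i1] + members[i2]
        for sym in merged:
            lengths[sym] += 1
        members[counter] = merged
        heapq.heappush(heap, (f1 + f2, counter))
        counter += 1
    return lengths


def canonical_code(lengths: Dict[str, int]) -> Dict[str, Tuple[int, int]]:
    """Canonical (code, length) assignment from code lengths."""
    code = 0
    prev_len = 0
    out: Dict[str, Tuple[int, int]] = {}
    for sym in sorted(lengths, key=lambda s: (lengths[s], s)):
        length = lengths[sym]
        code <<= length - prev_len
        out[sym] = (code, length)
        code += 1
        prev_len = length
    return out


def entropy_encode_specials(
    specials: Sequence[SpecialChar],
) -> Tuple[Dict[str, int], int, bytes, List[int]]:
    """Static entropy coding of the special-character stream.

    Returns (symbol code lengths, bit count, packed bitstream MSB-first,
    gap list).  More frequent symbols receive shorter codes; a
    single-symbol alphabet uses 1 bit per symbol.
    """
    freqs: Dict[str, int] = {}
    for sp in specials:
        freqs[sp.symbol] = freqs.get(sp.symbol, 0) + 1
    lengths = _code_lengths(freqs)
    codes = canonical_code(lengths)
    n_bits = 0
    acc = 0
    for sp in specials:
        code, length = codes[sp.symbol]
        acc = (acc << length) | code
        n_bits += length
    if n_bits:
        pad = (8 - n_bits % 8) % 8  # left-align bits in the final byte
        stream = (acc << pad).to_bytes((n_bits + 7) // 8, "big")
    else:
        stream = b""
    return lengths, n_bits, stream, [sp.gap for sp in specials]


def entropy_decode_specials(
    lengths: Dict[str, int], n_bits: int, stream: bytes, gaps: Sequence[int]
) -> List[SpecialChar]:
    codes = canonical_code(lengths)
    decode_map = {v: sym for sym, v in codes.items()}
    out: List[SpecialChar] = []
    bitpos = 0
    code = 0
    length = 0
    for gap in gaps:
        while True:
            if bitpos >= n_bits:
                raise CorruptArchiveError("entropy stream exhausted")
            byte = stream[bitpos // 8]
            bit = (byte >> (7 - bitpos % 8)) & 1
            bitpos += 1
            code = (code << 1) | bit
            length += 1
            sym = decode_map.get((code, length))
            if sym is not None:
                out.append(SpecialChar(gap=gap, symbol=sym))
                code = 0
                length = 0
                break
    return out


# ---------------------------------------------------------------------------
# backend compressors

_BACKENDS = {
    0: ("store", lambda b: b, lambda b: b),
    1: ("lzma", lambda b: lzma.compress(b, preset=9), lzma.decompress),
    2: ("zlib", lambda b: zlib.compress(b, 9), zlib.decompress),
    3: ("bz2", lambda b: bz2.compress(b, 9), bz2.decompress),
}
BACKEND_IDS = {name: bid for bid, (name, _, _) in _BACKENDS.items()}
DEFAULT_BACKEND = "lzma"


def backend_compress(data: bytes, backend: str = DEFAULT_BACKEND) -> bytes:
    bid = BACKEND_IDS.get(backend)
    if bid is None:
        raise UnsupportedBackendError(f"unknown backend {backend!r}")
    return _BACKENDS[bid][1](data)


def backend_decompress(data: bytes, backend: str = DEFAULT_BACKEND) -> bytes:
    bid = BACKEND_IDS.get(backend)
    if bid is None:
        raise UnsupportedBackendError(f"unknown backend {backend!r}")
    try:
        return _BACKENDS[bid][2](data)
    except Exception as exc:  # backend-specific stream errors
        raise CorruptArchiveError(f"backend payload corrupt: {exc}") from exc


# ---------------------------------------------------------------------------
# gain metric


def compression_gain(size_a: float, size_b: float) -> float:
    """Relative size reduction of A versus B: 100 * (1 - A/B), 2 decimals."""
    return round(100.0 * (1.0 - size_a / size_b), 2)


# ---------------------------------------------------------------------------
# archive container


@dataclass
class TargetSection:
    """Everything the archive stores for one target file."""

    identifier: str
    line_widths: List[int]
    lowercase: LowercaseMatchResult
    n_runs: List[Run]
    specials: List[SpecialChar]
    tokens: List[SecondLevelToken]
    newline: str = "\n"
    trailing_newline: bool = True


@dataclass
class Archive:
    k: int
    p: float
    mode: str  # "single" | "batch"
    backend: str
    ref_checksum: int
    targets: List[TargetSection]


def _write_runs(w: ByteWriter, runs: Sequence[Run]) -> None:
    w.varint(len(runs))
    for r in runs:
        w.varint(r.gap)
        w.varint(r.length)


def _read_runs(r: ByteReader) -> List[Run]:
    return [Run(gap=r.varint(), length=r.varint()) for _ in range(r.varint())]


def _write_tokens(w: ByteWriter, tokens: Sequence[SecondLevelToken]) -> None:
    w.varint(len(tokens))
    predicted = 0
    for tok in tokens:
        if isinstance(tok, RunTriple):
            w.u8(1)
            w.varint(tok.sequence_id)
            w.varint(tok.position)
            w.varint(tok.run_length)
        else:
            w.u8(0)
            w.svarint(tok.position - predicted)
            w.varint(tok.length)
            w.text(tok.mismatch)
            predicted = tok.position + tok.length + len(tok.mismatch)


def _read_tokens(r: ByteReader) -> List[SecondLevelToken]:
    n = r.varint()
    tokens: List[SecondLevelToken] = []
    predicted = 0
    for _ in range(n):
        tag = r.u8()
        if tag == 1:
            tokens.append(RunTriple(r.varint(), r.varint(), r.varint()))
        elif tag == 0:
            position = predicted + r.svarint()
            length = r.varint()
            mismatch = r.text()
            tokens.append(MatchedEntity(position, length, mismatch))
            predicted = position + length + len(mismatch)
        else:
            raise CorruptArchiveError(f"unknown token tag {tag}")
    return tokens


def _write_flags(w: ByteWriter, flags: Sequence[bool]) -> None:
    w.varint(len(flags))
    byte = 0
    nbits = 0
    for f in flags:
        byte = (byte << 1) | int(f)
        nbits += 1
        if nbits == 8:
            w.u8(byte)
            byte = 0
            nbits = 0
    if nbits:
        w.u8(byte << (8 - nbits))


def _read_flags(r: ByteReader) -> List[bool]:
    n = r.varint()
    data = r.raw((n + 7) // 8)
    return [bool((data[i // 8] >> (7 - i % 8)) & 1) for i in range(n)]


def _write_section(w: ByteWriter, t: TargetSection) -> None:
    flags = (1 if t.newline == "\r\n" else 0) | (0 if t.trailing_newline else 2)
    w.u8(flags)
    # identifier: RLE over characters
    id_pairs = rle_encode(list(t.identifier))
    w.varint(len(id_pairs))
    for ch, count in id_pairs:
        w.text(ch)
        w.varint(count)
    width_pairs = rle_encode(t.line_widths)
    w.varint(len(width_pairs))
    for value, count in width_pairs:
        w.varint(value)
        w.varint(count)
    _write_flags(w, t.lowercase.flags)
    w.varint(len(t.lowercase.matched_index_rle))
    for start, count in t.lowercase.matched_index_rle:
        w.varint(start)
        w.varint(count)
    _write_runs(w, t.lowercase.literal_runs)
    _write_runs(w, t.n_runs)
    lengths, n_bits, stream, gaps = entropy_encode_specials(t.specials)
    w.varint(len(lengths))
    for sym in sorted(lengths):
        w.text(sym)
        w.varint(lengths[sym])
    w.varint(n_bits)
    w.raw(stream)
    w.varint(len(gaps))
    for gap in gaps:
        w.varint(gap)
    _write_tokens(w, t.tokens)


def serialize_archive(archive: Archive) -> bytes:
    body = ByteWriter()
    body.varint(archive.k)
    body.varint(round(archive.p * 100))
    body.u8(0 if archive.mode == "single" else 1)
    body.varint(archive.ref_checksum)
    body.varint(len(archive.targets))
    for t in archive.targets:
        _write_section(body, t)
    bid = BACKEND_IDS.get(archive.backend)
    if bid is None:
        raise UnsupportedBackendError(f"unknown backend {archive.backend!r}")
    payload = backend_compress(body.getvalue(), archive.backend)
    head = ByteWriter()
    head.raw(MAGIC)
    head.u8(VERSION)
    head.u8(bid)
    head.varint(len(payload))
    head.raw(payload)
    return head.getvalue()


def deserialize_archive(data: bytes) -> Archive:
    r = ByteReader(data)
    if r.raw(4) != MAGIC:
        raise CorruptArchiveError("bad magic; not an archive")
    version = r.u8()
    if version != VERSION:
        raise CorruptArchiveError(f"unsupported archive version {version}")
    bid = r.u8()
    if bid not in _BACKENDS:
        raise UnsupportedBackendError(f"unknown backend id {bid}")
    backend = _BACKENDS[bid][0]
    payload = r.raw(r.varint())
    body = ByteReader(backend_decompress(payload, backend))
    k = body.varint()
    p = body.varint() / 100
    mode = "single" if body.u8() == 0 else "batch"
    ref_checksum = body.varint()
    n_targets = body.varint()
    targets = [_read_full_section(body) for _ in range(n_targets)]
    if body.pos != len(body.data):
        raise CorruptArchiveError("trailing bytes after last section")
    return Archive(
        k=k, p=p, mode=mode, backend=backend, ref_checksum=ref_checksum,
        targets=targets,
    )


def _read_full_section(r: ByteReader) -> TargetSection:
    flags = r.u8()
    identifier = "".join(
        rle_decode([(r.text(), r.varint()) for _ in range(r.varint())])
    )
    line_widths = rle_decode([(r.varint(), r.varint()) for _ in range(r.varint())])
    lc_flags = _read_flags(r)
    rle_pairs = [(r.varint(), r.varint()) for _ in range(r.varint())]
    literal_runs = _read_runs(r)
    n_runs = _read_runs(r)
    lengths = {r.text(): r.varint() for _ in range(r.varint())}
    n_bits = r.varint()
    stream = r.raw((n_bits + 7) // 8)
    gaps = [r.varint() for _ in range(r.varint())]
    specials = entropy_decode_specials(lengths, n_bits, stream, gaps)
    tokens = _read_tokens(r)
    return TargetSection(
        identifier=identifier,
        line_widths=line_widths,
        lowercase=LowercaseMatchResult(lc_flags, rle_pairs, literal_runs),
        n_runs=n_runs,
        specials=specials,
        tokens=tokens,
        newline="\r\n" if flags & 1 else "\n",
        trailing_newline=not flags & 2,
    )
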
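"""Decompression: invert every codec and reassemble the original files.

The archive stores only what the reference cannot supply, so the same
reference FASTA used at compression time is required; its B stream and
lowercase runs are re-extracted and checked against the stored checksum
before any decoding.  Restoration of one target proceeds special
characters -> N runs -> lowercase -> line wrapping, the reverse of the
extraction order, with all positions in concatenated-sequence
coordinates.  Runtime and memory are linear in the total output size.
"""

from __future__ import annotations

from typing import List

from . import fasta
from .codec import CorruptArchiveError, deserialize_archive
from .compress import reference_checksum
from .fasta import TargetInfo, delta_decode_runs, special_positions
from .lowercase import decode_lowercase
from .secondlevel import SecondLevelConfig, decode_second_level
from .firstlevel import decode_first_level


class ReferenceMismatchError(ValueError):
    """The supplied reference differs from the one used at compression."""


def reconstruct_target(info: TargetInfo) -> str:
    """Reassemble the original FASTA text from a target decomposition."""
    n_abs = delta_decode_runs(info.n_runs)
    sp_pos = special_positions(info.specials)
    total = len(info.B) + sum(length for _, length in n_abs) + len(sp_pos)
    if total != sum(info.line_widths):
        raise CorruptArchiveError(
            f"stream lengths ({total}) disagree with line widths "
            f"({sum(info.line_widths)})"
        )
    seq = [""] * total
    for start, length in n_abs:
        if start + length > total:
            raise CorruptArchiveError("N run out of bounds")
        for j in range(start, start + length):
            seq[j] = "N"
    for pos, sp in zip(sp_pos, info.specials):
        if pos >= total or seq[pos]:
            raise CorruptArchiveError("special character position conflict")
        seq[pos] = sp.symbol
    b_iter = iter(info.B)
    try:
        for j in range(total):
            if not seq[j]:
                seq[j] = next(b_iter)
    except StopIteration:
        raise CorruptArchiveError("B stream shorter than required") from None
    for start, length in delta_decode_runs(info.lowercase_runs):
        if start + length > total:
            raise CorruptArchiveError("lowercase run out of bounds")
        for j in range(start, start + length):
            seq[j] = seq[j].lower()
    lines = []
    pos = 0
    for width in info.line_widths:
        lines.append("".join(seq[pos : pos + width]))
        pos += width
    nl = info.newline
    text = nl.join([">" + info.identifier] + lines)
    if info.trailing_newline:
        text += nl
    return text


def decompress_archive(archive_bytes: bytes, reference_text: str) -> List[str]:
    """Restore every target FASTA text from an archive and its reference."""
    archive = deserialize_archive(archive_bytes)
    ref = fasta.extract_reference(fasta.parse_fasta(reference_text))
    if reference_checksum(ref.B) != archive.ref_checksum:
        raise ReferenceMismatchError(
            "reference B stream does not match the archive checksum"
        )
    token_streams = [t.tokens for t in archive.targets]
    entity_streams = decode_second_level(
        token_streams, SecondLevelConfig(p=archive.p)
    )
    outputs: List[str] = []
    for section, entities in zip(archive.targets, entity_streams):
        info = TargetInfo(
            identifier=section.identifier,
            line_widths=section.line_widths,
            B=decode_first_level(entities, ref.B),
            lowercase_runs=decode_lowercase(section.lowercase, ref.lowercase_runs),
            n_runs=section.n_runs,
            specials=section.specials,
            newline=section.newline,
            trailing_newline=section.trailing_newline,
        )
        outputs.append(reconstruct_target(info))
    return outputs
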
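"""End-to-end compression of a FASTA collection against a reference.

Pipeline per target: extract streams, first-level match the B stream
against the reference's k-mer index, match lowercase runs against the
reference's, then (in batch mode) second-level match the entity streams
across the collection, and finally serialize everything through the
stream codec into one archive.

``single`` mode compresses each target independently against the
reference (no second-level matching); ``batch`` mode additionally
exploits similarity among the targets themselves.
"""

from __future__ import annotations

import zlib
from typing import List, Sequence

from . import fasta
from .codec import Archive, DEFAULT_BACKEND, TargetSection, serialize_archive
from .firstlevel import build_kmer_index, match_first_level
from .lowercase import match_lowercase
from .secondlevel import SecondLevelConfig, match_second_level

DEFAULT_K = 14
DEFAULT_P = 10.0


def reference_checksum(B_ref: str) -> int:
    """CRC32 of the reference B stream, stored to detect a wrong reference."""
    return zlib.crc32(B_ref.encode("ascii"))


def compress_collection(
    reference_text: str,
    target_texts: Sequence[str],
    k: int = DEFAULT_K,
    p: float = DEFAULT_P,
    mode: str = "batch",
    backend: str = DEFAULT_BACKEND,
) -> bytes:
    """Compress target FASTA texts against a reference FASTA text.

    Returns the archive bytes.  Decompression with the same reference
    restores every target byte-for-byte.
    """
    if mode not in ("single", "batch"):
        raise ValueError(f"mode must be 'single' or 'batch', got {mode!r}")
    ref = fasta.extract_reference(fasta.parse_fasta(reference_text))
    idx = build_kmer_index(ref.B, k)
    infos = [fasta.extract_target(fasta.parse_fasta(t)) for t in target_texts]
    entity_streams = [match_first_level(info.B, idx) for info in infos]
    if mode == "batch" and len(entity_streams) > 1:
        token_streams = match_second_level(entity_streams, SecondLevelConfig(p=p))
    else:
        token_streams = [list(s) for s in entity_streams]
    sections: List[TargetSection] = []
    for info, tokens in zip(infos, token_streams):
        sections.append(
            TargetSection(
                identifier=info.identifier,
                line_widths=info.line_widths,
                lowercase=match_lowercase(info.lowercase_runs, ref.lowercase_runs),
                n_runs=info.n_runs,
                specials=info.specials,
                tokens=tokens,
                newline=info.newline,
                trailing_newline=info.trailing_newline,
            )
        )
    archive = Archive(
        k=k,
        p=p,
        mode=mode,
        backend=backend,
        ref_checksum=reference_checksum(ref.B),
        targets=sections,
    )
    return serialize_archive(archive)
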
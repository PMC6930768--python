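"""Lowercase-run matching against the reference and tolerance-1 RLE.

Soft-masked assemblies mark repeats with lowercase, and the case
structure of a resequenced genome is usually near-identical to its
reference's.  Each target lowercase run (a gap-encoded (gap, length)
tuple) is looked up in the reference's run list: a hit is stored as the
1-based reference index, a miss goes verbatim to a literal array.  The
matched indices are mostly consecutive, so they are run-length encoded
with "tolerance 1": a run is a maximal arithmetic progression with
common difference exactly +1, stored as (first_value, count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .fasta import Run
from .firstlevel import CorruptStreamError


@dataclass
class LowercaseMatchResult:
    """Per-tuple match flags, RLE-compacted reference indices, and literals."""

    flags: List[bool]
    matched_index_rle: List[Tuple[int, int]]
    literal_runs: List[Run]


def rle_tolerance1(indices: Sequence[int]) -> List[Tuple[int, int]]:
    """Encode maximal difference-(+1) progressions as (start, count) pairs."""
    out: List[Tuple[int, int]] = []
    for value in indices:
        if out and value == out[-1][0] + out[-1][1]:
            out[-1] = (out[-1][0], out[-1][1] + 1)
        else:
            out.append((value, 1))
    return out


def rle_tolerance1_decode(pairs: Sequence[Tuple[int, int]]) -> List[int]:
    """Expand (start, count) pairs back to the index list."""
    out: List[int] = []
    for start, count in pairs:
        out.extend(range(start, start + count))
    return out


def match_lowercase(
    target_runs: Sequence[Run], ref_runs: Sequence[Run]
) -> LowercaseMatchResult:
    """Match target lowercase tuples against the reference tuple array.

    Equality is exact on (gap, length); the whole reference array is
    scanned and the first occurrence wins.
    """
    first_index = {}
    for i, r in enumerate(ref_runs, start=1):
        first_index.setdefault((r.gap, r.length), i)
    flags: List[bool] = []
    indices: List[int] = []
    literals: List[Run] = []
    for r in target_runs:
        idx = first_index.get((r.gap, r.length))
        if idx is None:
            flags.append(False)
            literals.append(r)
        else:
            flags.append(True)
            indices.append(idx)
    return LowercaseMatchResult(
        flags=flags,
        matched_index_rle=rle_tolerance1(indices),
        literal_runs=literals,
    )


def decode_lowercase(
    result: LowercaseMatchResult, ref_runs: Sequence[Run]
) -> List[Run]:
    """Exact inverse of :func:`match_lowercase`."""
    indices = iter(rle_tolerance1_decode(result.matched_index_rle))
    literals = iter(result.literal_runs)
    out: List[Run] = []
    for flag in result.flags:
        if flag:
            idx = next(indices)
            if not 1 <= idx <= len(ref_runs):
                raise CorruptStreamError(f"lowercase index {idx} out of range")
            out.append(ref_runs[idx - 1])
        else:
            out.append(next(literals))
    return out
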
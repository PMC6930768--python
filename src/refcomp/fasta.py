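"""FASTA parsing and sequence-information extraction.

A genome record is decomposed into a basic base stream B (upper-case
A/C/G/T only) plus side-information streams that make the decomposition
lossless: lowercase runs, N runs, special (non-ACGTN) characters, the
header identifier and the per-line widths.  Run and character positions
are recorded on the concatenated sequence (line breaks removed, 0-based)
and stored gap-encoded: each run stores its distance from the end of the
previous run rather than an absolute coordinate.

Lowercase extraction happens before N/special removal, so a lowercase
``n`` contributes to both the lowercase runs and the N runs, and a
lowercase special character contributes to the lowercase runs as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

BASES = frozenset("ACGT")


class MalformedFastaError(ValueError):
    """Input is not a parseable single-record FASTA file."""


class MultiRecordError(MalformedFastaError):
    """More than one '>' header line; only single-record files are supported."""


class InvalidRunsError(ValueError):
    """Absolute runs overlap or are out of order."""


@dataclass(frozen=True)
class Run:
    """A homogeneous character run in gap (delta) coordinates.

    ``gap`` counts the characters between the end of the previous run of
    the same kind (or the sequence start for the first run) and this
    run's first character; ``length`` is the run length.
    """

    gap: int
    length: int

    def __post_init__(self) -> None:
        if self.gap < 0 or self.length < 1:
            raise InvalidRunsError(f"invalid run ({self.gap}, {self.length})")


@dataclass(frozen=True)
class SpecialChar:
    """One non-ACGTN character, gap-encoded against the previous one.

    ``gap`` is the number of characters strictly between the previous
    special character (or the sequence start) and this one; ``symbol``
    is stored case-folded to upper.
    """

    gap: int
    symbol: str


@dataclass
class RawFastaRecord:
    """One FASTA record split into header and raw sequence lines.

    ``newline`` and ``trailing_newline`` capture the byte-level line
    terminator style so reconstruction is byte-exact.
    """

    identifier: str
    lines: List[str]
    newline: str = "\n"
    trailing_newline: bool = True


@dataclass
class ReferenceInfo:
    """The two streams kept for a reference sequence: B and lowercase runs."""

    B: str
    lowercase_runs: List[Run]


@dataclass
class TargetInfo:
    """The complete lossless decomposition of one target FASTA file."""

    identifier: str
    line_widths: List[int]
    B: str
    lowercase_runs: List[Run]
    n_runs: List[Run]
    specials: List[SpecialChar]
    newline: str = "\n"
    trailing_newline: bool = True


def parse_fasta(content: str) -> RawFastaRecord:
    """Parse a single-record FASTA string, preserving line-structure metadata.

    Raises :class:`MalformedFastaError` if the first line is not a ``>``
    header and :class:`MultiRecordError` if more than one header appears.
    """
    if not content:
        raise MalformedFastaError("empty input")
    newline = "\r\n" if "\r\n" in content else "\n"
    trailing = content.endswith(("\n", "\r\n"))
    lines = content.replace("\r\n", "\n").split("\n")
    if trailing:
        lines = lines[:-1]
    if not lines or not lines[0].startswith(">"):
        raise MalformedFastaError("missing '>' header line")
    if any(ln.startswith(">") for ln in lines[1:]):
        raise MultiRecordError("multi-record FASTA files are not supported")
    return RawFastaRecord(
        identifier=lines[0][1:],
        lines=lines[1:],
        newline=newline,
        trailing_newline=trailing,
    )


def _scan_runs(flags: Iterable[bool]) -> List[Tuple[int, int]]:
    """Maximal runs of True positions as absolute (start, length) pairs."""
    runs: List[Tuple[int, int]] = []
    start = -1
    pos = 0
    for pos, flag in enumerate(flags):
        if flag and start < 0:
            start = pos
        elif not flag and start >= 0:
            runs.append((start, pos - start))
            start = -1
    if start >= 0:
        runs.append((start, pos + 1 - start))
    return runs


def delta_encode_runs(absolute_runs: Sequence[Tuple[int, int]]) -> List[Run]:
    """Gap-encode absolute (start, length) runs.

    The first run stores its start; each later run stores the distance
    from the previous run's end.  Inverse of :func:`delta_decode_runs`.
    """
    out: List[Run] = []
    prev_end = 0
    for start, length in absolute_runs:
        if start < prev_end:
            raise InvalidRunsError(f"run at {start} overlaps previous end {prev_end}")
        out.append(Run(gap=start - prev_end, length=length))
        prev_end = start + length
    return out


def delta_decode_runs(runs: Sequence[Run]) -> List[Tuple[int, int]]:
    """Recover absolute (start, length) pairs from gap-encoded runs."""
    out: List[Tuple[int, int]] = []
    prev_end = 0
    for run in runs:
        start = prev_end + run.gap
        out.append((start, run.length))
        prev_end = start + run.length
    return out


def _decompose(seq: str):
    """Split a concatenated sequence into B plus the three side streams."""
    lower_flags = [c.islower() for c in seq]
    upper = seq.upper()
    n_flags = [c == "N" for c in upper]
    b_chars: List[str] = []
    specials: List[SpecialChar] = []
    prev_special = -1
    for pos, c in enumerate(upper):
        if c == "N":
            continue
        if c in BASES:
            b_chars.append(c)
        else:
            gap = pos if prev_special < 0 else pos - prev_special - 1
            specials.append(SpecialChar(gap=gap, symbol=c))
            prev_special = pos
    return (
        "".join(b_chars),
        delta_encode_runs(_scan_runs(lower_flags)),
        delta_encode_runs(_scan_runs(n_flags)),
        specials,
    )


def extract_target(rec: RawFastaRecord) -> TargetInfo:
    """Decompose a to-be-compressed record into its full stream set."""
    seq = "".join(rec.lines)
    B, lowercase_runs, n_runs, specials = _decompose(seq)
    return TargetInfo(
        identifier=rec.identifier,
        line_widths=[len(ln) for ln in rec.lines],
        B=B,
        lowercase_runs=lowercase_runs,
        n_runs=n_runs,
        specials=specials,
        newline=rec.newline,
        trailing_newline=rec.trailing_newline,
    )


def extract_reference(rec: RawFastaRecord) -> ReferenceInfo:
    """Extract only the streams a reference needs: B and lowercase runs."""
    seq = "".join(rec.lines)
    B, lowercase_runs, _, _ = _decompose(seq)
    return ReferenceInfo(B=B, lowercase_runs=lowercase_runs)


def special_positions(specials: Sequence[SpecialChar]) -> List[int]:
    """Absolute concatenated-sequence positions of gap-encoded specials."""
    out: List[int] = []
    prev = -1
    for sp in specials:
        pos = sp.gap if prev < 0 else prev + 1 + sp.gap
        out.append(pos)
        prev = pos
    return out
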
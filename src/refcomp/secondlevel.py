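"""Second-level matching of entity streams across a sequence collection.

After first-level matching, near-duplicate targets produce long stretches
of identical (position, length, mismatch) entities.  Second-level matching
replaces maximal runs (length >= 2) of entities identical to a run in an
earlier target's *first-level* stream with a (sequence_id, position,
run_length) triple.  The first target is never rewritten, and only the
first ``p%`` of targets (at least one) serve as references, which bounds
memory on large collections.

Entity lookup uses a hash table with separate chaining: the hash mixes
position, length and every mismatch base with large prime multipliers,
and candidates are verified by full equality since distinct entities may
collide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

from .firstlevel import CorruptStreamError, MatchedEntity

# Large prime multipliers for entity hashing; table size is a power of two.
_P1 = 1_000_000_007
_P2 = 998_244_353
_TABLE_BITS = 20


@dataclass(frozen=True)
class RunTriple:
    """A run of entities copied from an earlier stream.

    ``sequence_id`` is the 1-based index of the referenced target in
    processing order, ``position`` the 1-based entity index where the run
    starts there, ``run_length`` the number of copied entities (>= 2).
    """

    sequence_id: int
    position: int
    run_length: int


SecondLevelToken = Union[MatchedEntity, RunTriple]


@dataclass(frozen=True)
class SecondLevelConfig:
    """``p``: percentage (0, 100] of targets eligible as references."""

    p: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p <= 100:
            raise ValueError("p must be in (0, 100]")

    def n_references(self, n_targets: int) -> int:
        return max(1, int(self.p / 100 * n_targets))


def entity_hash(e: MatchedEntity, table_bits: int = _TABLE_BITS) -> int:
    """Bucket index for an entity; equal entities hash equally."""
    h = e.position
    h = (h * _P1 + e.length) & 0xFFFFFFFFFFFFFFFF
    for c in e.mismatch:
        h = (h * _P2 + ord(c)) & 0xFFFFFFFFFFFFFFFF
    return h & ((1 << table_bits) - 1)


class EntityHasher:
    """Separate-chaining index of entity occurrences across reference streams."""

    def __init__(self, table_bits: int = _TABLE_BITS):
        self.table_bits = table_bits
        self.buckets: Dict[int, List[Tuple[int, int]]] = {}
        self.streams: Dict[int, Sequence[MatchedEntity]] = {}

    def add_stream(self, sequence_id: int, entities: Sequence[MatchedEntity]) -> None:
        self.streams[sequence_id] = entities
        for idx, e in enumerate(entities):
            self.buckets.setdefault(entity_hash(e, self.table_bits), []).append(
                (sequence_id, idx)
            )

    def occurrences(self, e: MatchedEntity) -> List[Tuple[int, int]]:
        """Verified occurrences of ``e`` as (sequence_id, 0-based index)."""
        return [
            (sid, idx)
            for sid, idx in self.buckets.get(entity_hash(e, self.table_bits), [])
            if self.streams[sid][idx] == e
        ]


def _rewrite_stream(
    entities: Sequence[MatchedEntity], hasher: EntityHasher
) -> List[SecondLevelToken]:
    tokens: List[SecondLevelToken] = []
    n = len(entities)
    t = 0
    while t < n:
        best_len, best_sid, best_idx = 0, 0, 0
        for sid, idx in hasher.occurrences(entities[t]):
            ref = hasher.streams[sid]
            run = 1
            while (
                t + run < n
                and idx + run < len(ref)
                and ref[idx + run] == entities[t + run]
            ):
                run += 1
            if run > best_len or (
                run == best_len and (sid, idx) < (best_sid, best_idx)
            ):
                best_len, best_sid, best_idx = run, sid, idx
        if best_len >= 2:
            tokens.append(RunTriple(best_sid, best_idx + 1, best_len))
            t += best_len
        else:
            tokens.append(entities[t])
            t += 1
    return tokens


def match_second_level(
    streams: Sequence[Sequence[MatchedEntity]],
    cfg: SecondLevelConfig = SecondLevelConfig(),
) -> List[List[SecondLevelToken]]:
    """Rewrite each stream against the first-level streams of earlier targets.

    Stream ``i`` (1-based) may reference streams ``j < i`` within the
    reference set of the first ``max(1, floor(p/100 * N))`` targets.  Runs
    of identical entities of length >= 2 become :class:`RunTriple` tokens;
    everything else stays raw.  Among candidate runs the longest wins,
    with ties broken by lowest sequence_id then lowest position.
    """
    n_ref = cfg.n_references(len(streams))
    hasher = EntityHasher()
    out: List[List[SecondLevelToken]] = []
    for i, entities in enumerate(streams, start=1):
        if i == 1:
            out.append(list(entities))
        else:
            out.append(_rewrite_stream(entities, hasher))
        if i <= n_ref:
            hasher.add_stream(i, list(entities))
    return out


def decode_second_level(
    token_streams: Sequence[Sequence[SecondLevelToken]],
    cfg: SecondLevelConfig = SecondLevelConfig(),
) -> List[List[MatchedEntity]]:
    """Exact inverse of :func:`match_second_level`."""
    decoded: List[List[MatchedEntity]] = []
    for i, tokens in enumerate(token_streams, start=1):
        entities: List[MatchedEntity] = []
        for tok in tokens:
            if isinstance(tok, RunTriple):
                if not 1 <= tok.sequence_id < i:
                    raise CorruptStreamError(
                        f"stream {i} references stream {tok.sequence_id}"
                    )
                ref = decoded[tok.sequence_id - 1]
                start = tok.position - 1
                if start < 0 or start + tok.run_length > len(ref):
                    raise CorruptStreamError(
                        f"triple {tok} out of bounds for stream {tok.sequence_id}"
                    )
                entities.extend(ref[start : start + tok.run_length])
            else:
                entities.append(tok)
        decoded.append(entities)
    return decoded
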
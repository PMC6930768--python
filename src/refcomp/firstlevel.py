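"""First-level matching: k-mer hash-chain index and greedy longest-match parsing.

The reference B stream is indexed with two arrays.  ``H`` has one slot per
possible k-mer value (4**k slots; bases map to 2-bit codes, so distinct
k-mers get distinct values) and holds the most recent start position of
that k-mer, or -1.  ``L`` chains each position to the previous occurrence
of the same k-mer, so following ``H[v]`` through ``L`` enumerates every
start of k-mer value ``v``, most recent first.  This is separate chaining
with the reference positions themselves as chain nodes; memory is
4 bytes/entry, i.e. 4 * 4**k bytes for H (2**30 at the default k=14).

A target B stream is parsed greedily left to right: at each position the
chain for the current k-mer is traversed in full, the longest extension
wins (ties go to the smallest reference position), and characters whose
k-mer is absent accumulate as a mismatch literal on the previous entity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_ARR = np.full(128, -1, dtype=np.int64)
for _b, _v in _CODE.items():
    _CODE_ARR[ord(_b)] = _v


class InvalidAlphabetError(ValueError):
    """A base stream contained a character outside {A,C,G,T}."""


class CorruptStreamError(ValueError):
    """An entity stream references positions outside the reference."""


@dataclass(frozen=True)
class MatchedEntity:
    """A (position, length, mismatch) triple from first-level matching.

    ``position`` is the 1-based start of the copied segment in the
    reference B stream; ``length`` its length; ``mismatch`` the literal
    bases following the copy.  ``position == length == 0`` is the
    sentinel for a leading literal with no preceding match.
    """

    position: int
    length: int
    mismatch: str = ""


def kmer_value(kmer: str, k: int) -> int:
    """Map a k-mer to its integer value in [0, 4**k) via 2-bit base codes."""
    if len(kmer) != k:
        raise ValueError(f"expected a {k}-mer, got {len(kmer)} characters")
    value = 0
    for c in kmer:
        code = _CODE.get(c)
        if code is None:
            raise InvalidAlphabetError(f"non-ACGT character {c!r}")
        value = value * 4 + code
    return value


class KmerIndex:
    """Hash-chain index of every k-mer of a reference B stream."""

    def __init__(self, B_ref: str, k: int):
        if not 1 <= k <= 15:
            raise ValueError("k must be in [1, 15]")
        self.k = k
        self.B_ref = B_ref
        self.empty = len(B_ref) < k
        if self.empty:
            warnings.warn(
                f"reference shorter than k={k}; index is empty", stacklevel=3
            )
        n_kmers = max(0, len(B_ref) - k + 1)
        self.H = np.full(4**k, -1, dtype=np.int64)
        self.L = np.full(n_kmers, -1, dtype=np.int64)
        if n_kmers == 0:
            self._codes = np.empty(0, dtype=np.int64)
            return
        codes = _CODE_ARR[np.frombuffer(B_ref.encode("ascii"), dtype=np.uint8)]
        if codes.min() < 0:
            bad = B_ref[int(np.argmin(codes))]
            raise InvalidAlphabetError(f"non-ACGT character {bad!r} in reference")
        self._codes = codes
        # Rolling k-mer values: drop the leading base with a mask, append
        # the next code; the full integer sequence is never materialized
        # beyond the per-window value array used to fill H/L in one pass.
        mask = 4**k - 1
        values = np.empty(n_kmers, dtype=np.int64)
        v = 0
        for j in range(k):
            v = (v << 2) | int(codes[j])
        values[0] = v
        for i in range(1, n_kmers):
            v = ((v << 2) | int(codes[i + k - 1])) & mask
            values[i] = v
        H, L = self.H, self.L
        for i in range(n_kmers):
            v = values[i]
            L[i] = H[v]
            H[v] = i

    def chain(self, value: int) -> List[int]:
        """All 0-based start positions of the k-mer ``value``, newest first."""
        out: List[int] = []
        p = int(self.H[value]) if not self.empty else -1
        while p != -1:
            out.append(p)
            p = int(self.L[p])
        return out


def build_kmer_index(B_ref: str, k: int) -> KmerIndex:
    """Index ``B_ref``; shorter-than-k references give an empty index."""
    return KmerIndex(B_ref, k)


def match_first_level(B_target: str, idx: KmerIndex) -> List[MatchedEntity]:
    """Greedily parse a target B stream into matched entities.

    Every match has length >= k and is maximally extended; among equal
    longest matches the smallest reference position wins.  The parse is
    lossless: :func:`decode_first_level` inverts it exactly.
    """
    k = idx.k
    ref = idx.B_ref
    n_ref = len(ref)
    n = len(B_target)
    codes = _CODE_ARR[np.frombuffer(B_target.encode("ascii"), dtype=np.uint8)]
    if n and codes.min() < 0:
        bad = B_target[int(np.argmin(codes))]
        raise InvalidAlphabetError(f"non-ACGT character {bad!r} in target")

    entities: List[MatchedEntity] = []
    cur_pos, cur_len = 0, 0  # sentinel until the first match
    literal: List[str] = []
    H, L = idx.H, idx.L
    mask = 4**k - 1
    i = 0
    v = -1  # rolling value of B_target[i:i+k]; -1 forces a rebuild
    while i < n:
        if i + k > n or idx.empty:
            literal.append(B_target[i])
            i += 1
            v = -1
            continue
        if v < 0:
            v = 0
            for j in range(i, i + k):
                v = (v << 2) | int(codes[j])
        p = int(H[v])
        if p == -1:
            literal.append(B_target[i])
            i += 1
            if i + k <= n:
                v = ((v << 2) | int(codes[i + k - 1])) & mask
            else:
                v = -1
            continue
        best_len, best_pos = 0, -1
        while p != -1:
            # hash values are injective, so the first k bases already match
            length = k
            while (
                p + length < n_ref
                and i + length < n
                and ref[p + length] == B_target[i + length]
            ):
                length += 1
            if length >= best_len:  # >= : later chain entries are earlier positions
                best_len, best_pos = length, p
            p = int(L[p])
        if cur_len > 0 or literal:
            entities.append(MatchedEntity(cur_pos, cur_len, "".join(literal)))
        cur_pos, cur_len = best_pos + 1, best_len
        literal = []
        i += best_len
        v = -1
    entities.append(MatchedEntity(cur_pos, cur_len, "".join(literal)))
    return entities


def decode_first_level(entities: List[MatchedEntity], B_ref: str) -> str:
    """Invert the first-level parse by expanding copies and literals."""
    out: List[str] = []
    n_ref = len(B_ref)
    for e in entities:
        if e.length > 0:
            start = e.position - 1
            if start < 0 or start + e.length > n_ref:
                raise CorruptStreamError(
                    f"entity ({e.position}, {e.length}) out of reference bounds"
                )
            out.append(B_ref[start : start + e.length])
        out.append(e.mismatch)
    return "".join(out)
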
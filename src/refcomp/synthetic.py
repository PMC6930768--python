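"""Seeded synthetic FASTA collections with resequencing structure.

The generator emulates the statistical structure a referential
compressor exploits: a collection of targets that are near-copies of one
reference, differing by SNPs and short indels, with soft-masked
(lowercase) runs, N runs from assembly gaps, rare non-ACGTN symbols and
a fixed line width.  It does not attempt biological realism (no
transition/transversion bias, no coalescent sharing of variants); it is
a workload model, not a population model.

All randomness is derived from ``numpy.random.default_rng`` seeded with
``(seed, file_index)``, so a collection is reproducible file by file
regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

_BASES = np.array(list("ACGT"))
_SPECIALS = np.array(list("RYKMSW"))  # IUPAC ambiguity codes


@dataclass(frozen=True)
class MutationConfig:
    """Rates and layout for synthetic references and mutated targets.

    Rates are per-base probabilities; run lengths are geometric.
    Defaults model a resequenced eukaryote assembly: ~0.1% SNPs, rarer
    short indels, soft-masked repeat runs covering a large fraction of
    the sequence, occasional assembly-gap N runs and very rare IUPAC
    ambiguity codes.
    """

    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    case_flip_rate: float = 5e-3
    n_run_rate: float = 1e-4
    special_rate: float = 1e-5
    indel_max_len: int = 10
    mean_case_run: int = 100
    mean_n_run: int = 50
    line_width: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "case_flip_rate",
                     "n_run_rate", "special_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _rng(cfg: MutationConfig, file_index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, file_index])


def _wrap(identifier: str, seq: str, width: int) -> str:
    lines = [seq[i : i + width] for i in range(0, len(seq), width)] or [""]
    return ">" + identifier + "\n" + "\n".join(lines) + "\n"


def _inject_runs(chars: np.ndarray, rng, rate: float, mean_len: int,
                 kind: str) -> None:
    """Overwrite (N) or lowercase (case) geometric-length runs in place."""
    n = len(chars)
    starts = np.flatnonzero(rng.random(n) < rate)
    for s in starts:
        length = 1 + rng.geometric(1.0 / mean_len) if mean_len > 1 else 1
        end = min(n, s + length)
        if kind == "N":
            chars[s:end] = "N"
        else:
            chars[s:end] = np.char.lower(chars[s:end])


def generate_reference(
    length: int, cfg: MutationConfig, identifier: str = "ref", file_index: int = 0
) -> str:
    """One seeded FASTA record of uniform ACGT with case/N run structure."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = _rng(cfg, file_index)
    chars = _BASES[rng.integers(0, 4, size=length)].copy()
    _inject_runs(chars, rng, cfg.n_run_rate, cfg.mean_n_run, "N")
    _inject_runs(chars, rng, cfg.case_flip_rate, cfg.mean_case_run, "case")
    return _wrap(identifier, "".join(chars), cfg.line_width)


def mutate(
    reference_text: str,
    cfg: MutationConfig,
    identifier: str | None = None,
    file_index: int = 1,
) -> str:
    """Derive a target FASTA from a reference by seeded mutation.

    Applies SNPs, short indels (length uniform in [1, indel_max_len]),
    case-run flips, N-run insertions and special-character substitutions
    at the configured per-base rates.  With all rates zero (and the
    header identifier left as the reference's) the target is a
    byte-identical copy.
    """
    rng = _rng(cfg, file_index)
    lines = reference_text.replace("\r\n", "\n").split("\n")
    if identifier is None:
        identifier = lines[0][1:]
    seq = "".join(ln for ln in lines[1:] if ln)
    out: List[str] = []
    i = 0
    n = len(seq)
    while i < n:
        r = rng.random()
        c = seq[i]
        if r < cfg.indel_rate:
            length = int(rng.integers(1, cfg.indel_max_len + 1))
            if rng.random() < 0.5:
                i += length  # deletion
            else:
                out.append("".join(_BASES[rng.integers(0, 4, size=length)]))
            continue
        if r < cfg.indel_rate + cfg.snp_rate and c.upper() in "ACGT":
            sub = _BASES[int(rng.integers(0, 4))]
            out.append(sub.lower() if c.islower() else sub)
        elif r < cfg.indel_rate + cfg.snp_rate + cfg.special_rate:
            out.append(str(_SPECIALS[int(rng.integers(0, len(_SPECIALS)))]))
        else:
            out.append(c)
        i += 1
    chars = np.array(list("".join(out))) if out else np.array([], dtype="<U1")
    if len(chars):
        _inject_runs(chars, rng, cfg.n_run_rate, cfg.mean_n_run, "N")
        _inject_runs(chars, rng, cfg.case_flip_rate, cfg.mean_case_run, "case")
    return _wrap(identifier, "".join(chars), cfg.line_width)


def generate_collection(
    length: int, n_targets: int, cfg: MutationConfig
):
    """A (reference_text, [target_texts]) pair for round-trip testing."""
    ref = generate_reference(length, cfg, identifier="ref", file_index=0)
    targets = [
        mutate(ref, cfg, identifier=f"target_{j}", file_index=j)
        for j in range(1, n_targets + 1)
    ]
    return ref, targets
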
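# Methods

## The compression model

`refcomp` treats a FASTA genome file as five independent information
sources and compresses each with a scheme matched to its statistics.

1. **Base stream B.** The sequence with line breaks removed, case
   folded to upper, and `N`/special characters deleted. For a
   resequenced target, B is a near-copy of the reference's B, so it is
   represented as a copy/literal factorization against the reference
   (first level) and, in collections, as runs of identical factors
   copied from earlier targets (second level).
2. **Lowercase runs.** Soft-masking annotation, stored as
   `(gap, length)` tuples on the concatenated sequence. Masking is
   highly conserved between assemblies of the same species, so target
   tuples are looked up in the reference's tuple array and hits stored
   as 1-based indices, compacted by tolerance-1 RLE (a run is a maximal
   arithmetic progression with difference +1). Misses go verbatim to a
   literal array; a per-tuple flag bit records which path was taken.
3. **N runs and special characters.** Stored gap-encoded but not
   matched: they are rare enough that matching machinery would cost
   more than it saves. Special symbols are entropy coded with a
   canonical prefix (Huffman) code built from their frequencies; a
   single-symbol alphabet spends one bit per symbol.
4. **Identifier and line widths.** Run-length encoded. Widths are
   stored per line, so ragged final lines and blank-line-free files of
   any width reconstruct exactly.
5. **Layout metadata.** One byte per target records newline style
   (LF/CRLF) and whether the file ends with a newline, making the
   round-trip byte-exact rather than merely sequence-exact.

Coordinates: all run/character positions are 0-based on the
concatenated sequence, before `N`/special removal; gap encoding stores
each item's distance from the end of its predecessor. Lowercase
extraction precedes removal, so a lowercase `n` appears in both the
lowercase and N streams, and a lowercase special character contributes
its position to the lowercase runs with its symbol case-folded.

## First-level matching

The reference B stream is indexed by k-mer with two arrays. Bases map
to 2-bit codes, a k-mer to the base-4 value of its code string —
injective, so equal values mean equal k-mers. `H` (length 4^k,
initialized to −1) holds the most recent start position per value; `L`
(length |B|−k+1) chains each position to the previous occurrence:
`L[i] = H[v_i]; H[v_i] = i`. Values are updated by a rolling shift-mask
per window rather than converting the whole sequence to integers.

Parsing is greedy: at target position *i* the chain for the current
k-mer is traversed completely; each candidate is extended by direct
comparison and the longest extension wins. The chain is ordered most
recent first, so a `>=` comparison during traversal leaves the
*smallest* reference position as the winner among ties — fixed for
determinism. A position whose k-mer is absent contributes one literal
character to the pending entity's mismatch; the final < k characters of
a target can never seed a window and always end up as literal. Emitted
entities are `(position, length, mismatch)` with 1-based positions;
a leading literal with no preceding match uses the `(0, 0, ...)`
sentinel.

Defaults: k = 14 balances chain length against index memory
(4·4^14 = 2^30 bytes for H); the CLI accepts k in [1, 15]. Tests use
k ≤ 12 so fixtures stay small.

## Second-level matching

Entity streams are re-matched across the collection. An entity hashes
by mixing position, length and each mismatch base with two large prime
multipliers (1000000007, 998244353) into a 2^20-bucket table with
separate chaining; distinct entities can collide, so every candidate is
verified by full equality before use. For target *i* the references are
the *first-level* streams of targets *j < i* within the reference set —
the first `max(1, floor(p/100 · N))` targets (default p = 10; the
worked-example tests use p = 100 so every prior target is eligible).
A maximal run of ≥ 2 identical entities is replaced by
`(sequence_id, position, run_length)`; the longest run wins, ties break
to lowest sequence id then lowest position; runs of length 1 stay raw,
which is what makes the rewritten streams reproduce the worked
example's printed output. Decoding replays triples against the
already-decoded first-level streams of earlier targets, so it is a
strict inverse.

## Encoding choices

* Positions of raw entities are predicted as
  `prev_position + prev_length + |prev_mismatch|`; including the
  literal length means an SNP-only target predicts exactly and encodes
  zero deltas. Deltas are zigzag-mapped, then everything is LEB128
  varint serialized. Run triples interleave with raw entities; the
  prediction state advances over raw entities only.
* The archive is: magic `RGCA`, version, backend id, then a
  backend-compressed body holding k, p, mode, a CRC32 of the reference
  B stream, and per-target sections in fixed order (layout flags,
  identifier RLE, width RLE, lowercase flags/RLE/literals, N runs,
  special code table + bitstream + gaps, token stream). The checksum
  makes decompression with the wrong reference fail early instead of
  producing garbage.
* Backends: `store`, `lzma` (default), `zlib`, `bz2` — all exact
  inverse pairs behind one id-dispatched interface. Compressed sizes
  are therefore an implementation property; the contract is
  losslessness and determinism (same inputs and configuration give
  identical archive bytes), not size parity with any other tool.
* Gain metric: `100 × (1 − size_A / size_B)`, reported to two decimals.

## Decompression

Backend-decode, deserialize, re-extract the reference's B and lowercase
runs, verify the checksum, decode second- then first-level matches,
then rebuild each file: place `N` runs and special characters at their
absolute positions, interleave the B characters into the remaining
slots, lowercase the positions covered by lowercase runs, split by the
stored line widths and prepend the `>` header. Time and memory are
linear in the total output size.

## Synthetic data generator

The generator emulates the workload the method is built for: a
collection of targets derived from one reference by per-base SNPs
(default rate 1e-3, the order of human inter-individual divergence),
short indels (1e-4, lengths uniform in [1, 10]), lowercase-run starts
(5e-3, geometric lengths of mean 100, emulating soft-masked repeats),
N-run starts (1e-4, mean 50, emulating assembly gaps), IUPAC ambiguity
substitutions (1e-5) and a 60-column line width. Each file draws from
`numpy.random.default_rng([seed, file_index])`, so collections are
reproducible file by file.

What it does *not* model: transition/transversion bias, mutation
hotspots, structural variants, shared population haplotypes (each
target mutates independently unless targets are derived from a common
mutated base), or real soft-masking geometry. Passing round-trip tests
therefore demonstrates losslessness and the machinery's correctness on
realistically structured inputs, not compression-ratio parity with real
genome corpora.

## Numerical and degenerate-input choices

* A reference shorter than k yields an empty index with a warning;
  every target then parses as pure literal and still round-trips.
* Greedy parsing at realistic scales emits a small residue of spurious
  ~k-length matches — a k-mer spanning a substituted base occasionally
  recurs by chance in a 100 kb reference — so the predictive delta
  stream is overwhelmingly but not entirely zero (measured 659/673
  zeros at SNP rate 0.01, k = 12, 100 kb).
* Lowercase tuple matching scans the whole reference array, first
  occurrence wins; no locality window is imposed.
* Multi-record FASTA files are rejected explicitly (one chromosome per
  file); any byte is accepted inside sequence lines.

## Problem sizes in the test suite

Fixtures are generated at 3–100 kb with 1–10 targets and k in [2, 12],
which exercises every code path (chains with collisions, multi-run
second-level rewrites, all side streams) while the whole suite runs in
seconds; the index arrays scale as 4^k, and nothing in the
implementation branches on input size beyond that.
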
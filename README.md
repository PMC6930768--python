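# refcomp

Lossless referential compression of FASTA genome collections.

Resequenced genomes are nearly identical to their reference: the
differences are dominated by SNPs, short indels and bookkeeping
structure (soft-masked lowercase runs, assembly-gap `N` runs, rare IUPAC
ambiguity codes, a fixed line width). `refcomp` exploits this twice.
First each target's base stream is parsed into copy/literal entities
against a reference via a k-mer hash-chain index; then, for a
collection, runs of identical entities are re-matched *across* targets,
so shared variants are stored once. Every side stream is preserved, and
decompression restores each input file byte-for-byte.

## Method

**Extraction.** A record is split into the basic base stream
*B* ∈ {A,C,G,T}\* plus side streams: lowercase runs, N runs and special
characters as gap-encoded `(gap, length)` / `(gap, symbol)` tuples on
the concatenated sequence, the header identifier, and per-line widths.

**First-level matching.** The reference *B* is indexed with arrays *H*
and *L*: bases code to 2 bits, so a k-mer maps injectively to a value
*v* ∈ [0, 4^k); insertion is `L[i] = H[v_i]; H[v_i] = i`, giving
separate chains of all occurrences (|H| = 4^k entries, 4 bytes each —
2^30 B at the default k = 14). The target is parsed greedily left to
right: at each position the chain of the current k-mer is traversed in
full, the longest extension wins (smallest reference position on ties),
and unmatched bases accumulate as mismatch literals, yielding
`(position, length, mismatch)` entities.

**Second-level matching.** For target *i*, maximal runs (length ≥ 2) of
entities identical to a run in an earlier target's entity stream become
`(sequence_id, position, run_length)` triples; the longest run wins.
Only the first *p*% of targets (at least one) are indexed as references,
bounding memory on large collections.

**Encoding.** Entity positions use predictive incremental coding — the
next position is predicted as previous position + length + literal
length, so SNP-only targets encode as near-all-zero deltas. Identifiers
and line widths are run-length encoded; lowercase runs are matched
against the reference's runs and their indices compacted with
tolerance-1 RLE; special characters get a canonical static prefix code.
Everything is varint/zigzag serialized and wrapped by a pluggable
backend compressor (LZMA by default; zlib, bz2, store). The gain metric
compares two sizes as `100 × (1 − A/B)` %.

## Worked example

```sh
$ refcomp synth -o demo --length 100000 --n-targets 3 --seed 7
wrote 1 reference + 3 target(s) to demo
$ refcomp compress -r demo/ref.fa -t demo/target_1.fa -t demo/target_2.fa \
    -t demo/target_3.fa -o demo/coll.rgc -k 12 -p 100
3 target(s), 305077 -> 3712 bytes (mode=batch, k=12, p=100, backend=lzma, gain vs raw 98.78%)
$ refcomp decompress -r demo/ref.fa -a demo/coll.rgc -o demo/restored
restored 3 file(s) to demo/restored
$ cmp demo/target_2.fa demo/restored/target_2.fa && echo IDENTICAL
IDENTICAL
```

Three 100 kb synthetic resequenced targets (305,077 bytes of FASTA)
compress to a 3,712-byte archive — a 98.78 % reduction relative to the
raw files — and decompress byte-identically given the same reference.
`refcomp gain 80.13 103.62` prints `22.67`, the percent size reduction
of an 80.13 MB archive versus a 103.62 MB one.

The same operations are available as a library:

```python
from refcomp import compress_collection, decompress_archive

archive = compress_collection(ref_text, [t1_text, t2_text], k=12, p=100)
assert decompress_archive(archive, ref_text) == [t1_text, t2_text]
```

## Limitations

One sequence record per FASTA file; nucleotide alphabets only; inputs
are held in memory (no streaming); no reverse-complement matching; no
random access into archives.
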
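# Methods

## Problem and representation

The compressor operates on a multiset `R` of `N` reads, each a string of
fixed length `L` over {A, C, G, T, N}. Read order and identifiers carry no
information and are discarded; decompression returns the multiset (as FASTA
with generated identifiers) in an unspecified order.

Distinct reads become nodes of a *read forest*: a directed graph in which
each node has at most one outgoing edge to its parent, a read whose suffix
covers the node's prefix with overlap at least `K`. Edge weight is
`L − overlap`; roots weigh `L`. Because out-degree is ≤ 1, every connected
component is a trie rooted at either a single node or a single cycle
("cycle-rooted trie"). The total weight equals the number of consensus
symbols the archive stores, so minimizing it minimizes the dominant stream.

## Greedy construction and its optimality

Reads are processed in input order. For each distinct read:

1. **Parent search** — a window of length `K` slides right-to-left across
   the read; each window queries a hash table of all stored read *suffixes*
   of length `K`. A hit is an exact seed; the remaining overlap positions
   are verified with at most `eps` mismatches. The first validated hit is
   the longest possible overlap and becomes the parent.
2. **Children search** — the window slides left-to-right, querying the
   *prefix* table; any existing node that the new read covers strictly
   better than its current parent is re-parented (roots count as weight
   `L`). Windows are visited best-first, so each candidate is reassigned at
   most once per insertion.
3. The read's K-prefix and K-suffix are inserted into the tables.

With `eps = 0` the final weight of every node equals `rep(v)`, its minimum
achievable weight over all other reads, so the greedy forest attains the
lower bound `Σ rep(v)` — no read forest with the same `K` can be smaller,
and the forest never stores more symbols than the shortest common
superstring of the reads. Both properties are asserted in the suite against
two independent brute-force oracles (naive all-pairs scanning, and
per-overlap-length sorted-array matching for large instances), plus exact
shortest-superstring enumeration for up to 7 reads. With `eps > 0` the
proof's premise (error-free reads) fails and no optimality is claimed.

Ties among equal-overlap parents go to the earliest-inserted node; hash
tables are keyed by the K-mer string itself, so collisions cannot create
false matches. Overlaps are capped at `L − 1`: with `eps > 0` a distinct
read could otherwise fully overlap another (weight 0), which would leave
nothing to anchor it in the consensus; requiring one new symbol per node
keeps all differential codes in `[1, L]` at a cost of at most one symbol
per such read. With `eps = 0` and deduplicated reads, full overlaps cannot
occur and the cap is vacuous.

**Duplicates** collapse into one node with a multiplicity; **N symbols**
are substituted by the placeholder base `A` for matching, with true
positions recorded per stored copy and restored on decode. **Strand
correction** (optional) runs the parent search for both orientations and
commits the read to the one with the longer validated overlap; the
orientation never changes afterwards, even if the parent is later
reassigned. Since a read and its reverse complement can then collapse onto
the same stored string while needing different output orientations,
orientation flags (and N positions) are tracked per stored copy, not per
node.

## Container format

The forest is decomposed into *contigs*. Cycles are detected first and
emitted as cycle contigs; each remaining node is covered by a leaf-to-root
walk that stops at the first already-claimed node, so every parent-contig
pointer refers to an earlier contig. Per contig the archive stores: a
cycle flag; a parent-contig pointer (Elias gamma) with a parent-read index
(`⌈log2 n⌉` bits, `n` = reads in the parent contig); per-read differential
codes — each read's edge weight, whose sum is exactly the contig's
consensus length — under a fixed-codebook canonical Huffman code; and
per-read mismatch records (gamma count, `⌈log2 L⌉`-bit offset, 2-bit base).

The Huffman codebook over `{1..L}` is built from a truncated geometric
weight profile `P(d) ∝ 0.85^(d−1)` (small deltas dominate at useful
coverage) with deterministic tie-breaking, so encoder and decoder derive
identical codes from `L` alone and no codebook is transmitted.

Reads are reconstructed root-to-leaf: each read borrows its covered prefix
from its parent's already-reconstructed string and appends its own
consensus symbols, then applies its mismatch records — so tree-contig error
records are exactly the ≤ `eps` seed-extension mismatches. Cycle contigs
store one turn of the circular consensus (length = sum of cycle weights)
and reads are gathered modulo that length; their error records are taken
against the gathered string and may exceed `eps` through chaining, which
affects size only, never decodability.

Roots with no children bypass the contig machinery: they are stored as raw
2-bit reads in a separate singleton stream. Global streams carry
multiplicities (gamma), per-copy orientation bits (present only when strand
correction was on), and per-copy N positions as (copy-index delta, offset)
pairs. Consensus and singleton streams are 2-bit packed and then passed
through DEFLATE at level 9 (recorded by the format version). The container
is little-endian, magic `ATRF`, with length-prefixed streams; all offsets
are 0-based. Encoding is fully deterministic: identical input and
parameters give byte-identical archives.

Defaults: `K = ⌊L/5⌋` (at least 1), `eps = 2`, strand correction off.
Larger `K` accelerates search but misses overlaps; `eps` trades mismatch
records against longer overlaps on noisy data.

## Entropy approximation

For reads sampled independently and uniformly from a genome `G` and
corrupted by i.i.d. substitutions at rate `p` (uniform over the three other
bases), the read-set entropy decomposes into error, sampling, and genome
terms:

```
H(R) ≈ N·L·log2(3)·h2(p) + |G|·H(Poisson(N/|G|)) + LZ(G)
```

`h2` is the binary entropy; the Poisson term models per-position read
counts at mean coverage `N/|G|`; `LZ(G)` is the DEFLATE (level 9)
description length of `G`. The two remaining conditional terms of the exact
chain-rule decomposition, `H(G|R)` and `H(R*|G,R)`, are negligible at
realistic coverage and are treated as zero. The Poisson entropy series is
truncated once the tail can contribute < 1e−12 bits, far below the
3-decimal reporting precision; per-base values divide every term by `N·L`.

**Caveat.** The approximation is a modeling bound, not a strict one: on
*uniform random* genomes DEFLATE needs ≈ 2.37 bits/base while the true
genome entropy is 2.0, inflating the `LZ(G)` term by ≈ 18%. At low error
rates and moderate coverage (e.g. error-free reads at 20×, 100 kb genome)
the compressor can therefore land slightly *below* the approximation
(measured: 0.1545 vs 0.1571 bits/base); at 40× and above, or at any
realistic error rate, the achieved rate sits above it, and the gap grows
with `p` because errors break the exact K-mer seeds.

## Synthetic data

The generator produces exactly the model above: uniform i.i.d. genomes,
read starts uniform on `[0, |G| − L]` (linear genome; the edge effect is
negligible for `|G| ≫ L`), i.i.d. substitutions, and independent strand
flips, all driven by a single seeded numpy PCG64 generator for bitwise
reproducibility. It deliberately omits position-dependent error profiles,
indels, genomic repeats, and paired-end structure — so passing tests
certify the combinatorial and coding machinery under the stated model, not
performance on real instrument data, where repeat content and error
structure shift both the achieved rate and the entropy terms.

Test problem sizes were chosen to exercise the asymptotic regime while
keeping the suite quick: optimality is certified on 200 randomized
instances (genomes 2–20 kb, L ∈ {20, 50, 100}, coverage 2–20×), the
superstring bound on 500 instances of ≤ 7 reads, and losslessness on a
parameter grid up to 50,000 reads of length 100 from a 100 kb genome,
with N symbols, duplicates, strand flips, and 1% errors.

## Known limitations

* Encoding holds the whole forest in memory (`Ω(N·L)`), like the prefix and
  suffix tables it needs; there is no streaming mode or random access.
* Variable-length reads are rejected — the model is defined for fixed `L` —
  and characters outside {A, C, G, T, N} are hard errors.
* Quality scores and read identifiers are not preserved.
* With `eps > 0`, compression quality (never correctness) depends on input
  order, since mismatch-tolerant overlaps are not order-symmetric.
* The strand-correction heuristic is greedy and commits early; reads whose
  best overlap appears only later keep their initial orientation.
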
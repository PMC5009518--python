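# Methods

## Index

The read set `R` (n reads, uniform length m, bases A/C/G/T after
preprocessing) is indexed as two Burrows–Wheeler transforms: of the
reads and of the reversed reads. Each read carries its own sentinel,
with the sentinel of read *i* ordering before that of read *j* for
`i < j`; suffixes are sorted by plain byte comparison with read-ID
tie-breaks, which realises exactly that order for equal-length reads.
Construction sorts all `n*(m+1)` suffix slices — O(n m² log nm) in
the worst case but simple, exact and fast at the scales this package
targets (up to a few hundred thousand reads). Each BWT symbol packs a
3-bit base/sentinel code and one flag bit recording whether the
base's Phred score met the quality cutoff at build time; rank support
is a full cumulative occurrence table (int64, five rows).

For a pattern `P` the index tracks four half-open intervals: `P` in
the forward index, `reverse(P)` in the reversed index (the classic
synchronized pair), plus `RC(P)` in the forward index and
`complement(P)` (= `RC(P)` read backwards) in the reversed index.
The first and last pairs each support constant-work extension on
either end via the smaller-symbol counting trick; the exposed triple
(`fwd`, `rc`, `rev`) matches the assembler's contract and

```
Dep(P) = |fwd interval| + |rev interval|
```

counts occurrences of `P` plus `RC(P)` over all reads with
multiplicity. Reads having `P` as a prefix (either orientation) are
found by locating sentinel symbols inside the intervals and mapping
them through the sentinel↔read-ID tables; read recovery walks m LF
steps from the read's sentinel rank.

N bases in input FASTQ are replaced by a deterministic pseudo-random
base (keyed on record name and position) at quality 0; pairs with more
than 10% N are dropped.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `d` | required | expected genome coverage (fold); estimable from distinct k-mers |
| `m` | from reads | uniform read length (bases) |
| `z` | 1.5 | inferred-unique ceiling multiplier on `d_k = (m-k+1)·d/m` |
| `tau` | 4 | minimum support depth (reads) for seeds, branch survival and paired-end votes |
| `quality_cutoff` | 20 | Phred threshold for the per-base high-quality bit |
| `min_seed_len` | 31 | shortest seed window; ~log₄(genome) is the uniqueness floor |
| `sig_ratio` | 4.0 | the single dominance ratio standing in for "significantly larger" in branch verdicts |
| `het_similarity` | 0.9 | branch sub-consensus identity floor for a heterozygous merge |
| `insert_mean`, `insert_sd` | 500, 50 | paired-end insert size model (bases) |
| `min_contig_len` | 2·m | output length floor |
| `repeat_seed_relax` | 3.0 | ceiling relaxation for continuation seeds inside repeats |

## Seed selection

Windows of the text are scanned with decreasing start and fixed end
(incremental backward extension). The first window of length
`k ≥ min_seed_len` with `0 < Dep ≤ z·d_k` is returned provided all its
bases carry the high-quality bit; when depth collapses below `tau`
the scan restarts left of the collapse, and a low-quality base inside
a qualifying window restarts the scan left of that base. Seeds found
in a read open new contigs; seeds found in the already-extended
consensus continue one. Continuation seeds are searched in windows of
escalating right end (from `2·min_seed_len` up to `m−1`, in ~8 bp
steps) so they sit as close to the assembly frontier as possible —
a seed far from the frontier leaves the extension tree no headroom.
When no strict seed exists in any window (the frontier lies inside a
repeat, where depth is a multiple of the single-copy expectation),
the scan retries with the ceiling relaxed by `repeat_seed_relax`;
reverse validation and paired-end evidence police the resulting walk.
Without this fallback no repeat longer than `m − min_seed_len` could
ever be crossed, because an extension tree rooted outside the repeat
cannot reach its far edge.

## Reverse validation

At a fork the depths of `t_x + C[0..i]` are recomputed left to right
for both children (`C` is the node's label continued into the
already-assembled consensus, capped at `m−1` so patterns never exceed
the read length — the extra right context is what lets a chimeric
repeat branch run into discriminating sequence). Candidate `x` is

* **erroneous** at the first `i` with `0 < Dep < tau` where the
  previous step, the sibling and the expected depth `d_{i+2}` are all
  `sig_ratio`-fold larger;
* **repetitive** when `Dep` hits zero under the analogous dominance
  conditions (the seed is flagged as a false-positive unique);
* otherwise the **heterozygosity** test compares greedy max-weight
  sub-consensuses of the two children, truncated to their common
  length (length mismatch is depth exhaustion, not allelic
  divergence): a merge requires identity ≥ `het_similarity` over at
  least 8 aligned bases and a weight split consistent with two
  alleles, assessed by an exact binomial test against 50/50 at
  α = 0.01 on the fork children's weights (labels of equal length, so
  weights are directly comparable). The heavier allele survives.
  The α is the conventional significance level: splits like 16/8 or
  12/5 are Binomial-plausible allele pairs, while error forks
  (≈15 vs 1–2) are rejected by orders of magnitude.

With more than two children, every lighter child is first tested for
the erroneous/repetitive cases against the heaviest; if more than two
survive the walk stops.

Reads terminating inside a branch removed as erroneous, or inside the
losing allele of a heterozygous merge, are consumed by the contig:
both are explained by this locus, and leaving them unmarked would
re-seed the same region once per leftover read. Repetitive and
paired-end losers keep their reads — they belong to another locus.

## Paired-end resolution

A fork that reverse validation leaves ambiguous is put to a
mate-pair vote. Each candidate branch is projected up to
`insert_mean + 3·insert_sd` bases past the fork by greedy single-base
extension of a sliding pattern window (about `2·min_seed_len` long,
rebuilt before it reaches the read length). Reads beginning on the
projection vote for the branch when their mate is already placed in
the contig with opposite orientation and an outer span within
`insert_mean ± 3·insert_sd` — the span test is symmetric in the two
mates rather than demanding forward-on-the-left, so that assembly of
the reverse-complemented read set behaves identically. A vote counts
only if the voting read verifiably covers a position where the two
projections differ; on sequence the branches share, reads carry no
information about which branch is real. The fork is resolved only
when exactly one side reaches `tau` votes.

Read placements used by the vote are recorded as the walk crosses
each read's start — but only where the anchoring label is itself
inferred-unique: inside a repeat the same label matches every copy
and a placement would be meaningless.

## Whole-assembly orchestration

Initial reads are visited in ascending ID; marked reads and reads
yielding no seed are skipped (every read initiates at most one
extension). A contig grows leftward in rounds of
seed → tree → walk, accepting a round only if it nets new bases, then
the reverse complement is extended the same way. A round that meets
eight or more reads claimed by other contigs while claiming none of
its own is walking over already-assembled territory and stops.
Output suppresses contigs below `min_contig_len` and contigs wholly
contained (either strand) in a longer one — re-walks started from
leftover erroneous reads of an already-claimed locus. FASTA output is
80-column wrapped, ordered by initiating read, and byte-deterministic.

## Synthetic data

The generator emulates uniform-coverage paired-end sequencing of a
random genome: fragment starts are stratified uniformly (evenly
spaced) so realized coverage is flat to the sequence ends, with
random strand, Gaussian insert length, substitution-only errors
(erroneous bases get the low Phred score of the quality model) and
optional planted features — exact or diverged repeat families at
recorded coordinates, and heterozygous SNPs on a second haplotype in
diploid mode. Every read records its true placement, haplotype and
error offsets for test oracles. What it does **not** model: indels,
instrument-specific quality profiles, coverage bias (GC or otherwise),
PCR duplicates, chimeras, or adapter contamination; passing tests on
this generator demonstrate the algorithmic contracts, not performance
on any particular instrument's artefacts.

## Evaluation

Contigs are aligned to the truth on both strands with infix
edit-distance alignment (edlib); a contig counts as aligned at ≥ 90%
identity. Coverage is the union of aligned truth intervals;
mismatch/indel rates come from the alignment operations; N50 is the
standard half-total length. This is a desk-scale evaluator for truth
genomes up to ~1 Mb, not a seeded long-read mapper.

## Problem sizes and numerical choices

The test-suite and acceptance scenarios use 12–20 kb genomes at
30–40× coverage with 100–250 bp reads — large enough that seeds are
overwhelmingly genome-unique and every decision path (error, repeat,
heterozygous, paired-end) is exercised, small enough to run the whole
suite in a few minutes on one CPU. Coordinates are 0-based half-open
throughout; empty SA intervals are canonicalized to (0, 0); ties in
greedy descents and child ordering break on the smaller base code, so
all outputs are deterministic given inputs and parameters.

## Known limitations

* Uniform read length is assumed; variable-length input is rejected.
* Suffix sorting is in-memory and quadratic-ish in m for pathological
  inputs; fine at desk scale, not for a lane of HiSeq.
* Quality flags inform seed selection only; branch classification
  relies on depth profiles alone.
* A fork whose branches differ only beyond one insert length cannot
  be resolved and ends the contig; there is no scaffolding pass.
* Heterozygous regions emit one allele (the heavier); the losing
  allele's reads are consumed, so no alternate-allele contig is
  produced.
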
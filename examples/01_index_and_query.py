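"""Build a bidirectional BWT of a few reads and query pattern depths.

The depth of a pattern counts its occurrences and those of its reverse
complement across all reads -- the assembler's proxy for how much
sequencing coverage supports a stretch of sequence.
"""

from adaseed import ReadSet, build_index

reads = ReadSet.from_strings([
    "ACGTACGGTCA",
    "CGTACGGTCAT",
    "GTACGGTCATT",
    "TGACCGTACGT",  # reverse complement of read 0
])
index = build_index(reads, quality_cutoff=20)

for pattern in ("ACGGTCA", "TACG", "GGGGG"):
    isr = index.isr_of(pattern)
    print(f"depth({pattern!r}) = {isr.depth}")
# ACGGTCA occurs in reads 0-2 plus once on the reverse strand -> 4;
# GGGGG occurs nowhere -> 0.

print("reads with prefix 'ACGT':", index.reads_with_prefix(index.isr_of("ACGT")))
# (0, False): read 0 starts with it; (3, True): read 3's reverse
# complement starts with it.

seq, hq = index.recover_read(1)
print("read 1 recovered from the BWT:", seq, "| high-quality bases:", int(hq.sum()))
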
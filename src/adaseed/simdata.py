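"""Synthetic genomes and paired-end read sets with known truth.

The generator emulates, at desk scale, the kind of data the assembler
targets: a haploid or diploid genome with optional planted repeats,
uniform-coverage innie read pairs with Gaussian insert sizes, and
substitution-only sequencing errors.  Every planted feature (repeat
copies, heterozygous sites, per-read placement and error positions) is
recorded so tests can check assembler decisions against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dna
from .readset import ReadSet


@dataclass
class SimSpec:
    genome_len: int = 20_000
    rng_seed: int = 1
    # (unit length, copy number, divergence fraction) per repeat family
    repeats: list[tuple[int, int, float]] = field(default_factory=list)
    het_rate: float = 0.0          # SNPs per base; > 0 switches on diploid mode
    read_len: int = 100
    depth: float = 30.0            # fold coverage d
    err_rate: float = 0.0          # substitutions per base
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    qual_model: tuple[int, int, float] = (40, 2, 0.0)  # (high Q, low Q, low-Q fraction)

    def __post_init__(self) -> None:
        for r in (self.het_rate, self.err_rate, self.qual_model[2]):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for unit, copies, divg in self.repeats:
            if unit * copies > self.genome_len:
                raise ValueError("planted repeats exceed the genome length")
            if not 0 <= divg <= 1:
                raise ValueError("repeat divergence must lie in [0, 1]")
        if self.read_len > self.genome_len:
            raise ValueError("read length exceeds genome length")
        if self.insert_mean < 2 * self.read_len:
            warnings.warn("insert mean shorter than two read lengths; "
                          "mates will overlap", stacklevel=2)


@dataclass
class GenomeTruth:
    hap1: str
    hap2: str | None                       # None in haploid mode
    repeat_copies: list[list[int]]         # per family: start of each copy
    repeat_units: list[int]                # per family: unit length
    het_sites: list[tuple[int, str, str]]  # (position, hap1 base, hap2 base)

    @property
    def diploid(self) -> bool:
        return self.hap2 is not None


@dataclass
class ReadTruth:
    """Genome placement of each simulated read, parallel to read IDs."""

    start: np.ndarray      # leftmost genome coordinate of the read
    is_rc: np.ndarray      # True when the read is the reverse strand
    hap: np.ndarray        # 0 or 1
    errors: list[list[int]]  # per read: offsets (in read coords) of planted errors


def simulate_genome(spec: SimSpec) -> GenomeTruth:
    """Random genome with planted repeats; diploid mode plants
    heterozygous SNPs at ``het_rate`` per base."""
    rng = np.random.default_rng(spec.rng_seed)
    g = rng.integers(1, 5, size=spec.genome_len, dtype=np.uint8)

    repeat_copies: list[list[int]] = []
    repeat_units: list[int] = []
    taken: list[tuple[int, int]] = []

    def free_slot(unit: int) -> int:
        for _ in range(1000):
            s = int(rng.integers(0, spec.genome_len - unit + 1))
            if all(s + unit <= lo or s >= hi for lo, hi in taken):
                taken.append((s, s + unit))
                return s
        raise ValueError("could not place repeat copies without overlap")

    for unit, copies, divg in spec.repeats:
        src = free_slot(unit)
        starts = [src]
        template = g[src : src + unit].copy()
        for _ in range(copies - 1):
            dst = free_slot(unit)
            copy = template.copy()
            if divg > 0:
                nmut = rng.binomial(unit, divg)
                for p in rng.choice(unit, size=nmut, replace=False):
                    copy[p] = 1 + (copy[p] - 1 + rng.integers(1, 4)) % 4
            g[dst : dst + unit] = copy
            starts.append(dst)
        repeat_copies.append(sorted(starts))
        repeat_units.append(unit)

    hap1 = dna.decode(g)
    hap2 = None
    het_sites: list[tuple[int, str, str]] = []
    if spec.het_rate > 0:
        g2 = g.copy()
        positions = np.flatnonzero(rng.random(spec.genome_len) < spec.het_rate)
        for p in positions:
            alt = 1 + (g2[p] - 1 + rng.integers(1, 4)) % 4
            het_sites.append((int(p), dna._CHAR_OF[g[p]], dna._CHAR_OF[alt]))
            g2[p] = alt
        hap2 = dna.decode(g2)
    return GenomeTruth(hap1, hap2, repeat_copies, repeat_units, het_sites)


def simulate_reads(genome: GenomeTruth, spec: SimSpec) -> tuple[ReadSet, ReadTruth]:
    """Uniform-coverage innie read pairs at mean depth ``depth``.

    Fragment starts are stratified uniformly (evenly spaced across the
    genome) so realized coverage is flat all the way to the sequence
    ends; strand, insert length and errors remain random.  Pair *i*
    yields read IDs ``2i`` (fragment left end, forward) and ``2i + 1``
    (fragment right end, reverse complement), with the roles swapped
    when the fragment is sequenced from the minus strand.  Erroneous
    bases receive the low Phred score of the quality model.
    """
    rng = np.random.default_rng(spec.rng_seed + 0x5EED)
    m = spec.read_len
    G = spec.genome_len
    haps = [np.frombuffer(genome.hap1.encode(), np.uint8),
            np.frombuffer((genome.hap2 or genome.hap1).encode(), np.uint8)]
    haps = [dna._BYTE_CODE[h] for h in haps]
    n_pairs = int(round(spec.depth * G / (2 * m)))
    hi_q, lo_q, lo_frac = spec.qual_model

    seqs = np.empty((2 * n_pairs, m), dtype=np.uint8)
    quals = np.full((2 * n_pairs, m), hi_q, dtype=np.uint8)
    start = np.empty(2 * n_pairs, dtype=np.int64)
    is_rc = np.empty(2 * n_pairs, dtype=bool)
    hap_of = np.empty(2 * n_pairs, dtype=np.int8)
    errors: list[list[int]] = [[] for _ in range(2 * n_pairs)]
    names: list[str] = []

    for i in range(n_pairs):
        h = int(rng.integers(0, 2)) if genome.diploid else 0
        frag = int(np.clip(round(rng.normal(spec.insert_mean, spec.insert_sd)), m, G))
        s = round(i * (G - frag) / max(1, n_pairs - 1))
        minus = bool(rng.random() < 0.5)
        # genome placement of the two reads (left end fwd, right end rc);
        # sequencing the minus strand swaps which mate is read first
        left = (s, False)
        right = (s + frag - m, True)
        first, second = (right, left) if minus else (left, right)
        for rid, (pos, rc) in ((2 * i, first), (2 * i + 1, second)):
            piece = haps[h][pos : pos + m]
            codes = dna.revcomp_codes(piece) if rc else piece.copy()
            if spec.err_rate > 0:
                hits = np.flatnonzero(rng.random(m) < spec.err_rate)
                for p in hits:
                    codes[p] = 1 + (codes[p] - 1 + rng.integers(1, 4)) % 4
                    quals[rid, p] = lo_q
                errors[rid] = [int(p) for p in hits]
            if lo_frac > 0:
                lows = rng.random(m) < lo_frac
                quals[rid, lows] = lo_q
            seqs[rid] = codes
            start[rid], is_rc[rid], hap_of[rid] = pos, rc, h
            names.append(f"p{i}/{1 if rid % 2 == 0 else 2} hap={h} pos={pos} "
                         f"rc={int(rc)}")

    rs = ReadSet(seqs, quals, paired=True, names=names)
    return rs, ReadTruth(start, is_rc, hap_of, errors)


def write_fastq(reads: ReadSet, prefix: str) -> tuple[str, str]:
    """Write the pairs as two plain FASTQ files ``<prefix>_1.fastq`` /
    ``<prefix>_2.fastq`` (Phred+33)."""
    paths = (f"{prefix}_1.fastq", f"{prefix}_2.fastq")
    handles = [open(p, "w") for p in paths]
    try:
        for i in range(reads.n):
            fh = handles[i % 2]
            name = reads.names[i] if reads.names else f"read{i}"
            qual = "".join(chr(q + 33) for q in reads.quals[i])
            fh.write(f"@{name.split()[0]}\n{reads.sequence(i)}\n+\n{qual}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


def write_genome_fasta(genome: GenomeTruth, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in [("hap1", genome.hap1), ("hap2", genome.hap2)]:
            if seq is None:
                continue
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
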
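"""Desk-scale contig evaluation against a known truth genome.

Each contig is aligned to every truth sequence on both strands with
edit-distance (infix) alignment; the report collects contiguity (N50),
how much of each contig aligns, how much of the genome is covered, and
the substitution / indel rates implied by the alignment operations.
Intended for truth genomes up to about a megabase -- this is an exact
aligner, not a seeded long-read mapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from . import dna


@dataclass
class EvalReport:
    contig_count: int
    total_bases: int
    n50: int
    aligned_rate: float     # aligned contig bases / total contig bases
    genome_coverage: float  # covered truth positions / truth length
    mismatch_rate: float    # substitutions / aligned contig bases
    indel_rate: float       # indel operations / aligned contig bases

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def n50(lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L sum to at least half
    of the total bases."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


# a contig counts as aligned when its best infix alignment to the truth
# is at least this similar
_MIN_IDENTITY = 0.9


def _best_alignment(contig: str, truths: list[str]):
    """(edit distance, truth index, strand, locations, cigar) of the
    best infix alignment over both strands of all truth sequences."""
    best = None
    for t_i, t in enumerate(truths):
        for strand, query in (("+", contig), ("-", dna.revcomp(contig))):
            r = edlib.align(query, t, mode="HW", task="path")
            if best is None or r["editDistance"] < best[0]:
                best = (r["editDistance"], t_i, strand, r["locations"],
                        r["cigar"])
    return best


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def evaluate(contig_seqs: list[str], truth_seqs: list[str]) -> EvalReport:
    """Align contigs to the truth genome and summarise accuracy."""
    if not truth_seqs:
        raise ValueError("empty truth genome")
    truth_len = sum(len(t) for t in truth_seqs)
    covered = [set() for _ in truth_seqs]
    total = sum(len(c) for c in contig_seqs)
    aligned_bases = 0
    mismatches = indels = 0
    for c in contig_seqs:
        if not c:
            continue
        dist, t_i, strand, locations, cigar = _best_alignment(c, truth_seqs)
        if 1.0 - dist / len(c) < _MIN_IDENTITY:
            continue
        aligned_bases += len(c)
        s, e = locations[0]
        covered[t_i].update(range(s, e + 1))
        for ln, op in _cigar_ops(cigar):
            if op == "X":
                mismatches += ln
            elif op in "ID":
                indels += ln
    coverage = sum(len(cv) for cv in covered) / truth_len
    return EvalReport(
        contig_count=len(contig_seqs),
        total_bases=total,
        n50=n50([len(c) for c in contig_seqs]) if contig_seqs else 0,
        aligned_rate=aligned_bases / total if total else 0.0,
        genome_coverage=coverage,
        mismatch_rate=mismatches / aligned_bases if aligned_bases else 0.0,
        indel_rate=indels / aligned_bases if aligned_bases else 0.0,
    )


def read_fasta(path: str) -> list[str]:
    """Sequences of a FASTA file (uppercased)."""
    seqs: list[str] = []
    cur: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            elif line:
                cur.append(line.upper())
    if cur:
        seqs.append("".join(cur))
    return seqs


def write_report(report: EvalReport, path: str) -> None:
    with open(path, "w") as fh:
        for key, val in report.as_dict().items():
            fh.write(f"{key}\t{val}\n")
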
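"""Whole-assembly orchestration.

Initial reads are visited in ascending ID order; each unmarked read is
scanned for an inferred-unique high-quality seed, the seed is extended
in both directions, and reads explained by the walk are marked so no
locus is assembled twice.  Contigs below the length floor or consuming
almost no unclaimed read mass (re-walks of loci whose reads are
already marked) are suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dna
from .extension import Contig, extend_bidirectional
from .fmindex import BidirectionalIndex
from .params import AssemblyParams
from .seeding import find_seed

logger = logging.getLogger(__name__)


@dataclass
class AssemblyState:
    global_marks: np.ndarray
    contigs: list[Contig] = field(default_factory=list)
    stats: dict[str, int] = field(default_factory=dict)


def assemble(
    index: BidirectionalIndex,
    params: AssemblyParams,
) -> AssemblyState:
    """Assemble all contigs from an indexed read set.

    Deterministic given the index and parameters.  Contigs whose
    sequence is wholly contained in a longer contig (re-walks started
    from leftover erroneous reads of an already-assembled locus) are
    suppressed from the output.
    """
    min_contig_len = params.min_contig_len or 2 * params.m
    marks = np.zeros(index.n, dtype=bool)
    state = AssemblyState(global_marks=marks)
    stats = {
        "reads": index.n, "initial_candidates": 0, "seeds_tried": 0,
        "contigs": 0, "bases": 0, "dropped_short": 0, "dropped_contained": 0,
        "erroneous": 0, "repetitive": 0, "heterozygous": 0,
        "paired_end": 0, "ambiguous": 0, "false_seeds": 0,
    }
    raw: list[Contig] = []
    for i in range(index.n):
        if marks[i]:
            continue
        stats["initial_candidates"] += 1
        seq, hq = index.recover_read(i)
        seed = find_seed(index, seq, params, hq=hq, source_id=i)
        marks[i] = True  # each read initiates at most one extension
        if seed is None:
            continue
        stats["seeds_tried"] += 1
        contig = extend_bidirectional(index, seed, params, marks, initial_read=i)
        for v in contig.verdicts:
            stats[v["label"]] += 1
            if v["label"] == "repetitive":
                stats["false_seeds"] += 1  # seed exposed as falsely unique
        if len(contig) < min_contig_len:
            stats["dropped_short"] += 1
            continue
        raw.append(contig)
    for contig in sorted(raw, key=lambda c: (-len(c), c.initial_read)):
        if any(contig.sequence in k or dna.revcomp(contig.sequence) in k
               for k in (c.sequence for c in state.contigs)):
            stats["dropped_contained"] += 1
            continue
        state.contigs.append(contig)
        stats["contigs"] += 1
        stats["bases"] += len(contig)
    state.contigs.sort(key=lambda c: c.initial_read)
    state.stats = stats
    logger.info("assembly: %s", stats)
    return state


def write_contigs(state: AssemblyState, path: str) -> None:
    """Write contigs as FASTA, 80 columns, ordered by the initial read
    that started each contig."""
    contigs = sorted(state.contigs, key=lambda c: c.initial_read)
    with open(path, "w") as fh:
        for k, c in enumerate(contigs):
            fh.write(f">contig_{k} len={len(c)} reads={len(c.used_reads)}\n")
            for j in range(0, len(c), 80):
                fh.write(c.sequence[j : j + 80] + "\n")
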
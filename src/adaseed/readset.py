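"""The indexed read collection.

A :class:`ReadSet` holds ``n`` reads of one uniform length ``m`` with
per-base Phred scores.  Reads ``2i`` and ``2i+1`` form the *i*-th pair
when paired-end mode is on.  All downstream stages (index construction,
seeding, extension) assume the uniform length; FASTQ records of any
other length are rejected at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import dna


class ReadSetError(ValueError):
    """Fatal input problem (unequal lengths, empty set, bad characters)."""


@dataclass
class ReadSet:
    """Equal-length DNA reads with Phred qualities and implicit pairing."""

    seq_codes: np.ndarray  # uint8, shape (n, m), codes 1..4
    quals: np.ndarray      # uint8, shape (n, m), Phred scores
    paired: bool = True
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seq_codes.ndim != 2 or self.seq_codes.shape[0] == 0:
            raise ReadSetError("empty read set")
        if self.quals.shape != self.seq_codes.shape:
            raise ReadSetError("quality array shape does not match reads")
        if self.paired and self.n % 2 != 0:
            raise ReadSetError("paired-end mode requires an even read count")

    @property
    def n(self) -> int:
        return self.seq_codes.shape[0]

    @property
    def m(self) -> int:
        return self.seq_codes.shape[1]

    def sequence(self, i: int) -> str:
        return dna.decode(self.seq_codes[i])

    def sequences(self) -> list[str]:
        return [self.sequence(i) for i in range(self.n)]

    def mate(self, i: int) -> int:
        """ID of the mate of read ``i`` (pairs are (2i, 2i+1))."""
        return i ^ 1

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------

    @classmethod
    def from_strings(
        cls,
        reads: Sequence[str],
        quals: Sequence[Sequence[int]] | None = None,
        default_qual: int = 40,
        paired: bool = False,
    ) -> "ReadSet":
        if not reads:
            raise ReadSetError("empty read set")
        m = len(reads[0])
        codes = np.empty((len(reads), m), dtype=np.uint8)
        for i, r in enumerate(reads):
            if len(r) != m:
                raise ReadSetError(
                    f"read {i} has length {len(r)}, expected {m}"
                )
            codes[i] = dna.encode(r)
        if quals is None:
            q = np.full((len(reads), m), default_qual, dtype=np.uint8)
        else:
            q = np.asarray(quals, dtype=np.uint8)
            if q.shape != codes.shape:
                raise ReadSetError("quality array shape does not match reads")
        return cls(codes, q, paired=paired)

    @classmethod
    def from_fastq(
        cls,
        path1: str,
        path2: str | None = None,
        max_n_fraction: float = 0.1,
        interleaved: bool = False,
    ) -> "ReadSet":
        """Load reads from FASTQ (optionally gzip, Phred+33).

        Two files are read as synchronized pairs; one file with
        ``interleaved=True`` alternates mates.  Bases called ``N`` are
        replaced by a deterministic pseudo-random base and their quality
        forced to 0; pairs in which either mate exceeds
        ``max_n_fraction`` of N calls are dropped.
        """
        import pysam

        def records(path: str) -> Iterable[tuple[str, str, list[int]]]:
            with pysam.FastxFile(path) as fh:
                for rec in fh:
                    qual = rec.get_quality_array()
                    if qual is None:
                        qual = [40] * len(rec.sequence)
                    yield rec.name, rec.sequence.upper(), qual

        if path2 is not None:
            pairs = zip(records(path1), records(path2), strict=True)
            flat = (rec for pair in pairs for rec in pair)
            paired = True
        elif interleaved:
            flat = records(path1)
            paired = True
        else:
            flat = records(path1)
            paired = False

        raw = list(flat)
        if not raw:
            raise ReadSetError(f"no FASTQ records in {path1}")
        m = len(raw[0][1])
        for name, seq, _ in raw:
            if len(seq) != m:
                raise ReadSetError(
                    f"record {name!r} has length {len(seq)}, expected {m} "
                    "(all reads must share one length)"
                )

        keep: list[tuple[str, str, list[int]]] = []
        step = 2 if paired else 1
        for i in range(0, len(raw), step):
            group = raw[i : i + step]
            if any(r[1].count("N") > max_n_fraction * m for r in group):
                continue
            keep.extend(group)
        if not keep:
            raise ReadSetError("all reads dropped by the N filter")

        codes = np.empty((len(keep), m), dtype=np.uint8)
        quals = np.empty((len(keep), m), dtype=np.uint8)
        names = []
        for i, (name, seq, qual) in enumerate(keep):
            if "N" in seq:
                seq, qual = _patch_n(seq, list(qual), name)
            codes[i] = dna.encode(seq)
            quals[i] = np.asarray(qual, dtype=np.uint8)
            names.append(name)
        return cls(codes, quals, paired=paired, names=names)


def _patch_n(seq: str, qual: list[int], name: str) -> tuple[str, list[int]]:
    # deterministic replacement keyed on the record name so reloading a
    # file reproduces the same read set
    out = list(seq)
    for j, ch in enumerate(out):
        if ch == "N":
            h = hashlib.blake2b(f"{name}:{j}".encode(), digest_size=2).digest()
            out[j] = dna.ALPHABET[h[0] & 3]
            qual[j] = 0
    return "".join(out), qual
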
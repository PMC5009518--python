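"""Bidirectional BWT index over a set of equal-length reads.

The index stores two Burrows-Wheeler transforms: one of the read set
``R`` (each read terminated by its own sentinel, with the sentinel of
read *i* ordered before that of read *j* for ``i < j``) and one of the
reversed reads ``R'``.  Together they support extending a tracked
pattern by one character on either end in constant work per call.

For a pattern ``P`` the index tracks the *intact SA range*: the suffix
array interval of ``P`` in ``R``, of ``RC(P)`` in ``R``, and of
``RC(P)`` in the reversed index (stored as the interval of the plain
complement of ``P``, which is ``RC(P)`` read backwards).  The depth of
``P`` is the number of occurrences of ``P`` and of ``RC(P)`` over all
reads, counted with multiplicity -- the assembler's proxy for local
sequencing coverage on both strands.

Each BWT symbol is packed in 4 bits: 3 bits for A/C/G/T/$ and one flag
bit marking bases whose Phred score met the quality cutoff at build
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dna
from .dna import SENT, comp
from .readset import ReadSet

_MAGIC = "adaseed-bdbwt"
_VERSION = 1


class IntactRange:
    """The three SA intervals tracking a pattern and its reverse complement.

    All intervals are half-open ``[lo, hi)``; an empty interval is the
    canonical ``(0, 0)``.  ``fwd`` is the interval of ``P`` in the
    forward index, ``rc`` that of ``RC(P)`` in the forward index and
    ``rev`` that of ``RC(P)`` in the reversed index.  A fourth, private
    interval (``P`` read backwards, in the reversed index) is the
    synchronization companion that makes forward extension constant
    work; it is an implementation detail.
    """

    __slots__ = ("fwd_lo", "fwd_hi", "rc_lo", "rc_hi", "rev_lo", "rev_hi",
                 "pr_lo", "pr_hi", "length")

    def __init__(self, fwd_lo, fwd_hi, rc_lo, rc_hi, rev_lo, rev_hi,
                 pr_lo, pr_hi, length):
        self.fwd_lo = fwd_lo
        self.fwd_hi = fwd_hi
        self.rc_lo = rc_lo
        self.rc_hi = rc_hi
        self.rev_lo = rev_lo
        self.rev_hi = rev_hi
        self.pr_lo = pr_lo
        self.pr_hi = pr_hi
        self.length = length

    @property
    def depth(self) -> int:
        """Occurrences of the pattern plus its reverse complement."""
        return max(0, self.fwd_hi - self.fwd_lo) + max(0, self.rev_hi - self.rev_lo)

    @property
    def fwd_size(self) -> int:
        return max(0, self.fwd_hi - self.fwd_lo)

    @property
    def rc_size(self) -> int:
        return max(0, self.rc_hi - self.rc_lo)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"IntactRange(len={self.length}, fwd=[{self.fwd_lo},{self.fwd_hi}), "
                f"rc=[{self.rc_lo},{self.rc_hi}), rev=[{self.rev_lo},{self.rev_hi}))")


def depth(isr: IntactRange) -> int:
    """Dep(P): total double-strand occurrence count of the tracked pattern."""
    return isr.depth


class _Half:
    """One BWT with rank support: occurrence table, cumulative counts,
    and the positions of the read sentinels."""

    __slots__ = ("bwt", "occ", "C", "sent_pos", "sent_ids", "size")

    def __init__(self, bwt: np.ndarray, sent_pos: np.ndarray, sent_ids: np.ndarray):
        self.bwt = bwt
        self.size = len(bwt)
        sym = (bwt & 7).astype(np.uint8)
        occ = np.zeros((5, self.size + 1), dtype=np.int64)
        for c in range(5):
            np.cumsum(sym == c, out=occ[c, 1:])
        self.occ = occ
        totals = occ[:, self.size]
        self.C = np.concatenate(([0], np.cumsum(totals)[:-1])).astype(np.int64)
        self.sent_pos = sent_pos
        self.sent_ids = sent_ids

    def step(self, lo: int, hi: int, c: int) -> tuple[int, int]:
        o = self.occ[c]
        nlo = int(self.C[c] + o[lo])
        nhi = int(self.C[c] + o[hi])
        if nlo >= nhi:
            return 0, 0
        return nlo, nhi

    def count(self, c: int, lo: int, hi: int) -> int:
        o = self.occ[c]
        return int(o[hi] - o[lo])

    def count_less(self, c: int, lo: int, hi: int) -> int:
        if c == 0:
            return 0
        o = self.occ[:c]
        return int(o[:, hi].sum() - o[:, lo].sum())

    def sentinel_reads(self, lo: int, hi: int) -> np.ndarray:
        """IDs of reads whose sentinel row falls inside [lo, hi)."""
        a = np.searchsorted(self.sent_pos, lo, side="left")
        b = np.searchsorted(self.sent_pos, hi, side="left")
        return self.sent_ids[a:b]


def _build_half(seqs: list[bytes], hq: np.ndarray) -> _Half:
    """BWT of a list of equal-length byte strings, one sentinel per
    string, sentinels ordered by string index."""
    m = len(seqs[0])
    # suffix keys: plain byte comparison matches sentinel-terminated
    # order because '$' would sort before 'A' exactly where one suffix
    # is a proper prefix of another; ties between identical suffixes
    # break on the read index, which realises $_i < $_j for i < j.
    entries = [(s[j:], i, j)
               for i, s in enumerate(seqs)
               for j in range(m, -1, -1)]
    entries.sort()
    n = len(seqs)
    size = n * (m + 1)
    bwt = np.empty(size, dtype=np.uint8)
    sent_pos = np.empty(n, dtype=np.int64)
    sent_ids = np.empty(n, dtype=np.int64)
    code = dna._BYTE_CODE
    s_i = 0
    for k, (_, i, j) in enumerate(entries):
        if j == 0:
            bwt[k] = SENT
            sent_pos[s_i] = k
            sent_ids[s_i] = i
            s_i += 1
        else:
            bwt[k] = code[seqs[i][j - 1]] | (np.uint8(8) if hq[i, j - 1] else 0)
    return _Half(bwt, sent_pos, sent_ids)


@dataclass
class BidirectionalIndex:
    """BWTs of the reads and of the reversed reads, with rank support
    and the read-ID <-> sentinel-position table."""

    fwd: _Half
    rev: _Half
    sentinel_table: np.ndarray  # read ID -> position of its '$' in bwt_fwd
    n: int
    m: int
    quality_cutoff: int
    paired: bool = True

    # ------------------------------------------------------------------
    # pattern tracking
    # ------------------------------------------------------------------

    def empty_range(self) -> IntactRange:
        N = self.fwd.size
        return IntactRange(0, N, 0, N, 0, N, 0, N, 0)

    def extend_backward(self, isr: IntactRange, c: int | str) -> IntactRange:
        """ISR(cP) from ISR(P)."""
        c = _as_code(c)
        f_lo, f_hi = self.fwd.step(isr.fwd_lo, isr.fwd_hi, c)
        if f_hi > f_lo:
            pr_lo = isr.pr_lo + self.fwd.count_less(c, isr.fwd_lo, isr.fwd_hi)
            pr_hi = pr_lo + (f_hi - f_lo)
        else:
            pr_lo = pr_hi = 0
        cc = comp(c)
        rev_lo, rev_hi = self.rev.step(isr.rev_lo, isr.rev_hi, cc)
        if rev_hi > rev_lo:
            rc_lo = isr.rc_lo + self.rev.count_less(cc, isr.rev_lo, isr.rev_hi)
            rc_hi = rc_lo + (rev_hi - rev_lo)
        else:
            rc_lo = rc_hi = 0
        return IntactRange(f_lo, f_hi, rc_lo, rc_hi, rev_lo, rev_hi,
                           pr_lo, pr_hi, isr.length + 1)

    def extend_forward(self, isr: IntactRange, c: int | str) -> IntactRange:
        """ISR(Pc) from ISR(P)."""
        c = _as_code(c)
        pr_lo, pr_hi = self.rev.step(isr.pr_lo, isr.pr_hi, c)
        if pr_hi > pr_lo:
            f_lo = isr.fwd_lo + self.rev.count_less(c, isr.pr_lo, isr.pr_hi)
            f_hi = f_lo + (pr_hi - pr_lo)
        else:
            f_lo = f_hi = 0
        cc = comp(c)
        rc_lo, rc_hi = self.fwd.step(isr.rc_lo, isr.rc_hi, cc)
        if rc_hi > rc_lo:
            rev_lo = isr.rev_lo + self.fwd.count_less(cc, isr.rc_lo, isr.rc_hi)
            rev_hi = rev_lo + (rc_hi - rc_lo)
        else:
            rev_lo = rev_hi = 0
        return IntactRange(f_lo, f_hi, rc_lo, rc_hi, rev_lo, rev_hi,
                           pr_lo, pr_hi, isr.length + 1)

    def isr_of(self, pattern: str | np.ndarray) -> IntactRange:
        """ISR of an explicit pattern, built by backward extensions."""
        codes = dna.encode(pattern) if isinstance(pattern, str) else pattern
        isr = self.empty_range()
        for c in codes[::-1]:
            isr = self.extend_backward(isr, int(c))
        return isr

    # ------------------------------------------------------------------
    # read lookup and recovery
    # ------------------------------------------------------------------

    def prefix_read_counts(self, isr: IntactRange) -> tuple[int, int]:
        """(forward, reverse-complement) counts of reads having the
        tracked pattern as a prefix: Dep($P) split by orientation."""
        nf = self.fwd.count(SENT, isr.fwd_lo, isr.fwd_hi) if isr.fwd_hi > isr.fwd_lo else 0
        nr = self.rev.count(SENT, isr.rev_lo, isr.rev_hi) if isr.rev_hi > isr.rev_lo else 0
        return nf, nr

    def reads_with_prefix(self, isr: IntactRange) -> set[tuple[int, bool]]:
        """IDs of reads whose sequence (flag False) or whose reverse
        complement (flag True) begins with the tracked pattern."""
        if isr.length == 0:
            raise ValueError("reads_with_prefix requires a non-empty pattern")
        out: set[tuple[int, bool]] = set()
        if isr.fwd_hi > isr.fwd_lo:
            for rid in self.fwd.sentinel_reads(isr.fwd_lo, isr.fwd_hi):
                out.add((int(rid), False))
        if isr.rev_hi > isr.rev_lo:
            for rid in self.rev.sentinel_reads(isr.rev_lo, isr.rev_hi):
                out.add((int(rid), True))
        return out

    def recover_read(self, read_id: int) -> tuple[str, np.ndarray]:
        """Original read ``read_id`` and its high-quality bit mask,
        reconstructed from the BWT in O(m)."""
        if not (0 <= read_id < self.n):
            raise IndexError(f"read id {read_id} out of range [0, {self.n})")
        # LF through read i's own sentinel lands at rank i of the
        # sentinel block (sentinels are ordered by read ID); from there
        # m LF steps spell the read right to left.
        assert self.fwd.bwt[self.sentinel_table[read_id]] & 7 == SENT
        row = read_id
        syms = np.empty(self.m, dtype=np.uint8)
        hq = np.empty(self.m, dtype=bool)
        occ = self.fwd.occ
        C = self.fwd.C
        bwt = self.fwd.bwt
        for j in range(self.m - 1, -1, -1):
            code = int(bwt[row])
            sym = code & 7
            syms[j] = sym
            hq[j] = bool(code >> 3)
            row = int(C[sym] + occ[sym, row])
        assert row == self.sentinel_table[read_id]
        return dna.decode(syms), hq

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def save(self, path: str) -> None:
        """Write the index container (magic, version, shapes, both BWTs,
        sentinel tables)."""
        np.savez_compressed(
            path,
            magic=np.array(_MAGIC),
            version=np.array(_VERSION),
            n=np.array(self.n),
            m=np.array(self.m),
            quality_cutoff=np.array(self.quality_cutoff),
            paired=np.array(self.paired),
            bwt_fwd=self.fwd.bwt,
            bwt_rev=self.rev.bwt,
            sent_pos_fwd=self.fwd.sent_pos,
            sent_ids_fwd=self.fwd.sent_ids,
            sent_pos_rev=self.rev.sent_pos,
            sent_ids_rev=self.rev.sent_ids,
        )

    @classmethod
    def load(cls, path: str) -> "BidirectionalIndex":
        with np.load(path) as z:
            if str(z["magic"]) != _MAGIC:
                raise ValueError(f"{path} is not an adaseed index")
            fwd = _Half(z["bwt_fwd"], z["sent_pos_fwd"], z["sent_ids_fwd"])
            rev = _Half(z["bwt_rev"], z["sent_pos_rev"], z["sent_ids_rev"])
            n = int(z["n"])
            table = np.empty(n, dtype=np.int64)
            table[fwd.sent_ids] = fwd.sent_pos
            return cls(fwd, rev, table, n, int(z["m"]),
                       int(z["quality_cutoff"]), bool(z["paired"]))


def _as_code(c: int | str) -> int:
    if isinstance(c, str):
        c = {"A": 1, "C": 2, "G": 3, "T": 4}.get(c, -1)
    if not 1 <= c <= 4:
        raise ValueError(f"extension character must be one of A,C,G,T, got {c!r}")
    return c


def build_index(reads: ReadSet, quality_cutoff: int = 20) -> BidirectionalIndex:
    """Build the bidirectional BWT of a read set.

    The high-quality flag of each BWT symbol is set iff that base's
    Phred score is >= ``quality_cutoff``.
    """
    n, m = reads.n, reads.m
    hq = reads.quals >= quality_cutoff
    seq_bytes = [dna.decode(reads.seq_codes[i]).encode("ascii") for i in range(n)]
    fwd = _build_half(seq_bytes, hq)
    rev_bytes = [s[::-1] for s in seq_bytes]
    rev = _build_half(rev_bytes, hq[:, ::-1])
    table = np.empty(n, dtype=np.int64)
    table[fwd.sent_ids] = fwd.sent_pos
    return BidirectionalIndex(fwd, rev, table, n, m, quality_cutoff,
                              paired=reads.paired)
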
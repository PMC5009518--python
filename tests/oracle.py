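"""Independent brute-force oracles used across the test suite.

Everything here works directly on Python strings with naive scans, so
it shares no code path with the FM-index implementation it checks.
"""

from __future__ import annotations

import random

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def count_occurrences(reads: list[str], pattern: str) -> int:
    """Overlapping occurrence count of pattern over all reads."""
    if not pattern:
        return sum(len(r) + 1 for r in reads)
    total = 0
    for r in reads:
        start = 0
        while True:
            k = r.find(pattern, start)
            if k < 0:
                break
            total += 1
            start = k + 1
    return total


def double_strand_depth(reads: list[str], pattern: str) -> int:
    """Occurrences of pattern plus of its reverse complement."""
    return count_occurrences(reads, pattern) + count_occurrences(
        reads, revcomp(pattern)
    )


def suffix_entries(reads: list[str]) -> list[tuple[str, int, int]]:
    """All (suffix, read, offset) triples in sentinel-aware sorted order:
    the sentinel compares below every base and sentinels of lower read
    IDs compare first."""
    entries = [
        (r[j:], i, j) for i, r in enumerate(reads) for j in range(len(r) + 1)
    ]
    # plain string order equals '$'-terminated order for equal-length
    # reads (prefix sorts first); ties between identical suffixes break
    # on read ID
    entries.sort(key=lambda e: (e[0], e[1]))
    return entries


def sa_interval(entries: list[tuple[str, int, int]], pattern: str) -> tuple[int, int]:
    """Half-open suffix-array interval of the suffixes starting with
    pattern, by linear scan."""
    lo, hi = None, 0
    for k, (suf, _, _) in enumerate(entries):
        if suf.startswith(pattern):
            if lo is None:
                lo = k
            hi = k + 1
    if lo is None:
        return 0, 0
    return lo, hi


def random_reads(rng: random.Random, n: int, m: int) -> list[str]:
    return ["".join(rng.choice("ACGT") for _ in range(m)) for _ in range(n)]


def n50_brute(lengths: list[int]) -> int:
    """Largest L such that contigs of length >= L hold half the bases."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = L
    return best
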
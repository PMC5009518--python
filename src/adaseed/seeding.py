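"""Inferred-unique seed selection.

A seed is a window of a read (or of an already-extended consensus)
whose observed double-strand depth is at most ``z`` times the depth
expected of a single-copy window of that length,
``d_k = (m - k + 1) * d / m``.  Such a window is likely to occur once
in the genome and therefore anchors an unambiguous extension.

The search scans suffix windows right-to-left with incremental backward
extension.  Two events steer it:

* the depth collapses below the support floor ``tau`` (typically a
  sequencing error near the window's right end) -- the scan restarts on
  the text left of the collapse;
* the window reaches the inferred-unique ceiling while still supported
  -- it is returned as a seed, provided all its bases carry the
  high-quality bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fmindex import BidirectionalIndex, IntactRange
from .params import AssemblyParams


def expected_depth(params: AssemblyParams, k: int) -> float:
    """Expected depth d_k = (m - k + 1) * d / m of a k-bp window."""
    if not 1 <= k <= params.m:
        raise ValueError(f"window length {k} outside [1, {params.m}]")
    return (params.m - k + 1) * params.d / params.m


@dataclass
class Seed:
    """An inferred-unique, high-quality window with its tracked range."""

    sequence: str
    isr: IntactRange
    depth: int
    origin: tuple[int, int, int]  # (source id, start, end) half-open
    high_quality: bool = True


def seed_quality_ok(seed: Seed, hq: np.ndarray) -> bool:
    """True iff every base of the seed window carries the high-quality
    bit in the source's flag array."""
    _, start, end = seed.origin
    return bool(np.all(hq[start:end]))


def find_seed(
    index: BidirectionalIndex,
    text: str,
    params: AssemblyParams,
    hq: np.ndarray | None = None,
    source_id: int = -1,
    ceiling_scale: float = 1.0,
) -> Seed | None:
    """First inferred-unique high-quality seed in ``text``, scanning
    windows that end as far right as possible.

    Returns ``None`` when no window qualifies, which tells the caller
    to move on to a new initial read.  ``ceiling_scale`` > 1 relaxes
    the inferred-unique ceiling (used for continuation seeds inside
    repeats, whose depth is a multiple of the single-copy expectation;
    reverse validation and paired-end evidence police such seeds).
    """
    if hq is None:
        hq = np.ones(len(text), dtype=bool)
    z, tau, min_len = params.z * ceiling_scale, params.tau, params.min_seed_len
    end = len(text)
    while end >= min_len:
        isr = index.empty_range()
        restart = -1
        for j in range(end - 1, -1, -1):
            isr = index.extend_backward(isr, text[j])
            dep = isr.depth
            k = end - j
            # inferred-unique test first: a window satisfying both this
            # and the tau floor at the same step still counts as a seed
            if dep > 0 and k >= min_len and dep <= z * expected_depth(params, k):
                if hq[j:end].all():
                    return Seed(text[j:end], isr, dep, (source_id, j, end))
                # the rightmost low-quality base poisons every further
                # window ending at `end`; resume left of it
                low = np.flatnonzero(~hq[j:end])
                restart = j + int(low[-1])
                break
            if dep < tau:
                restart = j
                break
        else:
            return None
        end = restart
    return None


def estimate_depth(index: BidirectionalIndex, reads, k: int = 21,
                   max_kmers: int = 2_000_000) -> float:
    """Rough fold-coverage estimate d = n*m / G with the genome size G
    approximated by the number of distinct canonical k-mers in the
    reads.  Adequate for deep, low-error data; supply ``d`` explicitly
    otherwise."""
    from . import dna

    seen: set[str] = set()
    budget = max_kmers
    for i in range(reads.n):
        s = reads.sequence(i)
        rc = dna.revcomp(s)
        for j in range(len(s) - k + 1):
            w = s[j : j + k]
            wrc = rc[len(s) - k - j : len(s) - j]
            seen.add(min(w, wrc))
        budget -= len(s) - k + 1
        if budget <= 0:
            # deep data saturates the distinct k-mer set well before the
            # budget runs out, so the partial count still estimates G
            break
    return reads.n * reads.m / max(1, len(seen))
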
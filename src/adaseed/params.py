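"""Assembly parameters.

``d`` is the expected genome-wide sequencing depth (fold coverage) and
``m`` the uniform read length; together they give the expected depth of
a k-bp window, ``d_k = (m - k + 1) * d / m``.  ``z`` scales that
expectation into the inferred-unique ceiling, ``tau`` is the minimum
support depth for any accepted evidence, and ``sig_ratio`` is the
single dominance ratio standing in for "significantly larger" in the
branch-classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass
class AssemblyParams:
    d: float                     # expected genome sequencing depth (fold)
    m: int                       # read length (bases)
    z: float = 1.5               # inferred-unique multiplier (dimensionless)
    tau: int = 4                 # minimum support depth (reads)
    quality_cutoff: int = 20     # Phred threshold for the high-quality bit
    min_seed_len: int = 31       # shortest window eligible as a seed (bases)
    het_similarity: float = 0.9  # allele-branch similarity floor [0, 1]
    sig_ratio: float = 4.0       # dominance ratio for branch verdicts (>1)
    insert_mean: float = 500.0   # paired-end insert size mean (bases)
    insert_sd: float = 50.0      # paired-end insert size s.d. (bases)
    min_contig_len: int | None = None  # default 2*m at assembly time
    pe_resolve: bool = True      # use paired-end evidence at stalled forks
    repeat_seed_relax: float = 3.0  # ceiling relaxation for continuation seeds

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("expected depth d must be positive")
        if not 0 < self.min_seed_len <= self.m:
            raise ValueError("require 0 < min_seed_len <= m")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.sig_ratio <= 1:
            raise ValueError("sig_ratio must exceed 1")
        if not 0 <= self.het_similarity <= 1:
            raise ValueError("het_similarity must lie in [0, 1]")

    def with_(self, **kw) -> "AssemblyParams":
        return replace(self, **kw)
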
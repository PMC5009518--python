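import random

import pytest

from adaseed import ReadSet, build_index

import oracle


@pytest.fixture(scope="session")
def tiny_index():
    """The two-read toy index used by the worked examples."""
    rs = ReadSet.from_strings(["ACG", "CGT"])
    return build_index(rs, quality_cutoff=20)


@pytest.fixture(scope="session")
def random_indexed_reads():
    """A modest random read set with its index, shared across tests."""
    rng = random.Random(20160831)
    reads = oracle.random_reads(rng, n=40, m=21)
    rs = ReadSet.from_strings(reads)
    return reads, build_index(rs, quality_cutoff=20)
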
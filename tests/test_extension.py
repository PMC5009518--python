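"""Extension trees, consensus walking, reverse validation and
paired-end resolution, checked against simulations with known truth."""

import numpy as np
import pytest

from adaseed import AssemblyParams, build_index, dna
from adaseed.extension import (
    Contig,
    build_tree,
    classify_branch,
    consensus_walk,
    extend_bidirectional,
)
from adaseed.seeding import find_seed
from adaseed.simdata import SimSpec, simulate_genome, simulate_reads


@pytest.fixture(scope="module")
def clean_run():
    """Error-free 30x 100 bp pairs over a 20 kb repeat-free genome."""
    spec = SimSpec(genome_len=20_000, rng_seed=1, depth=30, read_len=100,
                   insert_mean=300, insert_sd=30)
    genome = simulate_genome(spec)
    reads, truth = simulate_reads(genome, spec)
    index = build_index(reads, 20)
    params = AssemblyParams(d=30, m=100, insert_mean=300, insert_sd=30)
    return genome, reads, truth, index, params


class TestBuildTree:
    def test_error_free_unique_region_gives_single_path(self, clean_run):
        genome, reads, truth, index, params = clean_run
        seed = find_seed(index, reads.sequence(0), params)
        tree = build_tree(index, seed, params)
        depth = 0
        node = tree
        while node.children:
            assert len(node.children) == 1  # no error, repeat or allele
            node = node.children[0]
            depth += 1
        assert depth <= params.m - len(seed.sequence)
        assert depth >= params.m - len(seed.sequence) - 8  # near the cap

    def test_child_weight_never_exceeds_parent(self, clean_run):
        _, reads, _, index, params = clean_run
        seed = find_seed(index, reads.sequence(10), params)
        stack = [build_tree(index, seed, params)]
        while stack:
            node = stack.pop()
            for ch in node.children:
                assert ch.weight <= node.weight
                stack.append(ch)

    def test_terminal_reads_match_simulated_layout(self, clean_run):
        genome, reads, truth, index, params = clean_run
        seed = find_seed(index, reads.sequence(0), params)
        tree = build_tree(index, seed, params)
        # every terminal read must genuinely carry the node label as prefix
        node, label = tree, seed.sequence
        while node is not None:
            for rid, is_rc in node.terminal_reads:
                s = reads.sequence(rid)
                if is_rc:
                    s = dna.revcomp(s)
                assert s.startswith(label[: len(s)])
            node = node.children[0] if node.children else None
            if node is not None:
                label = _tag(node) + label
        # and a read starting exactly at the seed is terminal at the root
        seed_read_ids = {rid for rid, _ in tree.terminal_reads}
        assert all(
            reads.sequence(r).startswith(seed.sequence)
            or dna.revcomp(reads.sequence(r)).startswith(seed.sequence)
            for r in seed_read_ids
        )


def _tag(node):
    return "$ACGT"[node.tag]


class TestClassifyBranch:
    def _fork(self, index, text, params):
        """Find the first multi-child node walking a seed's tree."""
        seed = find_seed(index, text, params)
        assert seed is not None
        tree = build_tree(index, seed, params)
        node, emitted = tree, []
        while node.children:
            if len(node.children) > 1:
                return seed, node, emitted
            node = node.children[0]
            emitted.append(node.tag)
        return seed, None, emitted

    def test_low_frequency_substitution_branch_is_erroneous(self):
        """A branch carried by a couple of erroneous reads is removed
        and the true allele survives."""
        spec = SimSpec(genome_len=8_000, rng_seed=3, depth=40, read_len=100,
                       err_rate=0.005, insert_mean=300, insert_sd=30)
        genome = simulate_genome(spec)
        reads, truth = simulate_reads(genome, spec)
        index = build_index(reads, 20)
        params = AssemblyParams(d=40, m=100, insert_mean=300, insert_sd=30)
        checked = correct = 0
        for i in range(0, reads.n, 37):
            seed, fork, emitted = self._fork(index, reads.sequence(i), params)
            if fork is None or len(fork.children) != 2:
                continue
            a, b = fork.children
            label = "".join("$ACGT"[t] for t in reversed(emitted)) + seed.sequence
            v = classify_branch(index, a, b, label, params,
                               ref_base_depth=40.0,
                               child_label_len=len(label) + 1)
            if v.label != "erroneous":
                continue
            checked += 1
            # survivor's base must match the true genome: locate the label
            ctx = label[:40]
            for hay, flip in ((genome.hap1, False),
                              (dna.revcomp(genome.hap1), True)):
                p = hay.find(ctx)
                if p > 0:
                    if "$ACGT"[v.survivor.tag] == hay[p - 1]:
                        correct += 1
                    break
        assert checked >= 5
        assert correct / checked >= 0.95

    def test_heterozygous_fork_merges_to_heavier_allele(self):
        spec = SimSpec(genome_len=20_000, rng_seed=11, depth=40, read_len=100,
                       het_rate=0.0015, insert_mean=300, insert_sd=30)
        genome = simulate_genome(spec)
        reads, truth = simulate_reads(genome, spec)
        index = build_index(reads, 20)
        params = AssemblyParams(d=40, m=100, insert_mean=300, insert_sd=30)
        het_found = 0
        for i in range(0, reads.n, 23):
            seed, fork, emitted = self._fork(index, reads.sequence(i), params)
            if fork is None or len(fork.children) != 2:
                continue
            a, b = fork.children
            label = "".join("$ACGT"[t] for t in reversed(emitted)) + seed.sequence
            v = classify_branch(index, a, b, label, params,
                               ref_base_depth=40.0,
                               child_label_len=len(label) + 1)
            if v.label == "heterozygous":
                het_found += 1
                assert v.survivor.weight == max(a.weight, b.weight)
        assert het_found >= 3


class TestConsensusWalk:
    def test_single_path_tree_emits_full_depth(self, clean_run):
        _, reads, _, index, params = clean_run
        seed = find_seed(index, reads.sequence(0), params)
        tree = build_tree(index, seed, params)
        walk = consensus_walk(index, tree, params, seed.sequence)
        assert not walk.stopped_at_root
        assert len(walk.extension) >= params.m - len(seed.sequence) - 8
        # the extension must equal the true genome segment left of the seed
        whole = walk.extension + seed.sequence
        assert whole in clean_run[0].hap1 or dna.revcomp(whole) in clean_run[0].hap1

    def test_childless_root_stops_immediately(self, clean_run):
        _, reads, _, index, params = clean_run
        seed = find_seed(index, reads.sequence(0), params)
        tree = build_tree(index, seed, params)
        tree.children = []
        walk = consensus_walk(index, tree, params, seed.sequence)
        assert walk.extension == "" and walk.stopped_at_root


class TestExtendBidirectional:
    def test_full_genome_reconstruction_from_one_seed(self, clean_run):
        genome, reads, truth, index, params = clean_run
        marks = np.zeros(reads.n, dtype=bool)
        seed = find_seed(index, reads.sequence(0), params, source_id=0)
        contig = extend_bidirectional(index, seed, params, marks, initial_read=0)
        assert contig.sequence in (genome.hap1, dna.revcomp(genome.hap1))
        assert len(contig.support) == len(contig.sequence)
        assert min(contig.support) >= 1
        assert marks.sum() == reads.n  # every read consumed

    def test_edge_seed_extends_to_the_other_edge(self, clean_run):
        genome, reads, truth, index, params = clean_run
        # pick a read at the very start of the genome
        edge_read = int(np.argmin(truth.start))
        marks = np.zeros(reads.n, dtype=bool)
        seed = find_seed(index, reads.sequence(edge_read), params)
        contig = extend_bidirectional(index, seed, params, marks,
                                      initial_read=edge_read)
        assert len(contig) >= 0.99 * len(genome.hap1)

    def test_no_read_marked_twice_across_contigs(self, clean_run):
        genome, reads, truth, index, params = clean_run
        marks = np.zeros(reads.n, dtype=bool)
        seen: set[int] = set()
        for i in (0, 1000, 3000):
            if marks[i]:
                continue
            seed = find_seed(index, reads.sequence(i), params, source_id=i)
            if seed is None:
                continue
            contig = extend_bidirectional(index, seed, params, marks,
                                          initial_read=i)
            assert not (seen & set(contig.used_reads))
            seen |= set(contig.used_reads)


@pytest.fixture(scope="module")
def repeat_world():
    spec = SimSpec(genome_len=12_000, rng_seed=1, depth=30, read_len=250,
                   repeats=[(300, 2, 0.0)], insert_mean=500, insert_sd=50)
    genome = simulate_genome(spec)
    reads, _ = simulate_reads(genome, spec)
    index = build_index(reads, 20)
    return genome, reads, index


class TestPairedEndResolution:
    def _assemble(self, index, pe):
        from adaseed.assembler import assemble
        params = AssemblyParams(d=30, m=250, insert_mean=500, insert_sd=50,
                                pe_resolve=pe)
        return assemble(index, params)

    def test_pairs_span_exact_repeat(self, repeat_world):
        genome, reads, index = repeat_world
        state = self._assemble(index, pe=True)
        for start in genome.repeat_copies[0]:
            window = genome.hap1[start - 50 : start + genome.repeat_units[0] + 50]
            assert any(window in c.sequence or window in dna.revcomp(c.sequence)
                       for c in state.contigs)
        assert state.stats["paired_end"] >= 1

    def test_assembly_breaks_at_repeat_without_pairs(self, repeat_world):
        genome, reads, index = repeat_world
        state = self._assemble(index, pe=False)
        for start in genome.repeat_copies[0]:
            window = genome.hap1[start - 50 : start + genome.repeat_units[0] + 50]
            assert not any(window in c.sequence or window in dna.revcomp(c.sequence)
                           for c in state.contigs)
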
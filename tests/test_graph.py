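"""Block/path data-structure behaviour: edits, reconstruction, splitting,
consensus recomputation, orientation flips and polishing."""
import pytest
from hypothesis import given, strategies as st

from panblocks._seq import revcomp
from panblocks.graph import (DEL, FORWARD, INS, REVERSE, SUB, Edit,
                             GraphError, Pangraph, apply_edits, check_edits,
                             derive_edits, expand_alignment, flip_block,
                             polish_block, recompute_consensus, split_block)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=80)


def one_block_graph(consensus, edits=None, strand=FORWARD, circular=True):
    g = Pangraph()
    blk = g.add_block(consensus)
    node = g.add_node(blk, "iso", strand, edits or [])
    from panblocks.graph import Path
    g.paths["iso"] = Path("iso", [node.id], circular=circular)
    return g, blk, node


class TestEdits:
    def test_apply_each_kind(self):
        cons = "ACGTACGT"
        assert apply_edits(cons, [Edit(SUB, 3, "G")]) == "ACGGACGT"
        assert apply_edits(cons, [Edit(INS, 4, "TT")]) == "ACGTTTACGT"
        assert apply_edits(cons, [Edit(DEL, 2, 3)]) == "ACCGT"
        assert apply_edits(cons, []) == cons

    def test_invalid_edits_rejected(self):
        with pytest.raises(GraphError):
            Edit(SUB, -1, "A")
        with pytest.raises(GraphError):
            Edit(DEL, 0, 0)
        with pytest.raises(GraphError):
            check_edits("ACGT", [Edit(DEL, 2, 5)])
        with pytest.raises(GraphError):
            check_edits("ACGTACGT", [Edit(DEL, 0, 4), Edit(SUB, 2, "T")])

    @given(member=DNA, consensus=DNA)
    def test_derive_apply_roundtrip(self, member, consensus):
        """Optimal-alignment edits always reproduce the member exactly."""
        edits = derive_edits(member, consensus)
        check_edits(consensus, edits)
        assert apply_edits(consensus, edits) == member


class TestReconstruct:
    def test_identity_and_substitution(self):
        g, _, _ = one_block_graph("ACGTACGTAA")
        assert g.reconstruct("iso") == "ACGTACGTAA"
        g2, _, node = one_block_graph("ACGTACGTAA")
        node.edits = [Edit(SUB, 3, "G")]
        assert g2.reconstruct("iso") == "ACGGACGTAA"

    def test_reverse_strand(self):
        g, _, _ = one_block_graph("ACGTTT", strand=REVERSE)
        assert g.reconstruct("iso") == revcomp("ACGTTT")

    def test_unknown_path(self):
        g, _, _ = one_block_graph("ACGT")
        with pytest.raises(GraphError):
            g.reconstruct("nope")

    def test_roundtrip_simulated(self, small_population, small_graph):
        """Every simulated genome is reproduced byte-for-byte."""
        genomes, _ = small_population
        for name, seq in genomes:
            assert small_graph.reconstruct(name) == seq
        small_graph.validate()


class TestRecomputeConsensus:
    def test_depth_one_absorbs_edits(self):
        g, blk, node = one_block_graph("ACGTACGTAA")
        node.edits = [Edit(SUB, 0, "T"), Edit(DEL, 4, 2)]
        member = g.node_segment(node)
        recompute_consensus(g, blk.id)
        assert blk.consensus == member and node.edits == []

    def test_majority_vote_matches_bruteforce(self):
        """Column vote on a 3 x 10 substitution-only toy alignment."""
        cons = "ACGTACGTAA"
        g = Pangraph()
        blk = g.add_block(cons)
        from panblocks.graph import Path
        edit_sets = [[Edit(SUB, 3, "G")], [Edit(SUB, 3, "G")], []]
        members = [apply_edits(cons, e) for e in edit_sets]
        for i, edits in enumerate(edit_sets):
            node = g.add_node(blk, f"m{i}", FORWARD, edits)
            g.paths[f"m{i}"] = Path(f"m{i}", [node.id])
        recompute_consensus(g, blk.id)
        # independent column-wise majority (no indels -> plain vote)
        expected = "".join(
            max("ACGT", key=lambda b: [m[c] for m in members].count(b))
            for c in range(len(cons)))
        assert blk.consensus == expected
        assert blk.consensus[3] == "G"
        # former majority is now a substitution on the minority member
        assert [g.node_segment(g.nodes[n]) for n in blk.node_ids] == members

    def test_conservation_on_simulated_blocks(self, small_graph):
        from panblocks.merge import _union
        g = _union(small_graph, None)
        deep = [b.id for b in g.blocks.values() if b.depth >= 2][:5]
        assert deep, "expected shared blocks in the simulated graph"
        for bid in deep:
            before = sorted(g.node_segment(g.nodes[n])
                            for n in g.blocks[bid].node_ids)
            recompute_consensus(g, bid)
            after = sorted(g.node_segment(g.nodes[n])
                           for n in g.blocks[bid].node_ids)
            assert before == after


class TestSplitBlock:
    def test_no_cuts_is_identity(self):
        g, blk, _ = one_block_graph("ACGTACGTAA")
        assert split_block(g, blk.id, []) == [blk.id]
        assert g.reconstruct("iso") == "ACGTACGTAA"

    def test_forward_midpoint(self):
        g, blk, _ = one_block_graph("ACGTACGTAA")
        pieces = split_block(g, blk.id, [5])
        assert [len(g.blocks[p].consensus) for p in pieces] == [5, 5]
        assert len(g.paths["iso"].node_ids) == 2
        assert g.reconstruct("iso") == "ACGTACGTAA"

    def test_reverse_occurrence_swaps_piece_order(self):
        seq = "ACGTACGTAA"
        g, blk, _ = one_block_graph(seq, strand=REVERSE)
        before = g.reconstruct("iso")
        pieces = split_block(g, blk.id, [4])
        path = g.paths["iso"]
        order = [g.nodes[n].block_id for n in path.node_ids]
        assert order == [pieces[1], pieces[0]]
        assert all(g.nodes[n].strand == REVERSE for n in path.node_ids)
        assert g.reconstruct("iso") == before

    def test_spanning_deletion_is_partitioned(self):
        g, blk, node = one_block_graph("AAAACCCCGGGGTTTT")
        node.edits = [Edit(DEL, 6, 4)]
        before = g.reconstruct("iso")
        split_block(g, blk.id, [8])
        assert g.reconstruct("iso") == before
        for nid in g.paths["iso"].node_ids:
            check_edits(g.blocks[g.nodes[nid].block_id].consensus,
                        g.nodes[nid].edits)

    def test_bad_cuts_rejected(self):
        g, blk, _ = one_block_graph("ACGTACGTAA")
        with pytest.raises(GraphError):
            split_block(g, blk.id, [0])
        with pytest.raises(GraphError):
            split_block(g, blk.id, [3, 3])


class TestFlip:
    def test_involution_restores_graph(self):
        g, blk, node = one_block_graph("ACGTACGTAA")
        node.edits = [Edit(SUB, 1, "T"), Edit(INS, 5, "GG"), Edit(DEL, 7, 2)]
        before = (blk.consensus, list(node.edits), g.reconstruct("iso"))
        flip_block(g, blk.id)
        assert g.reconstruct("iso") == before[2]  # conserved under flip
        flip_block(g, blk.id)
        assert (blk.consensus, node.edits, g.reconstruct("iso")) == before


class TestPolish:
    def _two_member_block(self, cons, edits_a, edits_b):
        g = Pangraph()
        blk = g.add_block(cons)
        from panblocks.graph import Path
        for nm, ed in (("a", edits_a), ("b", edits_b)):
            node = g.add_node(blk, nm, FORWARD, ed)
            g.paths[nm] = Path(nm, [node.id])
        return g, blk

    def test_identical_members_unchanged(self):
        g, blk = self._two_member_block("ACGTACGTAA" * 3, [], [])
        polish_block(g, blk.id)
        assert blk.consensus == "ACGTACGTAA" * 3
        assert all(not g.nodes[n].edits for n in blk.node_ids)

    def test_shared_insertion_artifact_removed(self):
        """A shared indel double-counted by merging collapses after polish."""
        cons = "ACGTACGTAA" * 6
        shared = [Edit(INS, 30, "TTTTT")]
        g, blk = self._two_member_block(cons, list(shared), list(shared))
        members = sorted(g.node_segment(g.nodes[n]) for n in blk.node_ids)
        before = sum(len(g.nodes[n].edits) for n in blk.node_ids)
        polish_block(g, blk.id)
        after = sum(len(g.nodes[n].edits) for n in blk.node_ids)
        assert after < before  # the shared insertion is now consensus
        assert sorted(g.node_segment(g.nodes[n])
                      for n in blk.node_ids) == members

    def test_polish_conserves_simulated_graph(self, small_population,
                                              small_graph):
        from panblocks.merge import _union
        genomes, _ = small_population
        g = _union(small_graph, None)
        from panblocks.graph import polish_graph
        polish_graph(g)
        for name, seq in genomes:
            assert g.reconstruct(name) == seq


def test_expand_alignment_realizes_edits():
    cons = "ACGTACGT"
    edits = [[Edit(INS, 4, "TT")], [Edit(DEL, 2, 2)], []]
    cons_row, rows = expand_alignment(cons, edits)
    assert cons_row.replace("-", "") == cons
    for ed, row in zip(edits, rows):
        assert row.replace("-", "") == apply_edits(cons, ed)
    assert len({len(cons_row), *map(len, rows)}) == 1
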
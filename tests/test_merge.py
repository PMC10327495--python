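"""Pseudo-energy ranking and iterative graph merging."""
import pytest

from panblocks._seq import random_sequence, revcomp
from panblocks.graph import FORWARD, REVERSE, GraphError, Pangraph
from panblocks.kernel import Hit, KernelConfig, align_consensus_sets
from panblocks.merge import (MergeCandidate, MergeParams, _union,
                             apply_merger, build_pangraph,
                             candidate_from_hit, merge_round,
                             pairwise_graph_merge, pseudo_energy,
                             select_mergers, split_hit_at_long_indels)

P = MergeParams()


class TestPseudoEnergy:
    def test_direct_evaluation(self):
        assert pseudo_energy(0, 0, 0, P) == 0.0          # not admissible
        assert pseudo_energy(500, 2, 5, P) == -250.0
        # boundary: mergers become inadmissible exactly at 10 % divergence
        assert pseudo_energy(1000, 0, 100, P) == 0.0

    def test_divergence_ceiling_is_inverse_beta(self):
        for length in (100, 1000, 10_000):
            below = pseudo_energy(length, 0, 0.0999 * length, P)
            at = pseudo_energy(length, 0, 0.1 * length, P)
            assert below < 0 <= at

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            pseudo_energy(-1, 0, 0, P)


def _hit(qid, rid, qs, qe, rs, re_, strand=FORWARD, cigar=None):
    ln = max(qe - qs, re_ - rs)
    return Hit(qid, rid, qs, qe, rs, re_, strand,
               cigar or f"{ln}=", ln, ln)


def _graph_two_blocks(la, lb, rng):
    g = Pangraph()
    from panblocks.graph import Path
    a = g.add_block(random_sequence(la, rng))
    b = g.add_block(random_sequence(lb, rng))
    for nm, blk in (("x", a), ("y", b)):
        node = g.add_node(blk, nm, FORWARD)
        g.paths[nm] = Path(nm, [node.id])
    return g, a, b


class TestCandidates:
    def test_full_length_hit_no_cuts(self, rng):
        g, a, b = _graph_two_blocks(1000, 1000, rng)
        c = candidate_from_hit(_hit(a.id, b.id, 0, 1000, 0, 1000), g, P)
        assert c.n_cuts == 0 and c.energy == -1000

    def test_interior_interval_creates_two_flanks(self, rng):
        g, a, b = _graph_two_blocks(1000, 2000, rng)
        c = candidate_from_hit(_hit(a.id, b.id, 0, 1000, 400, 1400), g, P)
        assert c.n_cuts == 2
        assert c.energy == -1000 + P.alpha * 2

    def test_cut_near_end_snaps_and_does_not_count(self, rng):
        g, a, b = _graph_two_blocks(1000, 1040, rng)
        # hit ends 40 bp before b's end: inside L_min, snapped to the end
        c = candidate_from_hit(_hit(a.id, b.id, 0, 1000, 0, 1000), g, P)
        assert c.rcuts == (0, 1040) and c.n_cuts == 0

    def test_stale_hit_returns_none(self, rng):
        g, a, b = _graph_two_blocks(1000, 1000, rng)
        h = _hit(a.id, b.id, 0, 1000, 0, 1000)
        del g.blocks[a.id]
        assert candidate_from_hit(h, g, P) is None


class TestSelect:
    def _cand(self, qid, rid, energy, length=1000):
        h = _hit(qid, rid, 0, length, 0, length)
        return MergeCandidate(h, (0, length), (0, length), 0, 0, energy)

    def test_nonnegative_all_rejected(self):
        assert select_mergers([self._cand("a", "b", 0.0),
                               self._cand("c", "d", 5.0)]) == []

    def test_disjoint_kept_in_energy_order(self):
        out = select_mergers([self._cand("a", "b", -100.0),
                              self._cand("c", "d", -500.0)])
        assert [c.energy for c in out] == [-500.0, -100.0]

    def test_conflicting_candidates_resolved_greedily(self):
        out = select_mergers([self._cand("a", "b", -100.0),
                              self._cand("b", "c", -500.0)])
        assert len(out) == 1 and out[0].energy == -500.0


class TestSplitHitAtLongIndels:
    def test_clean_hit_untouched(self):
        h = _hit("a", "b", 0, 500, 0, 500)
        assert split_hit_at_long_indels(h, 100) == [h]

    def test_long_deletion_splits_hit(self):
        h = Hit("a", "b", 0, 1000, 0, 1500, FORWARD,
                "500=500D500=", 1000, 1500)
        parts = split_hit_at_long_indels(h, 100)
        assert [(p.qstart, p.qend, p.rstart, p.rend) for p in parts] == \
            [(0, 500, 0, 500), (500, 1000, 1000, 1500)]

    def test_reverse_strand_coordinates(self):
        h = Hit("a", "b", 0, 1000, 0, 1500, REVERSE,
                "500=500D500=", 1000, 1500)
        parts = split_hit_at_long_indels(h, 100)
        # cigar walks the reverse-complemented query: first piece is the
        # query's far end
        assert [(p.qstart, p.qend) for p in parts] == [(500, 1000), (0, 500)]
        assert [(p.rstart, p.rend) for p in parts] == [(0, 500), (1000, 1500)]


class TestApplyMerger:
    def test_identical_blocks_fuse_to_depth_two(self, rng):
        g, a, b = _graph_two_blocks(1000, 1000, rng)
        b.consensus = a.consensus
        c = candidate_from_hit(_hit(a.id, b.id, 0, 1000, 0, 1000), g, P)
        fused = apply_merger(g, c, P)
        assert len(g.blocks) == 1 and g.blocks[fused].depth == 2
        assert all(not g.nodes[n].edits for n in g.blocks[fused].node_ids)

    def test_known_snp_becomes_single_edit(self, rng):
        g, a, b = _graph_two_blocks(1000, 1000, rng)
        snp = "A" if a.consensus[500] != "A" else "C"
        b.consensus = a.consensus[:500] + snp + a.consensus[501:]
        before = {nm: g.reconstruct(nm) for nm in g.paths}
        c = candidate_from_hit(
            _hit(a.id, b.id, 0, 1000, 0, 1000,
                 cigar="500=1X499="), g, P)
        fused = apply_merger(g, c, P)
        edits = [e for n in g.blocks[fused].node_ids
                 for e in g.nodes[n].edits]
        assert len(edits) == 1 and edits[0].kind == "sub"
        assert {nm: g.reconstruct(nm) for nm in g.paths} == before

    def test_reverse_complement_merge_round_trips(self, rng):
        g, a, b = _graph_two_blocks(1000, 1000, rng)
        b.consensus = revcomp(a.consensus)
        before = {nm: g.reconstruct(nm) for nm in g.paths}
        c = candidate_from_hit(
            _hit(a.id, b.id, 0, 1000, 0, 1000, strand=REVERSE), g, P)
        fused = apply_merger(g, c, P)
        strands = sorted(g.nodes[n].strand for n in g.blocks[fused].node_ids)
        assert strands == [REVERSE, FORWARD] or strands == [-1, 1]
        assert {nm: g.reconstruct(nm) for nm in g.paths} == before

    def test_roundtrip_after_every_single_merger(self, small_population):
        """Reconstruction stays exact after each individual application."""
        genomes, _ = small_population
        d = dict(genomes[:2])
        g = Pangraph.from_genomes(sorted(d.items()))
        g.renumber()
        cfg = KernelConfig()
        for _ in range(40):
            blocks = sorted((b.id, b.consensus) for b in g.blocks.values())
            hits = align_consensus_sets(blocks, blocks, cfg)
            cands = []
            for h in hits:
                for sub in split_hit_at_long_indels(h, P.l_min):
                    if sub.length >= P.l_min:
                        c = candidate_from_hit(sub, g, P)
                        if c:
                            cands.append(c)
            chosen = select_mergers(cands)
            if not chosen:
                break
            for cand in chosen:
                apply_merger(g, cand, P)
                for nm, seq in d.items():
                    assert g.reconstruct(nm) == seq
            g.renumber()
        assert any(b.depth > 1 for b in g.blocks.values())


class TestPairwiseMerge:
    def test_identical_genomes_one_block(self, rng):
        seq = random_sequence(8_000, rng)
        ga = Pangraph.from_genomes([("x", seq)])
        gb = Pangraph.from_genomes([("y", seq)])
        g = pairwise_graph_merge(ga, gb)
        assert len(g.blocks) == 1 and len(g.paths) == 2

    def test_inversion_yields_opposed_middle_block(self, rng):
        seq = random_sequence(10_000, rng)
        inv = seq[:4500] + revcomp(seq[4500:5500]) + seq[5500:]
        g = pairwise_graph_merge(Pangraph.from_genomes([("x", seq)]),
                                 Pangraph.from_genomes([("y", inv)]))
        assert g.reconstruct("x") == seq and g.reconstruct("y") == inv
        mids = [b for b in g.blocks.values()
                if 900 <= len(b.consensus) <= 1100]
        assert len(mids) == 1
        strands = {g.nodes[n].path_name: g.nodes[n].strand
                   for n in mids[0].node_ids}
        assert strands["x"] != strands["y"]
        from panblocks.metrics import graph_breakpoints
        for pos in graph_breakpoints(g)["x"]:
            assert min(abs(pos - 4500), abs(pos - 5500)) <= 100

    def test_merged_graph_is_fixed_point(self, small_graph):
        g = _union(small_graph, None)
        g.renumber()
        assert merge_round(g, KernelConfig(), P) == 0

    def test_disjoint_names_required(self, rng):
        seq = random_sequence(2_000, rng)
        ga = Pangraph.from_genomes([("x", seq)])
        with pytest.raises(GraphError):
            pairwise_graph_merge(ga, Pangraph.from_genomes([("x", seq)]))


class TestBuild:
    def test_single_genome(self, rng):
        seq = random_sequence(5_000, rng)
        g = build_pangraph([("solo", seq)])
        assert len(g.blocks) == 1 and len(g.paths) == 1
        assert g.reconstruct("solo") == seq

    def test_identical_genomes_forced_compression(self, rng):
        from panblocks.metrics import graph_summary
        seq = random_sequence(10_000, rng)
        n = 5
        g = build_pangraph([(f"g{i}", seq) for i in range(n)])
        s = graph_summary(g)
        assert s["n_blocks"] == 1
        assert s["compression"] == pytest.approx(1 / n)
        assert s["core_fraction"] == 1.0

    def test_duplicate_names_rejected(self, rng):
        seq = random_sequence(1_000, rng)
        with pytest.raises(GraphError):
            build_pangraph([("a", seq), ("a", seq)])

    def test_l_min_floor_and_divergence_ceiling(self, small_graph):
        g = small_graph
        assert min(len(b.consensus) for b in g.blocks.values()) >= P.l_min
        # no block alignment may exceed the 1/beta consensus divergence
        for blk in g.blocks.values():
            for nid in blk.node_ids:
                node = g.nodes[nid]
                subs = sum(len(e.payload) for e in node.edits
                           if e.kind == "sub")
                assert subs / len(blk.consensus) < 1 / P.beta + 0.02

    def test_monotonic_compression(self, small_population):
        genomes, _ = small_population
        d = dict(genomes[:4])
        g = _union(Pangraph.from_genomes(sorted(d.items())), None)
        g.renumber()
        total = g.pangenome_length()
        for _ in range(30):
            if merge_round(g, KernelConfig(), P) == 0:
                break
            new_total = g.pangenome_length()
            assert new_total <= total
            total = new_total
            g.renumber()
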
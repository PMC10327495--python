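"""Iterative graph merging ranked by pseudo-energy.

Candidate mergers between homologous consensus intervals are scored by

    E = -l + alpha * N_c + beta * N_m

where ``l`` is the alignment length, ``N_c`` the number of additional
blocks the merger would create (cuts that do not coincide with block ends)
and ``N_m`` the number of polymorphism events in the consensus-consensus
alignment.  Only negative-energy mergers are performed, most negative
first.  With the defaults (alpha=100, beta=10) no merger joins consensus
sequences more than 10 % diverged, since for a cut-free match
E = l * (beta * d - 1).

``L_min`` keeps graph topology above a minimal scale: a hit boundary within
``L_min`` of a block end snaps to that end, absorbing the short flank into
the merged alignment as a terminal indel, and hits shorter than ``L_min``
are never considered.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .graph import (FORWARD, REVERSE, GraphError, Pangraph, derive_edits,
                    recompute_consensus, split_block)
from .guide_tree import MergeJob, SketchParams, build_guide_tree, merge_schedule
from .kernel import (Hit, KernelConfig, align_consensus_sets, cigar_stats,
                     parse_cigar)
from ._seq import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeParams:
    """Pseudo-energy parameters, in basepair-equivalents."""

    alpha: float = 100.0   # cost per additional block created
    beta: float = 10.0     # cost per consensus polymorphism
    l_min: int = 100       # minimal block length (bp)
    round_cap: int = 64    # safety cap on merge rounds per pairwise job

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.l_min < 0:
            raise ValueError("alpha, beta and l_min must be >= 0")


def pseudo_energy(length: float, n_cuts: int, n_poly: float,
                  params: MergeParams = MergeParams()) -> float:
    """E = -l + alpha*N_c + beta*N_m; a merger is admissible iff E < 0."""
    if length < 0 or n_cuts < 0 or n_poly < 0:
        raise ValueError("pseudo-energy arguments must be >= 0")
    return -length + params.alpha * n_cuts + params.beta * n_poly


@dataclass
class MergeCandidate:
    hit: Hit
    qcuts: tuple[int, int]   # snapped query interval
    rcuts: tuple[int, int]   # snapped reference interval
    n_cuts: int
    n_poly: int
    energy: float

    @property
    def block_pair(self) -> tuple[str, str]:
        return (self.hit.query_block, self.hit.ref_block)


def _snap(start: int, end: int, length: int, l_min: int) -> tuple[int, int]:
    s = 0 if start < l_min else start
    e = length if length - end < l_min else end
    return s, e


def split_hit_at_long_indels(hit: Hit, l_min: int) -> list[Hit]:
    """Subdivide a hit at indels of length >= ``l_min``.

    Aligners happily chain through large insertions/deletions (and encode
    inversions as paired giant indels), but structural variation at or
    above the minimal block scale belongs in graph topology, not inside a
    block alignment.  Each well-aligned stretch between such indels becomes
    its own hit; the indel gaps themselves are left unmerged.
    """
    ops = parse_cigar(hit.cigar)
    if not any(op in "ID" and n >= l_min for n, op in ops):
        return [hit]
    pieces: list[tuple[int, int, int, int, str]] = []
    r = qa = 0           # ref / query-alignment progress
    r0 = qa0 = 0
    cur: list[str] = []
    for n, op in ops:
        if op in "ID" and n >= l_min:
            if cur:
                pieces.append((r0, r, qa0, qa, "".join(cur)))
            if op == "D":
                r += n
            else:
                qa += n
            r0, qa0 = r, qa
            cur = []
            continue
        cur.append(f"{n}{op}")
        if op in "=XMD":
            r += n
        if op in "=XMI":
            qa += n
    if cur:
        pieces.append((r0, r, qa0, qa, "".join(cur)))
    out = []
    for r0, r1, qa0, qa1, cg in pieces:
        if r1 == r0 or qa1 == qa0:
            continue
        if hit.strand == FORWARD:
            qs, qe = hit.qstart + qa0, hit.qstart + qa1
        else:  # cigar walks the reverse-complemented query
            qs, qe = hit.qend - qa1, hit.qend - qa0
        cols, matches, _ = cigar_stats(cg)
        out.append(Hit(hit.query_block, hit.ref_block, qs, qe,
                       hit.rstart + r0, hit.rstart + r1, hit.strand,
                       cg, matches, cols))
    return out


def candidate_from_hit(hit: Hit, graph: Pangraph,
                       params: MergeParams = MergeParams()
                       ) -> MergeCandidate | None:
    """Score a hit; returns None for stale or degenerate hits."""
    if hit.query_block not in graph.blocks or hit.ref_block not in graph.blocks:
        return None
    lq = len(graph.blocks[hit.query_block].consensus)
    lr = len(graph.blocks[hit.ref_block].consensus)
    qs, qe = _snap(hit.qstart, hit.qend, lq, params.l_min)
    rs, re_ = _snap(hit.rstart, hit.rend, lr, params.l_min)
    if qe - qs < params.l_min or re_ - rs < params.l_min:
        return None
    if hit.query_block == hit.ref_block:
        # self-duplication: the two intervals must be disjoint after snapping
        if max(qs, rs) < min(qe, re_):
            return None
    n_cuts = sum(0 < c < lq for c in (qs, qe)) + \
        sum(0 < c < lr for c in (rs, re_))
    cols, _, events = cigar_stats(hit.cigar)
    energy = pseudo_energy(cols, n_cuts, events, params)
    return MergeCandidate(hit, (qs, qe), (rs, re_), n_cuts, events, energy)


def select_mergers(candidates: list[MergeCandidate]) -> list[MergeCandidate]:
    """Admissible candidates, most negative energy first, conflict-free.

    Once a block is consumed by an applied merger in a round, remaining
    candidates touching it are discarded; the homology is rediscovered by
    the re-alignment of the next round.
    """
    admissible = [c for c in candidates if c.energy < 0]
    admissible.sort(key=lambda c: (
        c.energy, -c.hit.length,
        min(c.block_pair), max(c.block_pair),
        c.qcuts, c.rcuts, -c.hit.strand))
    out = []
    consumed: set[str] = set()
    for c in admissible:
        if c.hit.query_block in consumed or c.hit.ref_block in consumed:
            continue
        out.append(c)
        consumed.update(c.block_pair)
    return out


def apply_merger(graph: Pangraph, cand: MergeCandidate,
                 params: MergeParams = MergeParams()) -> str:
    """Split both blocks at the snapped hit boundaries and fuse the
    homologous sub-blocks into one; returns the fused block id.

    The reference-side consensus hosts the fusion.  Incoming members are
    re-expressed against it by optimal global alignment (reverse hits flip
    the incoming occurrences' strands), then the consensus is majority-
    revoted.  Round-trip reconstruction is preserved exactly.
    """
    hit = cand.hit
    qid, rid = hit.query_block, hit.ref_block
    if qid not in graph.blocks or rid not in graph.blocks:
        raise GraphError("stale merge candidate")
    (qs, qe), (rs, re_) = cand.qcuts, cand.rcuts

    if qid == rid:
        lq = len(graph.blocks[qid].consensus)
        cuts = sorted({c for c in (qs, qe, rs, re_) if 0 < c < lq})
        pieces = split_block(graph, qid, cuts)
        bounds = [0] + cuts + [lq]
        q_piece = pieces[bounds.index(qs)]
        r_piece = pieces[bounds.index(rs)]
    else:
        lq = len(graph.blocks[qid].consensus)
        lr = len(graph.blocks[rid].consensus)
        q_pieces = split_block(graph, qid, [c for c in (qs, qe) if 0 < c < lq])
        q_piece = q_pieces[_bounds_of(graph, q_pieces).index(qs)]
        r_pieces = split_block(graph, rid, [c for c in (rs, re_) if 0 < c < lr])
        r_piece = r_pieces[_bounds_of(graph, r_pieces).index(rs)]

    _fuse(graph, host=r_piece, guest=q_piece, strand=hit.strand)
    recompute_consensus(graph, r_piece)
    return r_piece


def _total(graph: Pangraph, pieces: list[str]) -> int:
    return sum(len(graph.blocks[p].consensus) for p in pieces)


def _bounds_of(graph: Pangraph, pieces: list[str]) -> list[int]:
    """Start offsets of consecutive pieces of a split block."""
    out = []
    acc = 0
    for p in pieces:
        out.append(acc)
        acc += len(graph.blocks[p].consensus)
    return out


def _fuse(graph: Pangraph, host: str, guest: str, strand: int) -> None:
    """Move all occurrences of ``guest`` into ``host``.

    For reverse hits each incoming member enters reverse-complemented and
    with flipped strand, so every genome still reads exactly as before.
    """
    hblk = graph.blocks[host]
    gblk = graph.blocks[guest]
    for nid in list(gblk.node_ids):
        node = graph.nodes[nid]
        seg = graph.node_segment(node)
        if strand == REVERSE:
            seg = revcomp(seg)
            node.strand = -node.strand
        node.edits = derive_edits(seg, hblk.consensus)
        node.block_id = host
        hblk.node_ids.append(nid)
    gblk.node_ids.clear()
    del graph.blocks[guest]


def merge_round(graph: Pangraph, cfg: KernelConfig,
                params: MergeParams) -> int:
    """One align -> rank -> apply sweep over the whole graph.

    Returns the number of mergers applied.  The alignment includes the
    self-comparison of the block set, so duplications within a genome are
    found and merged too.
    """
    blocks = sorted((b.id, b.consensus) for b in graph.blocks.values())
    hits = align_consensus_sets(blocks, blocks, cfg)
    cands = []
    for h in hits:
        for sub in split_hit_at_long_indels(h, params.l_min):
            if sub.length < params.l_min:
                continue
            c = candidate_from_hit(sub, graph, params)
            if c is not None:
                cands.append(c)
    applied = 0
    for cand in select_mergers(cands):
        apply_merger(graph, cand, params)
        applied += 1
    return applied


def pairwise_graph_merge(graph_a: Pangraph, graph_b: Pangraph | None,
                         cfg: KernelConfig = KernelConfig(),
                         params: MergeParams = MergeParams()) -> Pangraph:
    """Merge two graphs with disjoint genome sets into one.

    The union graph is swept with align/rank/apply rounds until no
    negative-energy merger remains, then transitive chains are compacted.
    Passing ``graph_b=None`` sweeps a single graph to its fixed point
    (used for the initial self-merge of duplicated sequence).
    """
    g = _union(graph_a, graph_b)
    g.renumber()
    for _ in range(params.round_cap):
        if merge_round(g, cfg, params) == 0:
            break
        g.renumber()
    else:
        warnings.warn("merge loop hit the round cap before reaching a "
                      "fixed point; graph may be under-merged",
                      RuntimeWarning, stacklevel=2)
    from .marginalize import merge_transitive
    merge_transitive(g)
    g.renumber()
    return g


def _union(a: Pangraph, b: Pangraph | None) -> Pangraph:
    g = Pangraph()
    for src in (a,) if b is None else (a, b):
        if set(src.paths) & set(g.paths):
            raise GraphError("genome sets of merged graphs must be disjoint")
        _copy_into(g, src)
    return g


def _copy_into(g: Pangraph, src: Pangraph) -> None:
    from .graph import Path as _Path
    id_map = {bid: g.add_block(src.blocks[bid].consensus).id
              for bid in sorted(src.blocks)}
    for name in sorted(src.paths):
        path = src.paths[name]
        new_ids = []
        for nid in path.node_ids:
            node = src.nodes[nid]
            new = g.add_node(g.blocks[id_map[node.block_id]],
                             node.path_name, node.strand, list(node.edits))
            new_ids.append(new.id)
        g.paths[name] = _Path(name, new_ids, path.circular, path.offset)


def execute_schedule(initial: dict[str, Pangraph], jobs: list[MergeJob],
                     cfg: KernelConfig, params: MergeParams,
                     order: list[int] | None = None) -> Pangraph:
    """Run merge jobs (any dependency-respecting order gives the same graph)."""
    if not jobs:
        (g,) = initial.values()
        g.renumber()
        return g
    results: dict[tuple[str, ...], Pangraph] = {
        (name,): g for name, g in initial.items()}
    sequence = jobs if order is None else [jobs[i] for i in order]
    done: set[int] = set()
    for job in sequence:
        if any(d not in done for d in job.depends_on):
            raise ValueError("merge job order violates dependencies")
        ga = results.pop(job.left_leaves)
        gb = results.pop(job.right_leaves)
        results[job.leaves] = pairwise_graph_merge(ga, gb, cfg, params)
        done.add(job.id)
    (graph,) = results.values()
    return graph


def build_pangraph(genomes: list[tuple[str, str]],
                   sketch: SketchParams = SketchParams(),
                   cfg: KernelConfig = KernelConfig(),
                   params: MergeParams = MergeParams(),
                   circular: bool = True,
                   job_order: list[int] | None = None) -> Pangraph:
    """Align a set of genomes into a pangenome graph.

    Starts from one single-block graph per genome and merges pairs of
    graphs along the post-order schedule of the balanced guide tree.
    """
    names = [n for n, _ in genomes]
    if len(set(names)) != len(names):
        raise GraphError("genome names must be unique")
    if not genomes:
        raise GraphError("need at least one genome")
    for n, s in genomes:
        if not s:
            raise GraphError(f"genome {n!r} has empty sequence")
    logger.info("building pangraph: %d genomes, kernel=%s/%s, "
                "alpha=%g beta=%g l_min=%d", len(genomes), cfg.kernel,
                cfg.preset, params.alpha, params.beta, params.l_min)
    initial = {}
    for name, seq in genomes:
        g = Pangraph()
        g.add_genome(name, seq, circular=circular)
        # collapse internal duplications of the single genome first
        initial[name] = pairwise_graph_merge(g, None, cfg, params)
    if len(genomes) == 1:
        return initial[names[0]]
    tree = build_guide_tree(genomes, sketch)
    jobs = merge_schedule(tree)
    graph = execute_schedule(initial, jobs, cfg, params, order=job_order)
    return graph
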
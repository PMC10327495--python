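"""Projection of a graph onto a genome subset, without re-alignment.

Marginalization removes all other paths, prunes emptied blocks, revotes
the consensus of surviving blocks from their remaining members and fuses
*transitive* chains: pairs of blocks that are adjacent, in the same
relative orientation, in every single occurrence.  The result approximates
the graph one would have built directly for the subset, at a fraction of
the cost.
"""
from __future__ import annotations

from .graph import (FORWARD, REVERSE, Edit, GraphError, Pangraph,
                    _edit_sort_key, _merge_adjacent, flip_block,
                    recompute_consensus)


def marginalize(graph: Pangraph, keep: set[str]) -> Pangraph:
    """Project onto the genomes in ``keep`` (must be existing path names)."""
    unknown = set(keep) - set(graph.paths)
    if unknown:
        raise GraphError(f"unknown genome name(s): {sorted(unknown)}")
    if not keep:
        raise GraphError("keep set must be non-empty")
    from .merge import _union
    g = _union(graph, None)  # deep copy
    for name in sorted(set(g.paths) - set(keep)):
        path = g.paths.pop(name)
        for nid in path.node_ids:
            node = g.nodes.pop(nid)
            g.blocks[node.block_id].node_ids.remove(nid)
    for bid in [b for b, blk in g.blocks.items() if blk.depth == 0]:
        del g.blocks[bid]
    for bid in sorted(g.blocks):
        recompute_consensus(g, bid)
    merge_transitive(g)
    g.renumber()
    return g


def merge_transitive(graph: Pangraph) -> None:
    """Fuse chains of blocks that are unconditionally adjacent.

    Two distinct blocks are fused (consensus concatenation, edits lifted)
    when an end of one is joined to an end of the other in *every*
    occurrence of both — such a junction carries no structural information.
    Repeats to a fixed point.  A circular single-block path adjacent to
    itself is deliberately left alone.
    """
    while True:
        pair = _find_fusable(graph)
        if pair is None:
            return
        _fuse_pair(graph, *pair)


def _junctions(graph: Pangraph):
    """Oriented junctions as ``(end_out, end_in, path_name, i, j)``.

    An end is ``(block_id, side)`` with side 'L' (consensus start) or 'R'
    (consensus end).  A forward step exposes its R end to its successor; a
    reverse step exposes its L end.  Circular paths include the wrap
    junction from the last step back to the first.
    """
    out = []
    for name in sorted(graph.paths):
        path = graph.paths[name]
        n = len(path.node_ids)
        limit = n if path.circular and n > 1 else n - 1
        for i in range(limit):
            j = (i + 1) % n
            u = graph.nodes[path.node_ids[i]]
            v = graph.nodes[path.node_ids[j]]
            e_out = (u.block_id, "R" if u.strand == FORWARD else "L")
            e_in = (v.block_id, "L" if v.strand == FORWARD else "R")
            out.append((e_out, e_in, name, i, j))
    return out


def _find_fusable(graph: Pangraph):
    links: dict[tuple, set[tuple]] = {}
    counts: dict[tuple, int] = {}
    for e_out, e_in, *_ in _junctions(graph):
        links.setdefault(e_out, set()).add(e_in)
        links.setdefault(e_in, set()).add(e_out)
        counts[e_out] = counts.get(e_out, 0) + 1
        counts[e_in] = counts.get(e_in, 0) + 1
    for end in sorted(links):
        partners = links[end]
        if len(partners) != 1:
            continue
        (other,) = partners
        if other[0] == end[0]:
            continue  # self-adjacency (incl. circular single-block path)
        if links[other] != {end}:
            continue
        da = graph.blocks[end[0]].depth
        db = graph.blocks[other[0]].depth
        if da != db or counts[end] != da or counts[other] != db:
            continue
        return end, other
    return None


def _fuse_pair(graph: Pangraph, end_a: tuple, end_b: tuple) -> None:
    """Fuse the two blocks joined at ``end_a``/``end_b`` by concatenation,
    preserving every path byte-for-byte (including circular rotations)."""
    # normalize to x.R joined to y.L so the fusion reads x-then-y forward
    xa, sa = end_a
    xb, sb = end_b
    if sa == "L":
        flip_block(graph, xa)
        sa = "R"
    if sb == "R":
        flip_block(graph, xb)
    x, y = xa, xb

    bx = graph.blocks[x]
    by = graph.blocks[y]
    lx = len(bx.consensus)
    fused = graph.add_block(bx.consensus + by.consensus)

    # After normalization each junction instance is either a forward pair
    # (x,+) then (y,+), or a reverse pair (y,-) then (x,-).
    # pairs identified by node ids: splices below shift indices around
    pairs: dict[str, list[tuple[int, int, int]]] = {}
    for e_out, e_in, name, i, j in _junctions(graph):
        nid_i = graph.paths[name].node_ids[i]
        nid_j = graph.paths[name].node_ids[j]
        if e_out == (x, "R") and e_in == (y, "L"):
            pairs.setdefault(name, []).append((nid_i, nid_j, FORWARD))
        elif e_out == (y, "L") and e_in == (x, "R"):
            pairs.setdefault(name, []).append((nid_i, nid_j, REVERSE))

    for name, plist in pairs.items():
        path = graph.paths[name]
        for aid, bid, strand in plist:
            n = len(path.node_ids)
            i = path.node_ids.index(aid)
            j = path.node_ids.index(bid)
            a = graph.nodes[aid]
            b = graph.nodes[bid]
            if strand == FORWARD:
                u, v = a, b          # u on x, v on y
            else:
                v, u = a, b          # path shows (y,-) then (x,-)
            shifted = [Edit(e.kind, e.position + lx, e.payload)
                       for e in v.edits]
            edits = _merge_adjacent(sorted(u.edits + shifted,
                                           key=_edit_sort_key))
            new = graph.add_node(fused, name, strand, edits)
            if j == i + 1:
                path.node_ids[i:j + 1] = [new.id]
            else:  # wrap: i == n-1, j == 0; the concatenation rotates
                last_len = len(graph.node_segment(a))
                total = sum(len(graph.node_segment(graph.nodes[nid]))
                            for nid in path.node_ids)
                path.node_ids = [new.id] + path.node_ids[1:n - 1]
                path.offset = (path.offset + last_len) % total
            graph.drop_node(u)
            graph.drop_node(v)

    if graph.blocks[x].node_ids or graph.blocks[y].node_ids:
        raise GraphError("transitive fusion left orphan occurrences")
    del graph.blocks[x]
    del graph.blocks[y]
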
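"""Core pangenome-graph data structures.

A :class:`Pangraph` stores a set of *blocks* (directed nodes holding a
consensus sequence for a group of homologous segments) and *paths* (each
input genome as an ordered, oriented walk over blocks).  Every visit of a
genome to a block is an occurrence carrying the edits (substitutions,
insertions, deletions) that turn the block consensus into that genome's
segment.  Blocks therefore encapsulate a multiple alignment modelled as a
star phylogeny: one consensus, independent per-member edits.

Coordinates are 0-based and half-open on the block consensus.  An insertion
at position ``p`` inserts *before* consensus base ``p`` (``p == len`` appends).
Edits of one occurrence are sorted and non-overlapping.

The defining invariant is exact round-tripping: concatenating the edited
(and, for reverse occurrences, reverse-complemented) segments along a path
reproduces the input genome byte for byte.  Circular paths additionally
carry a rotation offset so the stored walk may start anywhere on the
chromosome.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from ._seq import revcomp

SUB = "sub"
INS = "ins"
DEL = "del"

FORWARD = 1
REVERSE = -1


class GraphError(ValueError):
    """Raised when an operation would corrupt the graph."""


@dataclass(frozen=True)
class Edit:
    """One difference of a member segment relative to the block consensus.

    ``payload`` holds the substituted/inserted bases for ``sub``/``ins``
    and the deleted length (bp) for ``del``.
    """

    kind: str
    position: int
    payload: str | int

    def __post_init__(self):
        if self.kind not in (SUB, INS, DEL):
            raise GraphError(f"unknown edit kind {self.kind!r}")
        if self.position < 0:
            raise GraphError("edit position must be >= 0")
        if self.kind == DEL:
            if not isinstance(self.payload, int) or self.payload < 1:
                raise GraphError("deletion length must be an int >= 1")
        elif not isinstance(self.payload, str) or len(self.payload) < 1:
            raise GraphError("sub/ins payload must be a non-empty string")

    @property
    def span(self) -> int:
        """Number of consensus bases consumed by this edit."""
        if self.kind == INS:
            return 0
        if self.kind == DEL:
            return self.payload
        return len(self.payload)


def _edit_sort_key(e: Edit):
    # insertions at position p precede edits consuming consensus from p
    return (e.position, 0 if e.kind == INS else 1)


@dataclass
class Node:
    """One occurrence: a single visit of a genome path to a block."""

    id: int
    block_id: str
    path_name: str
    strand: int
    edits: list[Edit] = field(default_factory=list)


@dataclass
class Block:
    id: str
    consensus: str
    node_ids: list[int] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.node_ids)


@dataclass
class Path:
    name: str
    node_ids: list[int] = field(default_factory=list)
    circular: bool = True
    offset: int = 0  # genome = concat(segments)[offset:] + [:offset]


class Pangraph:
    """Blocks plus paths; edges are implicit in path adjacencies."""

    def __init__(self):
        self.blocks: dict[str, Block] = {}
        self.paths: dict[str, Path] = {}
        self.nodes: dict[int, Node] = {}
        self._next_block = itertools.count()
        self._next_node = itertools.count()

    # -- construction -----------------------------------------------------

    def new_block_id(self) -> str:
        return f"b{next(self._next_block):07d}"

    def add_block(self, consensus: str, block_id: str | None = None) -> Block:
        if not consensus:
            raise GraphError("block consensus must be non-empty")
        bid = block_id if block_id is not None else self.new_block_id()
        if bid in self.blocks:
            raise GraphError(f"duplicate block id {bid}")
        blk = Block(bid, consensus)
        self.blocks[bid] = blk
        return blk

    def add_node(self, block: Block, path_name: str, strand: int,
                 edits: list[Edit] | None = None) -> Node:
        node = Node(next(self._next_node), block.id, path_name, strand,
                    list(edits) if edits else [])
        self.nodes[node.id] = node
        block.node_ids.append(node.id)
        return node

    def add_genome(self, name: str, seq: str, circular: bool = True) -> Path:
        """Add one genome as a fresh single-block path."""
        if name in self.paths:
            raise GraphError(f"duplicate genome name {name!r}")
        if not seq:
            raise GraphError(f"genome {name!r} has empty sequence")
        blk = self.add_block(seq.upper())
        node = self.add_node(blk, name, FORWARD)
        path = Path(name, [node.id], circular=circular)
        self.paths[name] = path
        return path

    @classmethod
    def from_genomes(cls, genomes, circular: bool = True) -> "Pangraph":
        g = cls()
        for name, seq in genomes:
            g.add_genome(name, seq, circular=circular)
        return g

    # -- basic queries -----------------------------------------------------

    def block_of(self, node: Node) -> Block:
        return self.blocks[node.block_id]

    def node_index(self) -> dict[int, int]:
        """Map node id -> ordinal of the step within its path."""
        idx = {}
        for path in self.paths.values():
            for i, nid in enumerate(path.node_ids):
                idx[nid] = i
        return idx

    def node_segment(self, node: Node) -> str:
        """Member segment in forward consensus coordinates (no strand flip)."""
        return apply_edits(self.blocks[node.block_id].consensus, node.edits)

    def pangenome_length(self) -> int:
        return sum(len(b.consensus) for b in self.blocks.values())

    def genome_length(self, name: str) -> int:
        return len(self.reconstruct(name))

    # -- reconstruction ----------------------------------------------------

    def reconstruct(self, name: str) -> str:
        if name not in self.paths:
            raise GraphError(f"unknown path name {name!r}")
        path = self.paths[name]
        parts = []
        for nid in path.node_ids:
            node = self.nodes[nid]
            seg = self.node_segment(node)
            parts.append(seg if node.strand == FORWARD else revcomp(seg))
        s = "".join(parts)
        if path.circular and path.offset:
            o = path.offset % len(s)
            s = s[o:] + s[:o]
        return s

    # -- bookkeeping -------------------------------------------------------

    def drop_node(self, node: Node) -> None:
        blk = self.blocks[node.block_id]
        blk.node_ids.remove(node.id)
        del self.nodes[node.id]

    def drop_block(self, block_id: str) -> None:
        blk = self.blocks.pop(block_id)
        for nid in blk.node_ids:
            self.nodes.pop(nid, None)

    def renumber(self) -> None:
        """Assign canonical block ids.

        Blocks are keyed by their first occurrence in path order (every
        occurrence belongs to exactly one block, so the key is unique and
        purely content-derived).  This makes block ids, and therefore all
        downstream orderings and exports, independent of construction
        history — required for schedule independence.
        """
        idx = self.node_index()

        def key(blk: Block):
            return min((self.nodes[n].path_name, idx[n]) for n in blk.node_ids)

        order = sorted(self.blocks.values(), key=key)
        mapping = {blk.id: f"B{i:06d}" for i, blk in enumerate(order, 1)}
        new_blocks = {}
        for blk in order:
            blk.id = mapping[blk.id]
            blk.node_ids.sort(key=lambda n: (self.nodes[n].path_name, idx[n]))
            new_blocks[blk.id] = blk
        self.blocks = new_blocks
        for node in self.nodes.values():
            node.block_id = mapping[node.block_id]

    def validate(self) -> None:
        """Check cross-reference bijection and edit consistency (testing aid)."""
        seen = set()
        for path in self.paths.values():
            for nid in path.node_ids:
                if nid in seen:
                    raise GraphError(f"node {nid} appears twice in paths")
                seen.add(nid)
                node = self.nodes[nid]
                if node.path_name != path.name:
                    raise GraphError("node/path name mismatch")
                if node.block_id not in self.blocks:
                    raise GraphError("node references missing block")
                if nid not in self.blocks[node.block_id].node_ids:
                    raise GraphError("node missing from its block")
        for blk in self.blocks.values():
            if not blk.consensus:
                raise GraphError(f"block {blk.id} has empty consensus")
            if blk.depth < 1:
                raise GraphError(f"block {blk.id} has no occurrences")
            for nid in blk.node_ids:
                if nid not in seen:
                    raise GraphError("block references node absent from paths")
                check_edits(blk.consensus, self.nodes[nid].edits)


# -- edit application ------------------------------------------------------


def check_edits(consensus: str, edits: list[Edit]) -> None:
    L = len(consensus)
    prev_end = -1
    prev = None
    for e in sorted(edits, key=_edit_sort_key):
        if e.position > L or e.position + e.span > L:
            raise GraphError(f"edit {e} outside consensus of length {L}")
        if e.position < prev_end or (e.position == prev_end and
                                     prev is not None and
                                     e.kind == INS and prev.kind == INS):
            raise GraphError(f"overlapping edits at {e.position}")
        prev_end = max(prev_end, e.position + e.span) if e.kind != INS \
            else max(prev_end, e.position)
        prev = e


def apply_edits(consensus: str, edits: list[Edit]) -> str:
    """Apply sorted, non-overlapping edits to a consensus sequence."""
    if not edits:
        return consensus
    out = []
    i = 0
    for e in sorted(edits, key=_edit_sort_key):
        if e.position < i or e.position + e.span > len(consensus):
            raise GraphError(f"edit {e} inconsistent with consensus")
        out.append(consensus[i:e.position])
        i = e.position
        if e.kind == INS:
            out.append(e.payload)
        elif e.kind == SUB:
            out.append(e.payload)
            i += len(e.payload)
        else:
            i += e.payload
    out.append(consensus[i:])
    return "".join(out)


def _merge_adjacent(edits: list[Edit]) -> list[Edit]:
    """Merge contiguous same-kind edits (e.g. split insertion runs)."""
    out: list[Edit] = []
    for e in edits:
        if out:
            p = out[-1]
            if p.kind == e.kind == INS and p.position == e.position:
                out[-1] = replace(p, payload=p.payload + e.payload)
                continue
            if p.kind == e.kind == SUB and p.position + len(p.payload) == e.position:
                out[-1] = replace(p, payload=p.payload + e.payload)
                continue
            if p.kind == e.kind == DEL and p.position + p.payload == e.position:
                out[-1] = replace(p, payload=p.payload + e.payload)
                continue
        out.append(e)
    return out


def derive_edits(member: str, consensus: str) -> list[Edit]:
    """Edits turning ``consensus`` into ``member`` via optimal global alignment."""
    if member == consensus:
        return []
    if not member:
        return [Edit(DEL, 0, len(consensus))]
    res = edlib.align(member, consensus, task="path", mode="NW")
    edits: list[Edit] = []
    cpos = 0
    mpos = 0
    n = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            n = n * 10 + int(ch)
            continue
        if ch == "=":
            cpos += n
            mpos += n
        elif ch == "X":
            edits.append(Edit(SUB, cpos, member[mpos:mpos + n]))
            cpos += n
            mpos += n
        elif ch == "I":  # present in member, absent in consensus
            edits.append(Edit(INS, cpos, member[mpos:mpos + n]))
            mpos += n
        elif ch == "D":  # consensus bases deleted in member
            edits.append(Edit(DEL, cpos, n))
            cpos += n
        else:  # pragma: no cover
            raise GraphError(f"unexpected cigar op {ch!r}")
        n = 0
    return _merge_adjacent(edits)


# -- implied multiple alignment -------------------------------------------


def expand_alignment(consensus: str, edits_per_member: list[list[Edit]]
                     ) -> tuple[str, list[str]]:
    """Materialize the implied gapped alignment of a block.

    Returns the gapped consensus row and one gapped row per member.  Member
    insertions at the same consensus offset are left-aligned within a shared
    gap slot (a deliberate, deterministic naive placement; ``polish`` cleans
    residual artefacts).
    """
    L = len(consensus)
    ins_len = np.zeros(L + 1, dtype=int)
    per_member = []
    for edits in edits_per_member:
        ins_at: dict[int, str] = {}
        chars = list(consensus)
        for e in sorted(edits, key=_edit_sort_key):
            if e.kind == INS:
                ins_at[e.position] = ins_at.get(e.position, "") + e.payload
            elif e.kind == SUB:
                for j, ch in enumerate(e.payload):
                    chars[e.position + j] = ch
            else:
                for j in range(e.payload):
                    chars[e.position + j] = "-"
        for p, s in ins_at.items():
            ins_len[p] = max(ins_len[p], len(s))
        per_member.append((ins_at, chars))

    def build(ins_at, chars):
        row = []
        for p in range(L + 1):
            if ins_len[p]:
                s = ins_at.get(p, "")
                row.append(s + "-" * (ins_len[p] - len(s)))
            if p < L:
                row.append(chars[p])
        return "".join(row)

    cons_row = build({}, list(consensus))
    rows = [build(ins_at, chars) for ins_at, chars in per_member]
    return cons_row, rows


_GAP = ord("-")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _majority_row(rows: list[str]) -> np.ndarray:
    """Column-wise majority over alignment rows.

    Ties between bases resolve to the lexicographically smallest base; a gap
    wins only with a strict majority over the best base.  Ambiguity codes
    never vote unless a column holds nothing but ambiguity codes.
    """
    M = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    M = M.reshape(len(rows), -1)
    ncols = M.shape[1]
    base_counts = np.stack([(M == b).sum(axis=0) for b in _BASES])
    gap_counts = (M == _GAP).sum(axis=0)
    best_idx = base_counts.argmax(axis=0)          # first max = lexicographic
    best_cnt = base_counts.max(axis=0)
    out = _BASES[best_idx].copy()
    out[gap_counts > best_cnt] = _GAP
    # columns with no ACGT vote at all: ambiguity codes (or pure gaps) decide
    nobase = best_cnt == 0
    if nobase.any():
        for c in np.flatnonzero(nobase):
            col = M[:, c]
            syms = sorted(bytes([s]) for s in col if s != _GAP)
            if not syms:
                out[c] = _GAP
                continue
            vals, counts = np.unique(np.array([s[0] for s in syms]),
                                     return_counts=True)
            best = vals[counts.argmax()]
            out[c] = _GAP if gap_counts[c] > counts.max() else best
    return out


def _edits_from_rows(cons_row: np.ndarray, member_row: str) -> list[Edit]:
    """Re-express one member against a (gapped) consensus row."""
    mem = np.frombuffer(member_row.encode("ascii"), dtype=np.uint8)
    cgap = cons_row == _GAP
    mgap = mem == _GAP
    # consensus coordinate of each column = number of consensus bases before it
    ccoord = np.concatenate([[0], np.cumsum(~cgap)])[:-1]
    edits: list[Edit] = []
    i = 0
    n = len(mem)
    while i < n:
        if cgap[i] and mgap[i]:
            i += 1
            continue
        if cgap[i]:                          # member base in consensus gap
            j = i
            buf = []
            while j < n and cgap[j] and not mgap[j]:
                buf.append(chr(mem[j]))
                j += 1
            edits.append(Edit(INS, int(ccoord[i]), "".join(buf)))
            i = j
        elif mgap[i]:                        # consensus base deleted in member
            j = i
            while j < n and not cgap[j] and mgap[j]:
                j += 1
            edits.append(Edit(DEL, int(ccoord[i]), int(np.sum(~cgap[i:j]))))
            i = j
        elif mem[i] != cons_row[i]:
            j = i
            buf = []
            while j < n and not cgap[j] and not mgap[j] and mem[j] != cons_row[j]:
                buf.append(chr(mem[j]))
                j += 1
            edits.append(Edit(SUB, int(ccoord[i]), "".join(buf)))
            i = j
        else:
            i += 1
    return _merge_adjacent(sorted(edits, key=_edit_sort_key))


def recompute_consensus(graph: Pangraph, block_id: str) -> None:
    """Majority-revote the consensus of a block and re-express all edits.

    Member sequences are strictly conserved; only the internal
    consensus/edit decomposition changes.
    """
    blk = graph.blocks[block_id]
    nodes = [graph.nodes[n] for n in blk.node_ids]
    if len(nodes) == 1:
        node = nodes[0]
        seg = graph.node_segment(node)
        if seg:
            blk.consensus = seg
            node.edits = []
        return
    _, rows = expand_alignment(blk.consensus, [n.edits for n in nodes])
    maj = _majority_row(rows)
    new_cons = maj[maj != _GAP].tobytes().decode("ascii")
    if not new_cons:        # degenerate: majority deletes everything
        return
    blk.consensus = new_cons
    for node, row in zip(nodes, rows):
        node.edits = _edits_from_rows(maj, row)


# -- structural operations -------------------------------------------------


def split_block(graph: Pangraph, block_id: str, cuts: list[int]) -> list[str]:
    """Split a block at consensus offsets, rewiring all paths.

    Returns the new block ids in consensus order.  With no cuts the graph is
    unchanged and the original id is returned.
    """
    blk = graph.blocks[block_id]
    L = len(blk.consensus)
    cuts = sorted(cuts)
    if len(set(cuts)) != len(cuts):
        raise GraphError("duplicate cut positions")
    if any(not 0 < c < L for c in cuts):
        raise GraphError(f"cut positions must lie strictly inside (0, {L})")
    if not cuts:
        return [block_id]
    bounds = [0] + cuts + [L]
    pieces = [graph.add_block(blk.consensus[a:b])
              for a, b in zip(bounds[:-1], bounds[1:])]

    idx = graph.node_index()
    for nid in list(blk.node_ids):
        node = graph.nodes[nid]
        sub_edits = _partition_edits(node.edits, bounds)
        new_nodes = [graph.add_node(piece, node.path_name, node.strand, ed)
                     for piece, ed in zip(pieces, sub_edits)]
        if node.strand == REVERSE:
            new_nodes = new_nodes[::-1]
        path = graph.paths[node.path_name]
        i = idx[nid]
        path.node_ids[i:i + 1] = [n.id for n in new_nodes]
        idx = graph.node_index()  # indices shifted
        del graph.nodes[nid]
    del graph.blocks[block_id]
    return [p.id for p in pieces]


def _partition_edits(edits: list[Edit], bounds: list[int]) -> list[list[Edit]]:
    """Distribute edits over consecutive consensus intervals.

    Edits spanning a cut are split at the cut; an insertion exactly at a cut
    is assigned to the left piece (appended at its end).
    """
    out: list[list[Edit]] = [[] for _ in range(len(bounds) - 1)]
    for e in sorted(edits, key=_edit_sort_key):
        for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            if e.kind == INS:
                # position in (a, b], except the leftmost piece also takes 0
                if (a < e.position <= b) or (a == 0 and e.position == 0):
                    out[k].append(replace(e, position=e.position - a))
                    break
            else:
                s, t = e.position, e.position + e.span
                lo, hi = max(s, a), min(t, b)
                if lo < hi:
                    if e.kind == DEL:
                        out[k].append(Edit(DEL, lo - a, hi - lo))
                    else:
                        out[k].append(Edit(SUB, lo - a,
                                           e.payload[lo - s:hi - s]))
    return out


def flip_block(graph: Pangraph, block_id: str) -> None:
    """Reverse-complement a block's orientation convention in place."""
    blk = graph.blocks[block_id]
    L = len(blk.consensus)
    blk.consensus = revcomp(blk.consensus)
    for nid in blk.node_ids:
        node = graph.nodes[nid]
        node.strand = -node.strand
        new = []
        for e in node.edits:
            if e.kind == INS:
                new.append(Edit(INS, L - e.position, revcomp(e.payload)))
            elif e.kind == SUB:
                new.append(Edit(SUB, L - e.position - len(e.payload),
                                revcomp(e.payload)))
            else:
                new.append(Edit(DEL, L - e.position - e.payload, e.payload))
        node.edits = sorted(new, key=_edit_sort_key)


def polish_block(graph: Pangraph, block_id: str, max_rounds: int = 4) -> None:
    """Iteratively refine a block's internal alignment.

    Each round re-derives every member's edits by optimal global pairwise
    alignment against the current consensus and then majority-revotes the
    consensus.  This removes artefacts (e.g. double-counted indels) left by
    progressive merging.  Member sequences are conserved; the loop stops
    when the total edit count stops decreasing.
    """
    blk = graph.blocks[block_id]
    if blk.depth < 2:
        recompute_consensus(graph, block_id)
        return
    best = sum(len(graph.nodes[n].edits) for n in blk.node_ids)
    for _ in range(max_rounds):
        for nid in blk.node_ids:
            node = graph.nodes[nid]
            node.edits = derive_edits(graph.node_segment(node), blk.consensus)
        recompute_consensus(graph, block_id)
        count = sum(len(graph.nodes[n].edits) for n in blk.node_ids)
        if count >= best:
            break
        best = count


def polish_graph(graph: Pangraph) -> None:
    for bid in sorted(graph.blocks):
        polish_block(graph, bid)
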
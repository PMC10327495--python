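"""Readers and writers for the interchange formats.

The graph's native on-disk form is a self-defined JSON document (lossless,
byte-stable round trip under canonical key ordering).  Graphs can also be
exported as GFA v1 (segments = blocks, paths = genomes), as a block-by-
genome presence/absence count matrix (TSV), and as per-block gapped FASTA
multiple alignments.  Sequences are stored uppercase.
"""
from __future__ import annotations

import json
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .graph import (DEL, FORWARD, INS, REVERSE, SUB, Edit, GraphError,
                    Pangraph, expand_alignment)

SCHEMA_VERSION = 1
FORMAT_NAME = "panblocks-graph"


class SchemaError(GraphError):
    pass


# -- FASTA -----------------------------------------------------------------


def read_fasta(handle: IO | str) -> list[tuple[str, str]]:
    """Multi-record FASTA as (name, uppercase sequence) pairs."""
    records = [(r.id, str(r.seq).upper())
               for r in SeqIO.parse(handle, "fasta")]
    if not records:
        raise GraphError("no FASTA records found")
    return records


def write_fasta(handle: IO, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write((SeqRecord(Seq(s), id=n, description="") for n, s in records),
                handle, "fasta")


# -- JSON ------------------------------------------------------------------


def _edit_to_json(e: Edit) -> dict:
    if e.kind == DEL:
        return {"kind": e.kind, "pos": e.position, "len": e.payload}
    return {"kind": e.kind, "pos": e.position, "seq": e.payload}


def _edit_from_json(d: dict, where: str) -> Edit:
    try:
        kind = d["kind"]
        pos = d["pos"]
        payload = d["len"] if kind == DEL else d["seq"]
        return Edit(kind, pos, payload)
    except (KeyError, GraphError, TypeError) as exc:
        raise SchemaError(f"invalid edit at {where}: {exc}") from exc


def to_json(graph: Pangraph, provenance: dict | None = None) -> str:
    """Canonical JSON text of a graph (deterministic byte-for-byte)."""
    graph.renumber()
    idx = graph.node_index()
    blocks = []
    for bid in sorted(graph.blocks):
        blk = graph.blocks[bid]
        occs = []
        for nid in blk.node_ids:
            node = graph.nodes[nid]
            occs.append({
                "path": node.path_name,
                "index": idx[nid],
                "strand": "+" if node.strand == FORWARD else "-",
                "edits": [_edit_to_json(e) for e in node.edits],
            })
        occs.sort(key=lambda o: (o["path"], o["index"]))
        blocks.append({"id": bid, "consensus": blk.consensus,
                       "occurrences": occs})
    paths = []
    for name in sorted(graph.paths):
        path = graph.paths[name]
        steps = []
        for nid in path.node_ids:
            node = graph.nodes[nid]
            steps.append([node.block_id,
                          "+" if node.strand == FORWARD else "-"])
        paths.append({"name": name, "circular": path.circular,
                      "offset": path.offset, "steps": steps})
    doc = {"format": FORMAT_NAME, "version": SCHEMA_VERSION,
           "provenance": provenance or {}, "blocks": blocks, "paths": paths}
    return json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"


def from_json(text: str) -> Pangraph:
    """Parse graph JSON; raises :class:`SchemaError` naming the bad field."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    for key in ("format", "version", "blocks", "paths"):
        if key not in doc:
            raise SchemaError(f"missing top-level field {key!r}")
    if doc["format"] != FORMAT_NAME:
        raise SchemaError(f"unknown format {doc['format']!r}")
    if doc["version"] != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {doc['version']!r}")
    g = Pangraph()
    occ_map: dict[tuple[str, int], tuple[str, int, list[Edit]]] = {}
    for b, bd in enumerate(doc["blocks"]):
        for key in ("id", "consensus", "occurrences"):
            if key not in bd:
                raise SchemaError(f"missing field blocks[{b}].{key}")
        g.add_block(bd["consensus"], block_id=bd["id"])
        for o, od in enumerate(bd["occurrences"]):
            where = f"blocks[{b}].occurrences[{o}]"
            for key in ("path", "index", "strand", "edits"):
                if key not in od:
                    raise SchemaError(f"missing field {where}.{key}")
            strand = FORWARD if od["strand"] == "+" else REVERSE
            edits = [_edit_from_json(e, where) for e in od["edits"]]
            occ_map[(od["path"], od["index"])] = (bd["id"], strand, edits)
    from .graph import Path as _Path
    for p, pd in enumerate(doc["paths"]):
        for key in ("name", "circular", "offset", "steps"):
            if key not in pd:
                raise SchemaError(f"missing field paths[{p}].{key}")
        node_ids = []
        for i, (bid, strand_s) in enumerate(pd["steps"]):
            if (pd["name"], i) not in occ_map:
                raise SchemaError(
                    f"paths[{p}].steps[{i}] has no matching occurrence")
            obid, strand, edits = occ_map[(pd["name"], i)]
            if obid != bid:
                raise SchemaError(
                    f"paths[{p}].steps[{i}] block mismatch {bid!r}/{obid!r}")
            node = g.add_node(g.blocks[bid], pd["name"], strand, edits)
            node_ids.append(node.id)
        g.paths[pd["name"]] = _Path(pd["name"], node_ids,
                                    pd["circular"], pd["offset"])
    g.validate()
    return g


# -- GFA v1 ----------------------------------------------------------------


def to_gfa(graph: Pangraph) -> str:
    """GFA v1: one S line per block, L lines for observed adjacencies
    (0M overlap), one P line per genome with +/- orientations."""
    graph.renumber()
    lines = ["H\tVN:Z:1.0"]
    for bid in sorted(graph.blocks):
        lines.append(f"S\t{bid}\t{graph.blocks[bid].consensus}")
    links = set()
    for name in sorted(graph.paths):
        path = graph.paths[name]
        n = len(path.node_ids)
        limit = n if path.circular and n > 1 else n - 1
        for i in range(limit):
            u = graph.nodes[path.node_ids[i]]
            v = graph.nodes[path.node_ids[(i + 1) % n]]
            links.add((u.block_id, "+" if u.strand == FORWARD else "-",
                       v.block_id, "+" if v.strand == FORWARD else "-"))
    for a, sa, b, sb in sorted(links):
        lines.append(f"L\t{a}\t{sa}\t{b}\t{sb}\t0M")
    for name in sorted(graph.paths):
        path = graph.paths[name]
        steps = ",".join(
            f"{graph.nodes[nid].block_id}"
            f"{'+' if graph.nodes[nid].strand == FORWARD else '-'}"
            for nid in path.node_ids)
        overlaps = ",".join("*" for _ in path.node_ids)
        lines.append(f"P\t{name}\t{steps}\t{overlaps}")
    return "\n".join(lines) + "\n"


# -- tabular exports -------------------------------------------------------


def export_presence_absence(graph: Pangraph) -> str:
    """TSV count matrix: rows = blocks, columns = genomes, entries =
    number of occurrences of the block in the genome."""
    graph.renumber()
    names = sorted(graph.paths)
    lines = ["block\t" + "\t".join(names)]
    for bid in sorted(graph.blocks):
        counts = dict.fromkeys(names, 0)
        for nid in graph.blocks[bid].node_ids:
            counts[graph.nodes[nid].path_name] += 1
        lines.append(bid + "\t" + "\t".join(str(counts[n]) for n in names))
    return "\n".join(lines) + "\n"


def export_block_msa(graph: Pangraph, block_id: str) -> str:
    """Gapped FASTA of one block's members (consensus + edits realized)."""
    if block_id not in graph.blocks:
        raise GraphError(f"unknown block id {block_id!r}")
    blk = graph.blocks[block_id]
    idx = graph.node_index()
    nodes = sorted((graph.nodes[n] for n in blk.node_ids),
                   key=lambda nd: (nd.path_name, idx[nd.id]))
    cons_row, rows = expand_alignment(blk.consensus,
                                      [n.edits for n in nodes])
    out = [f">consensus\n{cons_row}"]
    for node, row in zip(nodes, rows):
        strand = "+" if node.strand == FORWARD else "-"
        out.append(f">{node.path_name}|{idx[node.id]}|{strand}\n{row}")
    return "\n".join(out) + "\n"
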
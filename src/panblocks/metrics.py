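"""Quantitative evaluation of pangenome graphs.

Covers breakpoint-displacement benchmarking against simulation truth,
compression/core/L50-N50 summaries, pairwise partition agreement between
two graphs of the same genomes, and the divergence-corrected shared-k-mer
estimate of homologous sequence fraction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seq import canonical_kmer_set
from .graph import Pangraph

FORWARD = 1


@dataclass(frozen=True)
class MetricsConfig:
    pairing_window: int = 1_000        # max pairing distance (bp)
    displacement_threshold: int = 100  # "misplaced" above this (bp) = L_min
    kmer: int = 21                     # k for the shared-sequence estimate

    def __post_init__(self):
        if min(self.pairing_window, self.displacement_threshold, self.kmer) <= 0:
            raise ValueError("all metric parameters must be > 0")


# -- breakpoints ------------------------------------------------------------


def graph_breakpoints(graph: Pangraph) -> dict[str, list[int]]:
    """Per-genome sorted positions of block junctions, in the coordinates
    of the reconstructed (emitted) genome.

    Circular paths include the wrap junction between their last and first
    steps; a circular path consisting of a single block has no junction at
    all (the genome is one contiguous block around the circle).
    """
    out = {}
    for name in sorted(graph.paths):
        path = graph.paths[name]
        lens = [len(graph.node_segment(graph.nodes[nid]))
                for nid in path.node_ids]
        total = sum(lens)
        positions = []
        acc = 0
        for i, ln in enumerate(lens):
            acc += ln
            if i == len(lens) - 1 and (not path.circular or len(lens) == 1):
                break
            positions.append((acc - path.offset) % total)
        out[name] = sorted(set(positions))
    return out


def _circ_dist(a: int, b: int, total: int | None) -> int:
    d = abs(a - b)
    if total is not None:
        d = min(d, total - d)
    return d


def pair_breakpoints(pos_a: list[int], pos_b: list[int], window: int,
                     total: int | None = None, method: str = "greedy"
                     ) -> tuple[list[tuple[int, int, int]], int, int]:
    """Pair two breakpoint sets within a window.

    Greedy (default): closest pairs first, each breakpoint used once.
    ``method='optimal'`` solves the min-cost assignment restricted to the
    window instead.  Returns (pairs as (a, b, displacement), unpaired_a,
    unpaired_b); distances wrap when ``total`` is given.
    """
    cand = [(_circ_dist(a, b, total), i, j)
            for i, a in enumerate(pos_a) for j, b in enumerate(pos_b)
            if _circ_dist(a, b, total) <= window]
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    if method == "greedy":
        for d, i, j in sorted(cand):
            if i in used_a or j in used_b:
                continue
            pairs.append((pos_a[i], pos_b[j], d))
            used_a.add(i)
            used_b.add(j)
    elif method == "optimal":
        from scipy.optimize import linear_sum_assignment
        if cand:
            big = window * (len(pos_a) + len(pos_b) + 1) + 1
            C = np.full((len(pos_a), len(pos_b)), big, dtype=float)
            for d, i, j in cand:
                C[i, j] = d
            ri, ci = linear_sum_assignment(C)
            for i, j in zip(ri, ci):
                if C[i, j] <= window:
                    pairs.append((pos_a[i], pos_b[j], int(C[i, j])))
                    used_a.add(i)
                    used_b.add(j)
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    return pairs, len(pos_a) - len(used_a), len(pos_b) - len(used_b)


def breakpoint_displacement(bp_a: dict[str, list[int]],
                            bp_b: dict[str, list[int]],
                            cfg: MetricsConfig = MetricsConfig(),
                            totals: dict[str, int] | None = None,
                            method: str = "greedy"
                            ) -> dict[str, dict]:
    """Pair per-genome breakpoint sets and report displacements.

    Symmetric in its two arguments.  Raises if the genome sets differ.
    """
    if set(bp_a) != set(bp_b):
        raise ValueError("genome present in only one breakpoint set")
    out = {}
    for name in sorted(bp_a):
        total = totals.get(name) if totals else None
        pairs, ua, ub = pair_breakpoints(bp_a[name], bp_b[name],
                                         cfg.pairing_window, total, method)
        out[name] = {"displacements": [d for _, _, d in pairs],
                     "unpaired_a": ua, "unpaired_b": ub}
    return out


def fraction_misplaced(displacement_report: dict[str, dict],
                       cfg: MetricsConfig = MetricsConfig(),
                       unpaired: str = "exclude") -> float:
    """Share of breakpoints displaced beyond the precision threshold.

    ``unpaired='exclude'`` (default) counts paired breakpoints only;
    ``unpaired='misplaced'`` additionally counts every unpaired breakpoint
    as misplaced.
    """
    if unpaired not in ("exclude", "misplaced"):
        raise ValueError("unpaired must be 'exclude' or 'misplaced'")
    bad = tot = 0
    for rep in displacement_report.values():
        ds = rep["displacements"]
        tot += len(ds)
        bad += sum(d > cfg.displacement_threshold for d in ds)
        if unpaired == "misplaced":
            extra = rep["unpaired_a"] + rep["unpaired_b"]
            tot += extra
            bad += extra
    return bad / tot if tot else float("nan")


# -- summaries --------------------------------------------------------------


def graph_summary(graph: Pangraph) -> dict:
    """Compression, core size, and block-length summary of a graph."""
    n_genomes = len(graph.paths)
    block_lens = sorted((len(b.consensus) for b in graph.blocks.values()),
                        reverse=True)
    pangenome = sum(block_lens)
    genomes_total = sum(len(graph.reconstruct(n)) for n in graph.paths)
    core_len = 0
    n_core = 0
    for blk in graph.blocks.values():
        names = [graph.nodes[n].path_name for n in blk.node_ids]
        if len(names) == n_genomes and len(set(names)) == n_genomes:
            core_len += len(blk.consensus)
            n_core += 1
    acc = 0
    l50 = n50 = 0
    for i, ln in enumerate(block_lens, 1):
        acc += ln
        if acc > pangenome / 2:
            l50, n50 = i, ln
            break
    return {
        "n_genomes": n_genomes,
        "n_blocks": len(graph.blocks),
        "n_core_blocks": n_core,
        "pangenome_length": pangenome,
        "total_genome_length": genomes_total,
        "compression": pangenome / genomes_total if genomes_total else float("nan"),
        "core_length": core_len,
        "core_fraction": core_len / pangenome if pangenome else float("nan"),
        "L50": l50,
        "N50": n50,
    }


# -- partition agreement ----------------------------------------------------


def _shared_intervals(graph: Pangraph, name: str, other: str
                      ) -> list[tuple[int, int, bool]]:
    """(start, end, shared?) intervals of genome ``name`` in emitted
    coordinates; shared = the block also carries the other genome."""
    path = graph.paths[name]
    total = sum(len(graph.node_segment(graph.nodes[nid]))
                for nid in path.node_ids)
    out = []
    acc = 0
    for nid in path.node_ids:
        node = graph.nodes[nid]
        blk = graph.blocks[node.block_id]
        ln = len(graph.node_segment(node))
        owners = {graph.nodes[n].path_name for n in blk.node_ids}
        start = (acc - path.offset) % total
        out.append((start, start + ln, other in owners))
        acc += ln
    # unwrap intervals crossing the origin
    flat = []
    for s, e, lab in out:
        if e <= total:
            flat.append((s, e, lab))
        else:
            flat.append((s, total, lab))
            flat.append((0, e - total, lab))
    return sorted(flat)


def partition_compare(graph_a: Pangraph, graph_b: Pangraph,
                      pair: tuple[str, str]) -> dict[str, dict]:
    """Compare the shared/private partition two graphs induce on a genome
    pair.

    For each genome, every position is labelled shared or private under
    each graph; the intersection partition is classified into agree-shared,
    agree-private and disagree, reporting genome-length fractions and mean
    lengths of maximal same-category runs.
    """
    a, b = pair
    for g in (graph_a, graph_b):
        missing = {a, b} - set(g.paths)
        if missing:
            raise ValueError(f"graph lacks genome(s) {sorted(missing)}")
    out = {}
    for name, other in ((a, b), (b, a)):
        iv_a = _shared_intervals(graph_a, name, other)
        iv_b = _shared_intervals(graph_b, name, other)
        total = sum(e - s for s, e, _ in iv_a)
        bounds = sorted({x for s, e, _ in iv_a + iv_b for x in (s, e)})
        lab_a = _labeller(iv_a)
        lab_b = _labeller(iv_b)
        segments = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            la, lb = lab_a(s), lab_b(s)
            cat = ("agree_shared" if la and lb else
                   "agree_private" if not la and not lb else "disagree")
            segments.append((s, e, cat))
        # merge adjacent same-category runs (wrapping around the origin)
        merged = []
        for s, e, cat in segments:
            if merged and merged[-1][2] == cat and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, cat)
            else:
                merged.append((s, e, cat))
        if len(merged) > 1 and merged[0][2] == merged[-1][2] \
                and merged[-1][1] % total == merged[0][0]:
            s0, e0, cat = merged.pop(0)
            merged[-1] = (merged[-1][0], merged[-1][1] + (e0 - s0), cat)
        report = {}
        for cat in ("agree_shared", "agree_private", "disagree"):
            runs = [e - s for s, e, c in merged if c == cat]
            report[cat] = {
                "fraction": sum(runs) / total if total else 0.0,
                "mean_segment_length": float(np.mean(runs)) if runs else 0.0,
                "n_segments": len(runs),
            }
        out[name] = report
    return out


def _labeller(intervals):
    def lab(pos):
        for s, e, shared in intervals:
            if s <= pos < e:
                return shared
        raise ValueError(f"position {pos} not covered")
    return lab


# -- shared-sequence estimate ----------------------------------------------


def shared_sequence_estimate(seq_a: str, seq_b: str, core_divergence: float,
                             cfg: MetricsConfig = MetricsConfig()) -> float:
    """Alignment-free estimate of the shared-sequence fraction.

    Fraction of shared canonical k-mers (containment: intersection over the
    smaller set) divided by ``(1 - d)^k``, which corrects for k-mers on
    homologous sequence broken by point mutations at core divergence ``d``.
    Capped at 1 with a warning.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if not 0 <= core_divergence < 1:
        raise ValueError("core divergence must be in [0, 1)")
    ka = canonical_kmer_set(seq_a, cfg.kmer)
    kb = canonical_kmer_set(seq_b, cfg.kmer)
    frac = len(ka & kb) / min(len(ka), len(kb))
    est = frac / (1.0 - core_divergence) ** cfg.kmer
    if est > 1.0:
        warnings.warn("shared-sequence estimate exceeded 1; capping",
                      stacklevel=2)
        est = 1.0
    return est
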
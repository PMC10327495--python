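"""Pairwise homology search between block consensus sequences.

Two interchangeable kernels implement a narrow contract (sequences in,
:class:`Hit` records out):

* ``minimap2`` — shells out to the minimap2 binary with an assembly preset
  (``asm10``/``asm20``) and parses CIGAR-bearing PAF.  This is the default.
* ``builtin`` — a pure-Python seed-and-extend kernel (unique canonical
  k-mer anchors, diagonal chaining, banded global extension with edlib)
  that keeps the package fully functional without external binaries.

A slot for an mmseqs2-style high-divergence kernel exists in the config but
is not implemented.
"""
from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import edlib
import numpy as np

from ._seq import revcomp, seq_codes

FORWARD = 1
REVERSE = -1

_PRESETS = {"minimap2": ("asm5", "asm10", "asm20"),
            "builtin": ("builtin-default",),
            "mmseqs2": ()}


class KernelError(RuntimeError):
    pass


class KernelUnavailableError(KernelError):
    pass


@dataclass(frozen=True)
class KernelConfig:
    kernel: str = "minimap2"
    preset: str = "asm20"
    min_length: int = 100  # hits shorter than this are dropped (bp, columns)

    def __post_init__(self):
        if self.kernel not in _PRESETS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "mmseqs2":
            raise KernelUnavailableError(
                "the mmseqs2 kernel slot is not implemented; "
                "use kernel='minimap2' or the dependency-free 'builtin'")
        if self.preset not in _PRESETS[self.kernel]:
            raise ValueError(
                f"preset {self.preset!r} invalid for kernel {self.kernel!r}")


@dataclass
class Hit:
    """A homology match between two consensus sequences.

    Intervals are 0-based half-open on the forward strand of each
    consensus; for reverse hits the reverse complement of the query
    interval aligns to the forward reference interval.  ``length`` counts
    alignment columns, ``matches`` matching columns.
    """

    query_block: str
    ref_block: str
    qstart: int
    qend: int
    rstart: int
    rend: int
    strand: int
    cigar: str
    matches: int
    length: int

    @property
    def divergence(self) -> float:
        return 1.0 - self.matches / self.length if self.length else 0.0


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            if n == 0:
                raise KernelError(f"malformed cigar {cigar!r}")
            ops.append((n, ch))
            n = 0
    if n or not ops:
        raise KernelError(f"malformed cigar {cigar!r}")
    return ops


def cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(columns, matching columns, polymorphism events) of a =/X/I/D cigar.

    Each indel counts as a single polymorphism event regardless of length:
    a long insertion is one evolutionary event and should not veto a merger
    the way the same number of substitutions would.
    """
    cols = matches = events = 0
    for n, op in parse_cigar(cigar):
        cols += n
        if op == "=":
            matches += n
        elif op == "X":
            events += n
        elif op in "ID":
            events += 1
        elif op == "M":  # match-or-mismatch; treated as match (not emitted
            matches += n  # by either kernel, kept for PAF tolerance)
        else:
            raise KernelError(f"unsupported cigar op {op!r}")
    return cols, matches, events


def divergence_from_cigar(cigar: str) -> float:
    """Polymorphism events per alignment column, in [0, 1]."""
    cols, _, events = cigar_stats(cigar)
    return events / cols


def align_consensus_sets(blocks_a, blocks_b, cfg: KernelConfig = KernelConfig()
                         ) -> list[Hit]:
    """All-to-all homology search between two sets of ``(id, consensus)``.

    The two sets may be identical (self-alignment, which surfaces
    duplications); the trivial identity self-hit of each sequence is
    excluded, as are mirrored duplicates of the same match.
    """
    blocks_a = list(blocks_a)
    blocks_b = list(blocks_b)
    if not blocks_a or not blocks_b:
        raise KernelError("empty block set")
    if cfg.kernel == "minimap2":
        hits = _minimap2_hits(blocks_a, blocks_b, cfg)
    else:
        hits = _builtin_hits(blocks_a, blocks_b, cfg)
    return _dedupe(h for h in hits
                   if h.length >= cfg.min_length and not _is_identity(h))


def _is_identity(h: Hit) -> bool:
    return (h.query_block == h.ref_block and h.strand == FORWARD
            and h.qstart == h.rstart and h.qend == h.rend)


def _dedupe(hits) -> list[Hit]:
    seen = {}
    for h in hits:
        a = (h.query_block, h.qstart, h.qend)
        b = (h.ref_block, h.rstart, h.rend)
        key = (min(a, b), max(a, b), h.strand)
        if key not in seen:
            seen[key] = h
    return sorted(seen.values(),
                  key=lambda h: (h.query_block, h.ref_block,
                                 h.qstart, h.rstart, -h.strand))


# -- minimap2 adapter -------------------------------------------------------


def _minimap2_hits(blocks_a, blocks_b, cfg: KernelConfig) -> list[Hit]:
    if shutil.which("minimap2") is None:
        raise KernelUnavailableError(
            "minimap2 binary not found on PATH; fall back to the "
            "dependency-free builtin kernel (KernelConfig(kernel='builtin'))")
    same = {b for b, _ in blocks_a} == {b for b, _ in blocks_b}
    with tempfile.TemporaryDirectory(prefix="panblocks-mm2-") as tmp:
        ref = FsPath(tmp) / "ref.fa"
        _write_fasta(ref, blocks_b)
        if same:
            # all-vs-all: -X drops the trivial diagonal and dual mappings
            # but keeps off-diagonal (duplication) self hits
            cmd = ["minimap2", "-x", cfg.preset, "-X", "-c", "--eqx",
                   "-t", "1", str(ref), str(ref)]
        else:
            qry = FsPath(tmp) / "qry.fa"
            _write_fasta(qry, blocks_a)
            cmd = ["minimap2", "-x", cfg.preset, "-c", "--eqx", "-t", "1",
                   str(ref), str(qry)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise KernelError(f"minimap2 failed: {proc.stderr.strip()}")
        return _parse_paf(proc.stdout)


def _write_fasta(path: FsPath, blocks) -> None:
    with open(path, "w") as fh:
        for bid, seq in blocks:
            fh.write(f">{bid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def _parse_paf(text: str) -> list[Hit]:
    hits = []
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        cigar = None
        for tag in f[12:]:
            if tag.startswith("cg:Z:"):
                cigar = tag[5:]
        if cigar is None:
            continue
        cols, matches, _ = cigar_stats(cigar)
        hits.append(Hit(
            query_block=f[0], ref_block=f[5],
            qstart=int(f[2]), qend=int(f[3]),
            rstart=int(f[7]), rend=int(f[8]),
            strand=FORWARD if f[4] == "+" else REVERSE,
            cigar=cigar, matches=matches, length=cols))
    return hits


def hits_to_paf(hits: list[Hit], lengths: dict[str, int]) -> str:
    """Render hits as PAF records (debugging aid)."""
    rows = []
    for h in hits:
        rows.append("\t".join(map(str, [
            h.query_block, lengths[h.query_block], h.qstart, h.qend,
            "+" if h.strand == FORWARD else "-",
            h.ref_block, lengths[h.ref_block], h.rstart, h.rend,
            h.matches, h.length, 255, f"cg:Z:{h.cigar}"])))
    return "\n".join(rows) + ("\n" if rows else "")


# -- builtin seed-and-extend kernel ----------------------------------------

_K = 13          # anchor k-mer length
_MAX_OCC = 40    # skip k-mers more frequent than this in the target
_BAND = 150      # max diagonal drift within a chain (bp)
_MAX_GAP = 800   # max anchor-to-anchor gap within a chain (bp)


@dataclass
class _Chain:
    qs: int
    qe: int
    ts: int
    te: int
    anchors: int = field(default=0)


def _forward_kmer_codes(seq: str, k: int) -> np.ndarray:
    b = seq_codes(seq)
    if len(b) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(b, k)
    pw = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ pw
    codes[(win >= 4).any(axis=1)] = -1
    return codes


def _chain_anchors(pairs: list[tuple[int, int]], k: int) -> list[_Chain]:
    """Greedy colinear chaining of (qpos, tpos) anchors."""
    chains: list[_Chain] = []
    open_chains: list[_Chain] = []
    for q, t in sorted(pairs):
        d = q - t
        best = None
        for c in open_chains:
            if (abs((c.qe - k - c.te + k) - d) <= _BAND
                    and 0 <= q - (c.qe - k) <= _MAX_GAP
                    and t > c.te - k):
                best = c
                break
        if best is None:
            chains.append(_Chain(q, q + k, t, t + k, 1))
            open_chains.append(chains[-1])
            open_chains = [c for c in open_chains if q - (c.qe - k) <= _MAX_GAP]
        else:
            best.qe = q + k
            best.te = t + k
            best.anchors += 1
    return chains


def _builtin_pair(qid, qseq, tid, tseq, cfg, self_pair: bool) -> list[Hit]:
    tcodes = _forward_kmer_codes(tseq, _K)
    index: dict[int, list[int]] = defaultdict(list)
    for pos, code in enumerate(tcodes.tolist()):
        if code >= 0:
            index[code].append(pos)
    hits = []
    for strand in (FORWARD, REVERSE):
        q = qseq if strand == FORWARD else revcomp(qseq)
        qcodes = _forward_kmer_codes(q, _K)
        pairs = []
        for pos, code in enumerate(qcodes.tolist()):
            if code < 0:
                continue
            occ = index.get(code)
            if not occ or len(occ) > _MAX_OCC:
                continue
            for t in occ:
                if self_pair and strand == FORWARD and t == pos:
                    continue  # main diagonal of a self comparison
                pairs.append((pos, t))
        for c in _chain_anchors(pairs, _K):
            if c.anchors < 3 or min(c.qe - c.qs, c.te - c.ts) < cfg.min_length:
                continue
            qsub = q[c.qs:c.qe]
            tsub = tseq[c.ts:c.te]
            res = edlib.align(qsub, tsub, task="path", mode="NW")
            cigar = res["cigar"]
            cols, matches, _ = cigar_stats(cigar)
            if strand == FORWARD:
                qs, qe = c.qs, c.qe
            else:  # map back to forward query coordinates
                qs, qe = len(qseq) - c.qe, len(qseq) - c.qs
            if self_pair and (qs, qe) == (c.ts, c.te) and strand == FORWARD:
                continue
            hits.append(Hit(qid, tid, qs, qe, c.ts, c.te, strand,
                            cigar, matches, cols))
    return hits


def _builtin_hits(blocks_a, blocks_b, cfg: KernelConfig) -> list[Hit]:
    hits = []
    ids_b = {bid for bid, _ in blocks_b}
    done = set()
    for qid, qseq in blocks_a:
        for tid, tseq in blocks_b:
            if (tid, qid) in done and tid in ids_b:
                continue  # mirrored pair already searched
            done.add((qid, tid))
            hits.extend(_builtin_pair(qid, qseq, tid, tseq, cfg,
                                      self_pair=qid == tid))
    return hits
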
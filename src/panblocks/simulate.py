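"""Forward-time Wright-Fisher simulation of structural genome evolution.

A population of ``n`` circular genomes descends from a single random
ancestor for ``t`` generations.  Each child copies a uniformly chosen
parent and then receives a Poisson number of events of each class:

* substitutions — rate ``mu`` per site per generation;
* inversions    — rate ``inv_rate`` per genome per generation;
* deletions     — rate ``del_rate`` per genome per generation;
* horizontal transfer — rate ``hgt_rate`` per genome per generation: a
  geometric-length segment of a random donor replaces the recipient's
  homologous locus (located through shared ancestral coordinates; the
  replaced extant length equals the donor segment length, so transfer is
  length-neutral).

Inversion and deletion segment lengths are geometric with configurable
means.  Every genome is maintained as its extant sequence *plus* an exact
decomposition into ancestral intervals ``(start, end, strand)``, so the
true mosaic structure — and hence the true breakpoint set — is known.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import random_sequence, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimParams:
    n: int = 10                    # population size
    length: int = 100_000          # ancestral genome length (bp)
    generations: int = 50
    mu: float = 5e-4               # substitutions / site / generation
    inv_rate: float = 0.01         # inversions / genome / generation
    del_rate: float = 0.05         # deletions / genome / generation
    hgt_rate: float = 0.1          # transfers / genome / generation
    inv_mean: float = 5_000.0      # mean inversion length (bp)
    del_mean: float = 500.0        # mean deletion length (bp)
    hgt_mean: float = 5_000.0      # mean transferred length (bp)
    min_genome_length: int = 1_000  # deletions shrinking below this are skipped
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.length < 1 or self.generations < 0:
            raise ValueError("n, length >= 1 and generations >= 0 required")
        for r in (self.mu, self.inv_rate, self.del_rate, self.hgt_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


def expected_pair_coalescence(n: int, t: int) -> float:
    """E[min(pairwise coalescence time, t)] generations in a WF population."""
    return n * (1.0 - (1.0 - 1.0 / n) ** t)


def mutation_rate_for_divergence(d: float, n: int, t: int) -> float:
    """Per-site rate giving expected average pairwise divergence ``d``."""
    return d / (2.0 * expected_pair_coalescence(n, t))


Seg = tuple[int, int, int]  # ancestor (start, end) half-open, strand +-1


@dataclass
class _Genome:
    seq: bytearray
    segs: list[Seg]

    def copy(self) -> "_Genome":
        return _Genome(bytearray(self.seq), list(self.segs))


@dataclass
class TrueGraph:
    """Simulation ground truth: ancestral decomposition of each genome."""

    ancestor: str
    segments: dict[str, list[Seg]]
    sequences: dict[str, str] = field(default_factory=dict)

    def substitutions(self, name: str) -> list[tuple[int, str, str]]:
        """(extant position, ancestral base, extant base) differences."""
        out = []
        pos = 0
        seq = self.sequences[name]
        for s, e, strand in self.segments[name]:
            anc = self.ancestor[s:e]
            if strand < 0:
                anc = revcomp(anc)
            for k, (a, b) in enumerate(zip(anc, seq[pos:pos + (e - s)])):
                if a != b:
                    out.append((pos + k, a, b))
            pos += e - s
        return out

    def replay(self, name: str) -> str:
        """Rebuild the extant genome from ancestor + intervals + substitutions."""
        parts = []
        for s, e, strand in self.segments[name]:
            anc = self.ancestor[s:e]
            parts.append(anc if strand > 0 else revcomp(anc))
        base = list("".join(parts))
        for pos, _, b in self.substitutions(name):
            base[pos] = b
        return "".join(base)


def _rotate(g: _Genome, s: int) -> None:
    if s == 0:
        return
    g.seq = g.seq[s:] + g.seq[:s]
    g.segs = _split_at(g.segs, s)
    # move whole segments before the split point to the back
    acc = 0
    k = 0
    for k, seg in enumerate(g.segs):
        if acc == s:
            break
        acc += seg[1] - seg[0]
    else:
        k = len(g.segs)
    g.segs = g.segs[k:] + g.segs[:k]


def _split_at(segs: list[Seg], pos: int) -> list[Seg]:
    """Ensure an interval boundary at extant offset ``pos``."""
    out = []
    acc = 0
    for s, e, strand in segs:
        ln = e - s
        if acc < pos < acc + ln:
            cut = pos - acc
            if strand > 0:
                out.extend([(s, s + cut, strand), (s + cut, e, strand)])
            else:
                out.extend([(e - cut, e, strand), (s, e - cut, strand)])
        else:
            out.append((s, e, strand))
        acc += ln
    return out


def _geom_len(rng: np.random.Generator, mean: float, lo: int = 1) -> int:
    return max(lo, int(rng.geometric(1.0 / max(mean, 1.0))))


def _invert(g: _Genome, start: int, length: int) -> None:
    _rotate(g, start)
    g.seq[:length] = bytes(revcomp(g.seq[:length].decode("ascii")), "ascii")
    segs = _split_at(g.segs, length)
    head, tail, acc = [], [], 0
    for seg in segs:
        (head if acc < length else tail).append(seg)
        acc += seg[1] - seg[0]
    head = [(s, e, -strand) for s, e, strand in reversed(head)]
    g.segs = head + tail


def _delete(g: _Genome, start: int, length: int) -> None:
    _rotate(g, start)
    del g.seq[:length]
    segs = _split_at(g.segs, length)
    out, acc = [], 0
    for seg in segs:
        if acc >= length:
            out.append(seg)
        acc += seg[1] - seg[0]
    g.segs = out


def _extract(g: _Genome, start: int, length: int) -> tuple[bytes, list[Seg]]:
    """Copy a circular segment without mutating the genome."""
    tmp = g.copy()
    _rotate(tmp, start % len(g.seq))
    seq = bytes(tmp.seq[:length])
    segs = _split_at(tmp.segs, length)
    out, acc = [], 0
    for seg in segs:
        if acc < length:
            out.append(seg)
        acc += seg[1] - seg[0]
    return seq, out


def _locate_ancestral(g: _Genome, anc_pos: int) -> int | None:
    """Extant offset of ancestor coordinate ``anc_pos``, if it survives."""
    acc = 0
    for s, e, strand in g.segs:
        if s <= anc_pos < e:
            return acc + (anc_pos - s if strand > 0 else e - 1 - anc_pos)
        acc += e - s
    return None


def _transfer(g: _Genome, donor: _Genome, start: int, length: int,
              rng: np.random.Generator) -> None:
    seq, segs = _extract(donor, start, length)
    # homologous locus: recipient position of the donor segment's first
    # surviving ancestral coordinate; fallback to a uniform position
    anc_anchor = segs[0][0] if segs[0][2] > 0 else segs[0][1] - 1
    pos = _locate_ancestral(g, anc_anchor)
    if pos is None:
        pos = int(rng.integers(0, len(g.seq)))
    _rotate(g, pos)
    repl = min(length, max(0, len(g.seq) - 1))
    del g.seq[:repl]
    kept, acc = [], 0
    split = _split_at(g.segs, repl)
    for seg in split:
        if acc >= repl:
            kept.append(seg)
        acc += seg[1] - seg[0]
    g.seq = bytearray(seq) + g.seq
    g.segs = segs + kept


_BASE_IDX = {65: 0, 67: 1, 71: 2, 84: 3}
_BASES = b"ACGT"


def simulate_population(params: SimParams = SimParams()
                        ) -> tuple[list[tuple[str, str]], TrueGraph]:
    """Evolve a population; returns named genomes and the ground truth.

    Deterministic for a fixed parameter set (including the seed).
    """
    rng = np.random.default_rng(params.seed)
    ancestor = random_sequence(params.length, rng)
    pop = [_Genome(bytearray(ancestor, "ascii"), [(0, params.length, 1)])
           for _ in range(params.n)]
    for _gen in range(params.generations):
        parents = rng.integers(0, params.n, size=params.n)
        children = []
        for c in range(params.n):
            g = pop[parents[c]].copy()
            for _ in range(rng.poisson(params.inv_rate)):
                ln = min(_geom_len(rng, params.inv_mean, 2), len(g.seq) - 1)
                _invert(g, int(rng.integers(0, len(g.seq))), ln)
            for _ in range(rng.poisson(params.del_rate)):
                ln = _geom_len(rng, params.del_mean)
                if len(g.seq) - ln < params.min_genome_length:
                    logger.warning("skipping deletion: genome at floor")
                    continue
                _delete(g, int(rng.integers(0, len(g.seq))), ln)
            for _ in range(rng.poisson(params.hgt_rate)):
                donor = pop[int(rng.integers(0, params.n))]
                ln = min(_geom_len(rng, params.hgt_mean), len(donor.seq) - 1,
                         len(g.seq) - 1)
                _transfer(g, donor, int(rng.integers(0, len(donor.seq))),
                          ln, rng)
            n_sub = rng.poisson(params.mu * len(g.seq))
            if n_sub:
                pos = rng.integers(0, len(g.seq), size=n_sub)
                shift = rng.integers(1, 4, size=n_sub)
                for p, sh in zip(pos.tolist(), shift.tolist()):
                    cur = _BASE_IDX.get(g.seq[p], 0)
                    g.seq[p] = _BASES[(cur + sh) % 4]
            children.append(g)
        pop = children
    names = [f"genome_{i:02d}" for i in range(params.n)]
    genomes = [(nm, g.seq.decode("ascii")) for nm, g in zip(names, pop)]
    truth = TrueGraph(
        ancestor=ancestor,
        segments={nm: list(g.segs) for nm, g in zip(names, pop)},
        sequences=dict(genomes))
    return genomes, truth


def true_breakpoints(truth: TrueGraph) -> dict[str, list[int]]:
    """Per-genome sorted extant positions of ancestrally discontinuous
    junctions (circular; includes the wrap junction when discontinuous)."""
    L0 = len(truth.ancestor)
    out = {}
    for name, segs in truth.segments.items():
        positions = []
        acc = 0
        n = len(segs)
        total = sum(e - s for s, e, _ in segs)
        for i in range(n):
            a = segs[i]
            b = segs[(i + 1) % n]
            acc += a[1] - a[0]
            if not _contiguous(a, b, L0):
                positions.append(acc % total)
        out[name] = sorted(set(positions))
    return out


def truth_to_graph(truth: TrueGraph) -> "Pangraph":
    """Convert simulation truth into the true pangenome graph.

    The ancestor is cut at every interval boundary observed in any genome;
    each surviving atomic interval becomes a block (consensus = ancestral
    sequence, per-occurrence edits = accumulated substitutions), and each
    genome a path over the atoms it carries.  Transitive compaction then
    removes junctions that are identical in all genomes — events fixed in
    the whole sample leave no boundary, exactly as in a graph built from
    the extant sequences alone.
    """
    from .graph import Edit, Pangraph, SUB, FORWARD, REVERSE
    from .marginalize import merge_transitive

    L0 = len(truth.ancestor)
    cuts = sorted({c % L0 for segs in truth.segments.values()
                   for s, e, _ in segs for c in (s, e)})
    if not cuts:
        cuts = [0]
    atom_bounds = cuts + [cuts[0] + L0]
    atoms = [(a, b if b <= L0 else b - L0)
             for a, b in zip(atom_bounds[:-1], atom_bounds[1:])]

    def atoms_in(s: int, e: int) -> list[tuple[int, int]]:
        # ancestor-interval [s, e) as a run of atoms (never wraps: segment
        # coordinates are stored with s < e <= L0)
        out = []
        for a, b in atoms:
            b_eff = b if b > a else b + L0
            if s <= a and b_eff <= e:
                out.append((a, b))
        return sorted(out)

    g = Pangraph()
    blocks: dict[tuple[int, int], object] = {}
    for name in sorted(truth.segments):
        seq = truth.sequences[name]
        node_ids = []
        pos = 0
        for s, e, strand in truth.segments[name]:
            run = atoms_in(s, e)
            if strand < 0:
                run = run[::-1]
            for a, b in run:
                ln = (b - a) % L0 or L0
                if (a, b) not in blocks:
                    cons = truth.ancestor[a:b] if b > a else \
                        truth.ancestor[a:] + truth.ancestor[:b]
                    blocks[(a, b)] = g.add_block(cons)
                blk = blocks[(a, b)]
                piece = seq[pos:pos + ln]
                member = piece if strand > 0 else revcomp(piece)
                edits = []
                run_start = None
                buf = []
                for k, (x, y) in enumerate(zip(member, blk.consensus)):
                    if x != y:
                        if run_start is None:
                            run_start = k
                        buf.append(x)
                    elif run_start is not None:
                        edits.append(Edit(SUB, run_start, "".join(buf)))
                        run_start, buf = None, []
                if run_start is not None:
                    edits.append(Edit(SUB, run_start, "".join(buf)))
                node = g.add_node(blk, name,
                                  FORWARD if strand > 0 else REVERSE, edits)
                node_ids.append(node.id)
                pos += ln
        from .graph import Path as _Path
        g.paths[name] = _Path(name, node_ids, circular=True, offset=0)
    merge_transitive(g)
    g.renumber()
    return g


def _contiguous(a: Seg, b: Seg, L0: int) -> bool:
    """Whether extant neighbours a-then-b are ancestrally contiguous and
    co-oriented (the ancestor itself is circular, so coordinates wrap)."""
    if a[2] != b[2]:
        return False
    if a[2] > 0:
        return a[1] % L0 == b[0] % L0
    return b[1] % L0 == a[0] % L0
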
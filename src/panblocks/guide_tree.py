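"""Guide-tree construction for progressive graph alignment.

Genomes are sketched into minimizer sets (windowed minima over an invertible
hash of canonical k-mers); pairwise Jaccard distances between sketches feed
neighbour joining, and the NJ tree is rebalanced into a balanced binary tree
that preserves the NJ leaf ordering.  Internal nodes of the balanced tree are
the pairwise merge jobs; jobs in disjoint subtrees are independent and the
final graph must not depend on their execution order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import kmer_codes, splitmix64


@dataclass(frozen=True)
class SketchParams:
    """Minimizer sketch settings: k-mer length and window size (bp)."""

    k: int = 15
    w: int = 10

    def __post_init__(self):
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31]")
        if self.w < 1:
            raise ValueError("w must be >= 1")


def minimizer_sketch(seq: str, params: SketchParams = SketchParams()) -> set[int]:
    """Set of minimizer hash values of a sequence.

    The minimizer of each window of ``w`` consecutive k-mers is the k-mer
    with the smallest hash; hashing canonical k-mers makes the sketch
    identical for a sequence and its reverse complement.
    """
    k, w = params.k, params.w
    if len(seq) < k + w - 1:
        raise ValueError(f"sequence shorter than one window ({k + w - 1} bp)")
    codes, valid = kmer_codes(seq, k)
    h = splitmix64(codes)
    h[~valid] = np.iinfo(np.uint64).max  # invalid k-mers never win a window
    if w == 1:
        mins = h[valid]
    else:
        win = np.lib.stride_tricks.sliding_window_view(h, w)
        mins = win.min(axis=1)
        keep = mins != np.iinfo(np.uint64).max
        mins = mins[keep]
    return set(mins.tolist())


def sketch_genome(contigs: list[str], params: SketchParams = SketchParams()) -> set[int]:
    """Sketch of a (possibly multi-contig) genome: union over contigs."""
    out: set[int] = set()
    for seq in contigs:
        out |= minimizer_sketch(seq, params)
    return out


def jaccard_distance_matrix(sketches: list[set[int]]) -> np.ndarray:
    """Pairwise Jaccard distances ``1 - |A∩B| / |A∪B|``.

    Intersections are counted with a single global sort of all minimizers
    (log-linear), not nested per-pair set scans.
    """
    n = len(sketches)
    if n < 2:
        raise ValueError("need at least two sketches")
    sizes = np.array([len(s) for s in sketches])
    if (sizes == 0).any():
        raise ValueError("empty sketch")
    hashes = np.concatenate([np.fromiter(s, dtype=np.uint64, count=len(s))
                             for s in sketches])
    owners = np.repeat(np.arange(n), sizes)
    order = np.argsort(hashes, kind="stable")
    hashes, owners = hashes[order], owners[order]
    inter = np.zeros((n, n), dtype=np.int64)
    starts = np.flatnonzero(np.concatenate([[True], np.diff(hashes) != 0]))
    ends = np.concatenate([starts[1:], [len(hashes)]])
    for a, b in zip(starts, ends):
        if b - a > 1:
            group = np.sort(owners[a:b])
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    inter[group[i], group[j]] += 1
    inter = inter + inter.T
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        D = 1.0 - inter / union
    np.fill_diagonal(D, 0.0)
    return D


# -- trees ------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a (guide) tree; leaves carry genome names."""

    name: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def newick(self) -> str:
        def rec(n):
            if n.is_leaf:
                return f"{n.name}:{n.length:.6g}"
            return f"({rec(n.left)},{rec(n.right)}):{n.length:.6g}"
        return rec(self) + ";"


def neighbor_joining(D: np.ndarray, labels: list[str]) -> TreeNode:
    """Classical neighbour joining, rooted at the final agglomeration.

    Ties in the Q criterion are broken by the smallest (i, j) pair in the
    current node ordering, making the result deterministic.  Only the
    left-to-right leaf ordering matters downstream.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes = [TreeNode(name=lab) for lab in labels]
    if n == 1:
        return nodes[0]
    D = D.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j)
        best = np.unravel_index(np.argmin(Q), Q.shape)
        i, j = sorted(best)
        di = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        dj = sub[i, j] - di
        a, b = active[i], active[j]
        parent = TreeNode(left=nodes[a], right=nodes[b])
        nodes[a].length = max(di, 0.0)
        nodes[b].length = max(dj, 0.0)
        new_row = 0.5 * (D[a, active] + D[b, active] - D[a, b])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = new_row
        D[active, -1] = new_row
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]
    a, b = active
    root = TreeNode(left=nodes[a], right=nodes[b])
    half = 0.5 * D[a, b]
    nodes[a].length = nodes[b].length = max(half, 0.0)
    return root


def balance_guide_tree(tree: TreeNode) -> TreeNode:
    """Balanced binary tree preserving the input tree's leaf order.

    Built by recursive halving of the leaf sequence; the result has depth
    ``ceil(log2 n)``, maximizing the number of independent merge jobs.
    """
    order = tree.leaves()

    def rec(names: list[str]) -> TreeNode:
        if len(names) == 1:
            return TreeNode(name=names[0])
        mid = (len(names) + 1) // 2
        return TreeNode(left=rec(names[:mid]), right=rec(names[mid:]))

    return rec(order)


@dataclass
class MergeJob:
    """One internal guide-tree node: merge the graphs of two leaf sets."""

    id: int
    left_leaves: tuple[str, ...]
    right_leaves: tuple[str, ...]
    depends_on: tuple[int, ...] = field(default_factory=tuple)

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.left_leaves + self.right_leaves


def merge_schedule(tree: TreeNode) -> list[MergeJob]:
    """Post-order list of merge jobs with explicit dependencies.

    Jobs whose leaf sets are disjoint carry no dependency on each other and
    may run in any relative order (or concurrently); the merged graph is
    required to be identical regardless.
    """
    jobs: list[MergeJob] = []

    def rec(node: TreeNode) -> tuple[tuple[str, ...], int | None]:
        if node.is_leaf:
            return (node.name,), None
        ll, lj = rec(node.left)
        rl, rj = rec(node.right)
        deps = tuple(j for j in (lj, rj) if j is not None)
        job = MergeJob(len(jobs), ll, rl, deps)
        jobs.append(job)
        return ll + rl, job.id

    if not tree.is_leaf:
        rec(tree)
    return jobs


def build_guide_tree(genomes: list[tuple[str, str]],
                     params: SketchParams = SketchParams()) -> TreeNode:
    """Sketch genomes, estimate distances, NJ, and balance."""
    names = [n for n, _ in genomes]
    if len(genomes) == 1:
        return TreeNode(name=names[0])
    sketches = [sketch_genome([seq], params) for _, seq in genomes]
    D = jaccard_distance_matrix(sketches)
    return balance_guide_tree(neighbor_joining(D, names))
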
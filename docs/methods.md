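# Methods

This note documents the models and algorithmic choices in `panblocks`, the
parameters that matter, and what the synthetic benchmarks do and do not
demonstrate.

## Graph model

A graph is a set of **blocks** and **paths**. A block holds a non-empty
consensus sequence and one *occurrence* per visit of a genome: the path
name, orientation, and a sorted, non-overlapping list of edits
(substitution, insertion, deletion) against the consensus. Coordinates are
0-based, half-open, on the block consensus; an insertion at offset *p*
inserts before consensus base *p*. Edits are stored against the consensus
rather than pairwise between members — a star-phylogeny model of the
in-block alignment: each member differs independently from one reference
row. A path is an ordered, oriented walk over blocks with a `circular`
flag and a rotation `offset` (bp) so that a circular chromosome's stored
walk may begin anywhere; reconstruction concatenates the edited (and, for
reverse steps, reverse-complemented) segments and rotates. The defining
invariant, enforced after every mutating operation and in every test, is
exact round-tripping of all input genomes.

Consensus recomputation materializes the implied gapped alignment
(insertions at the same offset share a left-aligned gap slot), takes a
column-wise majority, and re-derives all edits from the alignment rows.
Ties between bases resolve to the lexicographically smallest base; a gap
wins a column only with a strict majority over the best base; IUPAC
ambiguity codes are preserved verbatim in members but never vote unless a
column contains nothing else. `polish` iterates optimal pairwise
re-alignment of each member against the consensus (edlib, global) with
majority re-voting until the total edit count stops decreasing; this
removes double-counted indels left by progressive merging. A
profile–profile MSA would be marginally more accurate here, but iterative
refinement has the same conservation guarantees with far less machinery,
and block alignments start near-optimal because merging only ever joins
consensuses below the divergence ceiling.

## Guide tree

Genomes are sketched into minimizer sets: canonical (strand-symmetric)
k-mers hashed with an invertible 64-bit mixer, windowed minima collected
over `w` consecutive positions. Defaults `k=15`, `w=10` are conventional
minimizer settings — dense enough that 20–100 kb test genomes yield stable
distance estimates, sparse enough to stay cheap on 5 Mb chromosomes.
Pairwise Jaccard distances are computed by one global sort of all
minimizers rather than per-pair set intersections. Neighbour joining is
the classical dense O(n³) algorithm (adequate for the ≤ few hundred
genomes this package targets), with Q-criterion ties broken by the
smallest node-index pair; root placement is at the final agglomeration and
is irrelevant downstream because only the left-to-right leaf order
survives balancing. The balanced tree is built by recursive halving of the
leaf order (depth ⌈log₂ n⌉). Merge jobs in disjoint subtrees are
independent; the final graph is required (and tested) to be byte-identical
in its canonical JSON export no matter how independent jobs are ordered.
Canonical exports are possible because block identifiers are regenerated
from content — each block is keyed by its first occurrence in path
order — after every merge job.

## Alignment kernels

The kernel contract is: two sets of `(id, consensus)` pairs in, `Hit`
records (intervals, strand, `=/X/I/D` CIGAR, match count) out. Two
kernels implement it:

* **minimap2** (default, preset `asm20`): all-vs-all with `-X -c --eqx`,
  which drops the trivial self-diagonal and mirrored duplicates but keeps
  off-diagonal self-hits, so duplications within one genome are found.
* **builtin**: unique canonical 13-mer anchors, greedy diagonal chaining
  (band 150 bp, max gap 800 bp), global edlib extension of each chained
  region. It exists so the package runs and is testable with no external
  binaries, and it doubles as an independent cross-check of the minimap2
  adapter in the test suite. It is adequate below ~5 % divergence and on
  the simulator's genome sizes; minimap2 is preferred for real data.

A configuration slot for an mmseqs2-style high-sensitivity kernel exists
but is deliberately unimplemented.

Hits shorter than `L_min` are dropped at the kernel boundary. Before
scoring, hits are subdivided at indels ≥ `L_min`: aligners chain through
large insertions/deletions (and can encode an inversion as a pair of giant
indels), but structure at or above the minimal block scale belongs in
graph topology, not inside a block alignment. Without this subdivision,
whole genomes can collapse into a single block that hides true structural
breakpoints as bulk edits.

## Merging

Each candidate merger is scored by the pseudo-energy
`E = -l + alpha*N_c + beta*N_m` in basepair equivalents. `N_c` counts the
cuts that do not coincide with a block end — a hit boundary within `L_min`
of an end snaps to the end, absorbing the short flank into the merged
alignment as a terminal indel. `N_m` counts polymorphism events in the
consensus–consensus CIGAR, where each indel counts once regardless of
length (an indel is one evolutionary event; a long insertion should not
veto a merger the way the same number of substitutions would). Only
`E < 0` candidates are applied, sorted by energy (ties: longer alignment,
then lexicographic block-id pair). Conflict resolution is greedy at block
granularity per round: once a block is touched, other candidates on it
wait for the next round's re-alignment, which rediscovers surviving
homology. Defaults `alpha=100`, `beta=10`, `L_min=100` bp give the
divergence ceiling `1/beta = 10 %` on consensus–consensus comparisons.

Applying a merger splits both blocks at the snapped boundaries and fuses
the two homologous pieces: the reference-side consensus hosts the fusion,
each incoming member is re-expressed against it by optimal global
alignment (reverse-strand hits flip the incoming occurrences), and the
consensus is majority-revoted. Re-aligning members directly, instead of
composing their edits through the hit CIGAR, is exact by construction and
immune to coordinate-bookkeeping errors; it costs one edlib alignment per
incoming member, negligible at the divergences the energy admits. The
merge loop (align all-vs-all including self, score, apply) runs to a fixed
point, with a safety cap of 64 rounds that raises a warning if ever hit.
After each pairwise job, transitive chains — block pairs adjacent with the
same relative orientation in every occurrence, at equal depth — are fused
by concatenation; fusing across a circular path's stored origin adjusts
that path's rotation offset. A circular single-block path adjacent to
itself is left alone.

## Simulator

`simulate_population` runs a Wright–Fisher population of `n` circular
genomes for `T` generations (default 50) from one random ancestor. Each
child draws Poisson event counts: substitutions at `mu` per site per
generation; inversions at 0.01 and deletions at 0.05 per genome per
generation; horizontal transfer at a tunable rate (default 0.1). Event
lengths are geometric (means: inversions 5 000 bp, deletions 500 bp,
transfers 5 000 bp) — bacterial structural variants span orders of
magnitude and the geometric is the natural maximum-entropy choice given
only a mean. Transfer copies a donor segment over the recipient's
homologous locus, located by following the donor segment's first ancestral
coordinate into the recipient (uniform fallback if that coordinate was
lost); the replaced extant length equals the donor segment length, so
transfer is length-neutral. Deletions that would shrink a genome below a
floor (default 1 000 bp) are skipped with a warning. Event order within a
child is inversions, deletions, transfers, then substitutions; at these
rates multiple structural events per child per generation are rare, so the
order is immaterial in distribution.

Every genome carries an exact decomposition into ancestral intervals
`(start, end, strand)`; substitution lists are recoverable by diffing
(structural events never change interval-internal alignment). The helper
`mutation_rate_for_divergence` inverts the expected pairwise coalescence
time `E[min(T2, T)] = N(1-(1-1/N)^T)` to hit a target average pairwise
divergence.

Two truth surfaces exist. `true_breakpoints` lists, per genome, junctions
that are discontinuous in ancestor coordinates. `truth_to_graph` converts
the truth into an actual pangenome graph: the ancestor is atomized at all
observed interval boundaries, atoms become blocks, and transitive
compaction removes junctions identical in every genome. The distinction
matters: an event fixed in the entire sample (it happened before the
sample's common ancestor) leaves *no signal* in the extant sequences, and
no alignment-based method can recover it; the compacted true graph is the
correct benchmark target, while the raw ancestor-relative lists describe
each genome's full history.

## Metrics

Breakpoints of a graph are its block junctions in emitted-genome
coordinates (circular paths include the wrap junction; a single-block
circular path has none — the genome is one contiguous block around the
circle). Two breakpoint sets are paired greedily, closest first, within a
window (default 1 kb, circular distances); an optimal min-cost assignment
variant is available and is used as the test oracle. The misplaced
fraction counts paired breakpoints displaced beyond a threshold (default
100 bp = `L_min`); unpaired breakpoints are excluded by default and
reported separately, with an option to count them as misplaced.

`graph_summary` reports compression (pangenome length over summed genome
lengths), core length/fraction (blocks present exactly once in every
genome), and L50/N50 over block lengths. `partition_compare` labels every
position of a genome pair shared/private under two graphs and classifies
the intersection partition into agree-shared / agree-private / disagree
with genome-length fractions and mean run lengths. The shared-sequence
estimate is the canonical 21-mer containment fraction (intersection over
the smaller set — containment, because genome lengths differ) divided by
`(1-d)^k` to correct for k-mers broken by point mutations at core
divergence `d`, capped at 1 with a warning.

## Marginalization

Projection onto a strain subset removes the other paths, deletes emptied
blocks, revotes each surviving consensus from the remaining members, and
compacts transitive chains — no re-alignment. Nested projections agree
with direct projections in structure (block boundaries, reconstructions);
consensus bytes can differ by equivalent alignment choices since majority
voting depends on the membership at the time of the vote.

## Problem sizes and what the benchmarks show

The shipped tests and acceptance checks run the full pipeline at reduced
scale: populations of 8–25 genomes of 20–100 kb, chosen so the entire
suite completes in a few minutes while every code path (duplications,
inversions, circular origins, transfer mosaics) is exercised. The
simulator emulates the dominant structural processes of bacterial
chromosome evolution but not selection, recombination hotspots, mobile
element biology, or assembly artefacts; passing benchmarks demonstrate
algorithmic correctness and the method's resolution limits (the `L_min`
precision scale, the `1/beta` divergence ceiling, loss of aligner
sensitivity beyond ~5–10 %), not performance on any particular real
dataset. On real data the same limits apply: species whose core divergence
approaches the kernel's sensitivity will under-merge, and sub-`L_min`
structure is represented inside block alignments, not in graph topology.

## Degenerate inputs and numerical conventions

Empty genomes, duplicate genome names, cuts outside `(0, L)`, unknown
path/block ids and malformed CIGARs raise typed errors. A depth-1 block's
consensus is its member sequence. Majority voting that would delete an
entire consensus leaves the block unchanged. All orderings that affect
output (hit sorting, candidate ties, export order) are made explicit and
content-derived, so a fixed input and parameter set yields byte-identical
outputs across runs and job schedules.
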
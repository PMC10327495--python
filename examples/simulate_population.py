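"""Simulate a bacterial population with structural variation.

Runs the Wright-Fisher simulator (substitutions, inversions, deletions,
horizontal transfer) and prints, per genome, its final length and its true
structural breakpoints: the positions where the extant chromosome stops
being contiguous in ancestor coordinates.  Genomes shorter than the
ancestral 50 kb lost sequence to deletions; transfer is length-neutral.
"""
from panblocks.simulate import (SimParams, simulate_population,
                                true_breakpoints)

params = SimParams(n=6, length=50_000, generations=50, mu=2e-4,
                   inv_rate=0.01, del_rate=0.05, hgt_rate=0.1, seed=7)
genomes, truth = simulate_population(params)
breakpoints = true_breakpoints(truth)

print(f"ancestor length: {params.length} bp, {params.generations} generations")
for name, seq in genomes:
    bp = breakpoints[name]
    print(f"{name}: {len(seq)} bp, {len(bp)} true breakpoints at {bp}")
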
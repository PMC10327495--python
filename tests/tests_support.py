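"""Shared brute-force oracles used by multiple test modules."""
import numpy as np

from panblocks._seq import revcomp, splitmix64


def brute_force_sketch(seq, k, w):
    """O(L*w) reference minimizer sketch: canonical k-mer hash minimum of
    every window, skipping k-mers with non-ACGT bases."""
    hashes = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) - set("ACGT"):
            hashes.append(None)
            continue

        def enc(s):
            return sum("ACGT".index(c) << (2 * (k - 1 - j))
                       for j, c in enumerate(s))
        code = min(enc(kmer), enc(revcomp(kmer)))
        hashes.append(int(splitmix64(np.array([code], dtype=np.uint64))[0]))
    out = set()
    for i in range(len(hashes) - w + 1):
        window = [h for h in hashes[i:i + w] if h is not None]
        if window:
            out.add(min(window))
    return out
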
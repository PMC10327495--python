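"""Low-level nucleotide helpers shared across modules."""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: encoding used for k-mer arithmetic; anything not ACGT is invalid (code 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and case."""
    return seq.translate(_COMP)[::-1]


def seq_codes(seq: str) -> np.ndarray:
    """Per-base 2-bit codes (A=0 C=1 G=2 T=3); 4 marks non-ACGT bases."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-symmetric) k-mer codes at every offset.

    Returns ``(codes, valid)`` where ``codes[i]`` encodes the canonical form
    of ``seq[i:i+k]`` as a 2k-bit integer and ``valid[i]`` is False when the
    window contains a non-ACGT base.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    b = seq_codes(seq)
    if len(b) < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(b, k)
    valid = (win < 4).all(axis=1)
    w64 = win.astype(np.uint64)
    pw_f = (np.uint64(1) << (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    fwd = w64 @ pw_f
    # reverse complement read: complement bases, reversed order
    pw_r = (np.uint64(1) << (np.uint64(2) * np.arange(k, dtype=np.uint64)))
    rev = ((np.uint64(3) - w64) % np.uint64(4)) @ pw_r
    return np.minimum(fwd, rev), valid


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Invertible 64-bit finalizer used to hash k-mer codes."""
    with np.errstate(over="ignore"):
        z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def canonical_kmer_set(seq: str, k: int = 21) -> set[int]:
    """Set of canonical k-mer codes of a sequence (non-ACGT windows skipped)."""
    codes, valid = kmer_codes(seq, k)
    return set(codes[valid].tolist())


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
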
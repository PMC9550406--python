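"""Sliding-window k-mer count features for k in {3, 4, 5}.

Each segment maps to a vector of length 4^k indexed by the lexicographic
order of k-mers over {A, C, G, T} (AAA.., AAC.., ...).  Windows containing
'N' are skipped, so on N-free segments the counts sum to L - k + 1.
Strand is meaningful for single-stranded RNA: a k-mer and its reverse
complement are distinct features.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .segments import Segment

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_labels(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order (the feature column names)."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


def encode_kmer(segment: Segment | str, k: int, normalize: bool = False) -> np.ndarray:
    """Count every length-k window of the segment, stride 1.

    With ``normalize=True`` counts are divided by their sum (frequencies);
    an all-N segment normalizes to the zero vector.
    """
    seq = segment.seq if isinstance(segment, Segment) else segment
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds segment length {len(seq)}")
    codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
    counts = np.zeros(4**k, dtype=float)
    # rolling base-4 index over the last k bases; reset at every N
    idx = 0
    valid = 0  # consecutive non-N bases ending at the current position
    mod = 4**k
    for c in codes:
        if c < 0:
            valid = 0
            idx = 0
            continue
        idx = (idx * 4 + c) % mod
        valid += 1
        if valid >= k:
            counts[idx] += 1
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return counts
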
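"""Position-wise Shannon-entropy / information-content encoding of segments.

For a set of aligned equal-length segments, the per-position nucleotide
distribution p_{i,b} measures how conserved position i is.  Shannon entropy

    H_i = -sum_b p_{i,b} log2 p_{i,b}        (bits, 0 <= H_i <= 2)

is maximal (2 bits) for a uniform position and zero for a fully conserved
one; the information content of base b at position i,

    ic_{i,b} = p_{i,b} * (2 - H_i),

is the familiar logo-height contribution of that base.  Binding sites sit
in a conserved motif window, so the entropy of the positive (binding)
training set dips below that of the negative set there; the per-position
difference H_neg - H_int is the conservation-difference track.

A segment is turned into a feature vector by PSSM-style lookup: at each
position, the information content of the *observed* base under the positive
profile and under the negative profile (2L features for length-L segments).
Profiles must be built from training data only, and are frozen (read-only
arrays) once built so that encoding held-out segments can never leak into
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segments import Segment, SegmentSet

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MAX_ENTROPY_BITS = 2.0  # log2(4), four-letter alphabet


def _freeze(a: np.ndarray) -> np.ndarray:
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class PositionProfile:
    """Per-position base counts and (pseudocounted) probabilities."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    counts: np.ndarray  # (L, 4) raw counts, N excluded
    pseudocount: float
    n_sequences: int

    def __post_init__(self) -> None:
        if self.probs.shape != self.counts.shape or self.probs.shape[1] != 4:
            raise ValueError("profile matrices must be (L, 4) and congruent")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("each probability row must sum to 1")
        _freeze(self.probs)
        _freeze(self.counts)

    @property
    def length(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class IEProfile:
    """Entropy vector plus per-base information-content matrix."""

    entropy: np.ndarray  # (L,) bits
    ic: np.ndarray  # (L, 4), ic[i,b] = p[i,b] * (2 - H_i)
    source: PositionProfile

    def __post_init__(self) -> None:
        _freeze(self.entropy)
        _freeze(self.ic)

    @property
    def length(self) -> int:
        return self.entropy.shape[0]


@dataclass(frozen=True)
class DifferenceTrack:
    """Per-position entropy difference, nonbinding minus binding (bits).

    Positive values mean the binding set is the more conserved at that
    position; for motif-driven binding the track peaks across the motif
    window around the central site base.
    """

    delta_entropy: np.ndarray

    def __post_init__(self) -> None:
        _freeze(self.delta_entropy)


def build_profile(
    segments: SegmentSet | Iterable[Segment], pseudocount: float = 1.0
) -> PositionProfile:
    """Count bases per position and convert to pseudocounted probabilities.

    p_{i,b} = (count_{i,b} + pseudocount) / (sum_b count_{i,b} + 4*pseudocount).
    'N' bases contribute nothing.  Add-one smoothing is the default so no
    probability is ever exactly zero on small training sets.
    """
    segs = list(segments)
    if not segs:
        raise ValueError("cannot build a profile from an empty set")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    L = len(segs[0].seq)
    counts = np.zeros((L, 4), dtype=np.int64)
    for s in segs:
        if len(s.seq) != L:
            raise ValueError(f"segment {s.id!r} length {len(s.seq)} != {L}")
        for i, b in enumerate(s.seq):
            j = BASE_INDEX.get(b)
            if j is not None:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    if pseudocount == 0 and np.any(totals == 0):
        bad = int(np.flatnonzero(totals[:, 0] == 0)[0])
        raise ValueError(
            f"position {bad} has zero effective count and zero pseudocount"
        )
    probs = (counts + pseudocount) / (totals + 4.0 * pseudocount)
    return PositionProfile(
        probs=probs, counts=counts, pseudocount=float(pseudocount), n_sequences=len(segs)
    )


def entropy(profile: PositionProfile) -> np.ndarray:
    """Shannon entropy per position in bits, with 0*log2(0) := 0."""
    p = profile.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -terms.sum(axis=1)
    # clip the tiny negative round-off at fully conserved positions
    return np.clip(h, 0.0, MAX_ENTROPY_BITS)


def information_content(profile: PositionProfile) -> IEProfile:
    """ic[i,b] = p[i,b] * (2 - H_i); sums over b to 2 - H_i per position."""
    h = entropy(profile)
    ic = profile.probs * (MAX_ENTROPY_BITS - h)[:, None]
    return IEProfile(entropy=h, ic=ic, source=profile)


def difference_profile(
    pos: PositionProfile, neg: PositionProfile
) -> DifferenceTrack:
    """Conservation-difference track H_negative - H_positive per position."""
    if pos.length != neg.length:
        raise ValueError(f"profile lengths differ: {pos.length} vs {neg.length}")
    return DifferenceTrack(delta_entropy=entropy(neg) - entropy(pos))


def encode_ie(segment: Segment, pos_ie: IEProfile, neg_ie: IEProfile) -> np.ndarray:
    """PSSM-style information-content features of one segment.

    Returns a 2L vector: entry i is the information content of the observed
    base at position i under the positive-training profile, entry L+i the
    same under the negative profile.  'N' positions contribute 0.
    """
    L = len(segment.seq)
    if pos_ie.length != L or neg_ie.length != L:
        raise ValueError(
            f"segment length {L} does not match profiles "
            f"({pos_ie.length}, {neg_ie.length})"
        )
    out = np.zeros(2 * L, dtype=float)
    for i, b in enumerate(segment.seq):
        j = BASE_INDEX.get(b)
        if j is not None:
            out[i] = pos_ie.ic[i, j]
            out[L + i] = neg_ie.ic[i, j]
    return out


def profile_to_frame(profile: PositionProfile) -> pd.DataFrame:
    """Tabular view (1-based position, p_A..p_T, H) for inspection/plotting."""
    h = entropy(profile)
    return pd.DataFrame(
        {
            "position": np.arange(1, profile.length + 1),
            **{f"p_{b}": profile.probs[:, i] for i, b in enumerate(BASES)},
            "H": h,
        }
    )


def write_profile_tsv(profile: PositionProfile, path: str | Path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False, float_format="%.6f")
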
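"""Synthetic segment sets with the statistical structure of CLIP-derived data.

Positives are background sequence with a PWM-sampled motif implanted in the
central window (1-based positions 48-54 for the default 7-mer, mirroring
where real binding motifs concentrate around the crosslink site at base 51);
negatives are pure background.  Not every bound segment carries a clean
motif in real libraries, so only a fraction of positives (default 0.9)
receive the implant.

:func:`structure_toy` produces paired dot-bracket strings in which positives
fold into a central hairpin while negatives keep the central window inside
a stem, for end-to-end tests of the structure encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import Segment, SegmentSet
from .structure import pairing_table

BASES = "ACGT"
DEFAULT_LENGTH = 101
DEFAULT_PLACEMENT = 47  # 0-based; 1-based window 48-54 for a 7-mer
DEFAULT_CONSENSUS = "TATTTAT"  # A/T-rich, like QKI-style motifs
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


def consensus_pwm(consensus: str = DEFAULT_CONSENSUS, dominant: float = 0.85) -> np.ndarray:
    """PWM with `dominant` probability on the consensus base at each row."""
    if not 0.25 <= dominant <= 1.0:
        raise ValueError("dominant probability must be in [0.25, 1]")
    off = (1.0 - dominant) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        pwm[i, BASES.index(b)] = dominant
    return pwm


@dataclass(frozen=True)
class MotifSpec:
    """Motif PWM, its placement, and the fraction of positives carrying it."""

    pwm: np.ndarray
    placement: int = DEFAULT_PLACEMENT
    implant_fraction: float = 0.9

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("pwm must be (motif length, 4)")
        if np.any(pwm < 0) or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must be probability vectors")
        if not 0.0 < self.implant_fraction <= 1.0:
            raise ValueError("implant_fraction must be in (0, 1]")
        if self.placement < 0:
            raise ValueError("placement must be nonnegative")

    @property
    def motif_length(self) -> int:
        return np.asarray(self.pwm).shape[0]


def default_motif(dominant: float = 0.85, implant_fraction: float = 0.9) -> MotifSpec:
    return MotifSpec(pwm=consensus_pwm(dominant=dominant), implant_fraction=implant_fraction)


def _sample_background(rng: np.random.Generator, n: int, length: int, bg: np.ndarray) -> list[str]:
    codes = rng.choice(4, size=(n, length), p=bg)
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[codes]]


def generate(
    spec: MotifSpec,
    n_pos: int,
    n_neg: int,
    length: int = DEFAULT_LENGTH,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    seed: int = 0,
) -> SegmentSet:
    """Labeled motif-implantation benchmark set; deterministic per seed."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a probability 4-vector")
    if spec.placement + spec.motif_length > length:
        raise ValueError("motif does not fit at its placement within the segment")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for i, seq in enumerate(_sample_background(rng, n_pos, length, bg)):
        if rng.random() < spec.implant_fraction:
            motif = "".join(
                BASES[rng.choice(4, p=row)] for row in np.asarray(spec.pwm, dtype=float)
            )
            seq = seq[: spec.placement] + motif + seq[spec.placement + spec.motif_length :]
        segments.append(Segment(id=f"pos_{i:05d}", seq=seq, label=1))
    for i, seq in enumerate(_sample_background(rng, n_neg, length, bg)):
        segments.append(Segment(id=f"neg_{i:05d}", seq=seq, label=0))
    return SegmentSet(segments, protein="synthetic", source_dataset="synthetic")


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _structured_sequence(rng: np.random.Generator, db: str) -> str:
    """Random sequence consistent with a dot-bracket (paired bases complement)."""
    pair = pairing_table(db)
    seq = [""] * len(db)
    for i in range(len(db)):
        if pair[i] == -1 or pair[i] > i:
            seq[i] = BASES[rng.integers(4)]
        else:
            seq[i] = _PAIR[seq[pair[i]]]
    return "".join(seq)


def _hairpin_db(length: int, stem: int, loop: int, loop_center: int) -> str:
    """Dots + one stem-loop whose loop is centered at `loop_center`."""
    loop_start = loop_center - loop // 2
    open_start = loop_start - stem
    close_end = loop_start + loop + stem
    if open_start < 0 or close_end > length:
        raise ValueError("stem-loop does not fit")
    return (
        "." * open_start
        + "(" * stem
        + "." * loop
        + ")" * stem
        + "." * (length - close_end)
    )


def structure_toy(
    n: int, seed: int = 0, length: int = DEFAULT_LENGTH
) -> tuple[SegmentSet, list[str]]:
    """Paired set + dot-brackets: positive hairpin loops sit in the central
    window, negative stems cover it (their loops pushed toward the 5' end).

    Returns the segment set (structure strings attached) and the raw
    dot-bracket list in the same order, for feeding external annotators.
    """
    if n < 2:
        raise ValueError("need at least 2 segments (one per class)")
    rng = np.random.default_rng(seed)
    center = length // 2
    n_pos = n // 2 + n % 2
    segments: list[Segment] = []
    brackets: list[str] = []
    from .structure import annotate  # local import to avoid cycle at module load

    for i in range(n):
        positive = i < n_pos
        stem = int(rng.integers(8, 13))
        loop = int(rng.integers(5, 9))
        if positive:
            db = _hairpin_db(length, stem, loop, loop_center=center)
        else:
            # loop pushed 5' so the closing stem spans the center (S there)
            shift = stem // 2 + (loop - loop // 2)
            db = _hairpin_db(length, stem, loop, loop_center=center - shift)
        seq = _structured_sequence(rng, db)
        label = 1 if positive else 0
        sid = f"{'pos' if positive else 'neg'}_{i:05d}"
        segments.append(Segment(id=sid, seq=seq, label=label, structure=annotate(db)))
        brackets.append(db)
    return SegmentSet(segments, protein="toy", source_dataset="toy"), brackets
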
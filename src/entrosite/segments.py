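"""Labeled RNA segment sets: I/O, windowing, dataset merging and splitting.

A *segment* is a fixed-length nucleotide window (default 101 nt) centered on
a candidate protein-binding site; the center base is the 51st (1-based).
Sequences are normalized to the DNA alphabet on ingest (U -> T) and may
contain 'N' for ambiguous calls.  Labels are binary: 1 = binding (positive),
0 = nonbinding (negative).

CLIP-seq experiments frequently assay the same protein under different
protocols; :func:`merge_groups` pools per-experiment sets into one
per-protein set, driven by a manifest mapping each dataset to a group
letter.  The built-in :func:`clip_manifest` reproduces the canonical 31
experiment -> 19 protein grouping, in which the MNase-digested Ago2 and
ELAVL1 libraries count as distinct proteins.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_SEGMENT_LENGTH = 101
DEFAULT_FLANK = 50

_SEQ_ALPHABET = set("ACGTN")
_STRUCT_ALPHABET = set("SMHITF")


@dataclass(frozen=True)
class Segment:
    """One labeled RNA segment, optionally with a six-state structure string."""

    id: str
    seq: str
    label: int
    structure: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"segment {self.id!r}: label must be 0 or 1, got {self.label!r}")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"segment {self.id!r}: invalid characters {sorted(bad)} (alphabet is A/C/G/T/N)"
            )
        if self.structure is not None:
            if len(self.structure) != len(self.seq):
                raise ValueError(
                    f"segment {self.id!r}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.seq)}"
                )
            badst = set(self.structure) - _STRUCT_ALPHABET
            if badst:
                raise ValueError(
                    f"segment {self.id!r}: invalid structure states {sorted(badst)}"
                )


class SegmentSet:
    """Ordered collection of equal-length segments with unique ids."""

    def __init__(
        self,
        segments: Iterable[Segment],
        protein: str = "",
        source_dataset: str = "",
    ) -> None:
        self.segments: list[Segment] = list(segments)
        self.protein = protein
        self.source_dataset = source_dataset
        self._validate()

    def _validate(self) -> None:
        lengths = {len(s.seq) for s in self.segments}
        if len(lengths) > 1:
            raise ValueError(f"segments have mixed lengths: {sorted(lengths)}")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate segment ids: {sorted(dups)[:5]}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> Segment:
        return self.segments[i]

    @property
    def segment_length(self) -> int:
        if not self.segments:
            raise ValueError("empty segment set has no length")
        return len(self.segments[0].seq)

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.segments]

    def subset(self, labels: Iterable[int] | None = None) -> "SegmentSet":
        """Segments whose label is in `labels` (all segments if None)."""
        want = None if labels is None else set(labels)
        kept = [s for s in self.segments if want is None or s.label in want]
        return SegmentSet(kept, protein=self.protein, source_dataset=self.source_dataset)

    def positives(self) -> "SegmentSet":
        return self.subset([1])

    def negatives(self) -> "SegmentSet":
        return self.subset([0])


@dataclass(frozen=True)
class Split:
    """Stratified train/test partition of one segment set."""

    train: SegmentSet
    test: SegmentSet
    ratio: tuple[int, int]
    seed: int


def normalize_seq(raw: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet (U -> T)."""
    return raw.upper().replace("U", "T")


def read_segments(
    fasta_path: str | Path,
    labels_path: str | Path,
    structures_path: str | Path | None = None,
    segment_length: int | None = DEFAULT_SEGMENT_LENGTH,
    protein: str = "",
    source_dataset: str = "",
) -> SegmentSet:
    """Read a segment set from FASTA plus a two-column (id <TAB> label) TSV.

    Structure strings, if given, are plain text with one line per FASTA
    record in the same order.  Set ``segment_length=None`` to accept any
    uniform length.
    """
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(labels_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{labels_path}:{lineno}: expected 'id<TAB>label', got {line!r}")
        labels[parts[0]] = int(parts[1])

    structures: list[str] | None = None
    if structures_path is not None:
        structures = [
            ln.strip() for ln in Path(structures_path).read_text().splitlines() if ln.strip()
        ]

    segments: list[Segment] = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        seq = normalize_seq(str(rec.seq))
        if segment_length is not None and len(seq) != segment_length:
            raise ValueError(
                f"record {rec.id!r}: length {len(seq)} != configured segment length {segment_length}"
            )
        if rec.id not in labels:
            raise ValueError(f"record {rec.id!r}: no label in {labels_path}")
        structure = None
        if structures is not None:
            if i >= len(structures):
                raise ValueError(f"record {rec.id!r}: no structure line at position {i}")
            structure = structures[i]
        segments.append(Segment(id=rec.id, seq=seq, label=labels[rec.id], structure=structure))
    return SegmentSet(segments, protein=protein, source_dataset=source_dataset)


def write_segments(
    segset: SegmentSet,
    fasta_path: str | Path,
    labels_path: str | Path,
    structures_path: str | Path | None = None,
) -> None:
    """Write FASTA + label TSV (+ optional structure text, one line/record)."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in segset
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    Path(labels_path).write_text("".join(f"{s.id}\t{s.label}\n" for s in segset))
    if structures_path is not None:
        missing = [s.id for s in segset if s.structure is None]
        if missing:
            raise ValueError(f"segments without structure: {missing[:5]}")
        Path(structures_path).write_text("".join(f"{s.structure}\n" for s in segset))


def extract_window(sequence: str, center: int, flank: int = DEFAULT_FLANK) -> str:
    """Window of ``2*flank + 1`` bases around a 0-based center index.

    The site base sits at index `flank` of the output; a window running off
    either end of the sequence is an error (no silent padding).
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    lo, hi = center - flank, center + flank
    if lo < 0 or hi >= len(sequence):
        raise ValueError(
            f"window [{lo}, {hi}] exceeds sequence bounds [0, {len(sequence) - 1}]"
        )
    return sequence[lo : hi + 1]


@dataclass(frozen=True)
class ManifestRow:
    dataset_id: str
    protein: str
    group: str


class GroupManifest:
    """Maps experiment dataset ids to per-protein merge groups (letters)."""

    def __init__(self, rows: Iterable[ManifestRow | tuple[str, str, str]]) -> None:
        self.rows: list[ManifestRow] = [
            r if isinstance(r, ManifestRow) else ManifestRow(*r) for r in rows
        ]
        seen: dict[str, str] = {}
        for r in self.rows:
            if r.dataset_id in seen and seen[r.dataset_id] != r.group:
                raise ValueError(f"dataset {r.dataset_id!r} mapped to multiple groups")
            seen[r.dataset_id] = r.group

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def groups(self) -> list[str]:
        """Distinct group letters in first-appearance order."""
        out: list[str] = []
        for r in self.rows:
            if r.group not in out:
                out.append(r.group)
        return out

    def group_of(self, dataset_id: str) -> str:
        for r in self.rows:
            if r.dataset_id == dataset_id:
                return r.group
        raise KeyError(f"dataset {dataset_id!r} not in manifest")

    def protein_of_group(self, group: str) -> str:
        proteins = [r.protein for r in self.rows if r.group == group]
        if not proteins:
            raise KeyError(f"group {group!r} not in manifest")
        return proteins[0]


def read_manifest(path: str | Path) -> GroupManifest:
    """Read a TSV manifest with columns dataset_id, protein, group."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        rows.append(ManifestRow(*parts))
    return GroupManifest(rows)


# Canonical grouping of the 31 public CLIP-seq experiment datasets into 19
# per-protein groups A-S.  The MNase-digested Ago2 and ELAVL1 libraries are
# treated as distinct proteins (groups R and S) because nuclease digestion
# changes the footprint structure.
_CLIP_GROUPING: tuple[tuple[str, str, str], ...] = (
    ("01_Ago-EIF2C", "Ago2", "A"),
    ("03_Ago2-1", "Ago2", "A"),
    ("04_Ago2-2", "Ago2", "A"),
    ("05_Ago2", "Ago2", "A"),
    ("06_eIF4AIII-1", "eIF4AIII", "B"),
    ("07_eIF4AIII-2", "eIF4AIII", "B"),
    ("08_ELAVL1-1", "ELAVL1", "C"),
    ("10_ELAVL1A", "ELAVL1", "C"),
    ("11_ELAVL1-2", "ELAVL1", "C"),
    ("12_ESWR1", "ESWR1", "D"),
    ("13_FUS", "FUS", "E"),
    ("14_Mut-FUS", "FUS", "E"),
    ("15_IGF2BP1-3", "IGF2BP1-3", "F"),
    ("16_hnRNPC-1", "hnRNPC", "G"),
    ("17_hnRNPC-2", "hnRNPC", "G"),
    ("18_hnRNPL-1", "hnRNPL", "H"),
    ("19_hnRNPL-2", "hnRNPL", "H"),
    ("20_hnRNPL-like", "hnRNPL", "H"),
    ("21_MOV10", "MOV10", "I"),
    ("22_Nsun2", "Nsun2", "J"),
    ("23_PUM2", "PUM2", "K"),
    ("24_QKI", "QKI", "L"),
    ("25_SRSF1", "SRSF1", "M"),
    ("26_TAF15", "TAF15", "N"),
    ("27_TDP-43", "TDP-43", "O"),
    ("28_TIA1", "TIA1", "P"),
    ("29_TIAL1", "TIA1", "P"),
    ("30_U2AF2", "U2AF2", "Q"),
    ("31_U2AF2-KD", "U2AF2", "Q"),
    ("02_Ago2-MNase", "Ago2-MNase", "R"),
    ("09_ELAVL1-MNase", "ELAVL1-MNase", "S"),
)


def clip_manifest() -> GroupManifest:
    """The built-in 31-dataset -> 19-group CLIP-seq manifest."""
    return GroupManifest(_CLIP_GROUPING)


def merge_groups(
    manifest: GroupManifest, sets: Sequence[SegmentSet]
) -> dict[str, SegmentSet]:
    """Pool per-experiment sets into one set per group letter.

    Segment ids are prefixed with their source dataset so pooled ids stay
    unique; every input segment appears in exactly one output set.
    """
    by_group: dict[str, list[Segment]] = {}
    for segset in sets:
        if not segset.source_dataset:
            raise ValueError("input set has no source_dataset to look up in manifest")
        group = manifest.group_of(segset.source_dataset)  # KeyError if unmapped
        bucket = by_group.setdefault(group, [])
        for s in segset:
            bucket.append(replace(s, id=f"{segset.source_dataset}/{s.id}"))
    return {
        g: SegmentSet(segs, protein=manifest.protein_of_group(g), source_dataset=g)
        for g, segs in by_group.items()
    }


def train_test_split(
    segset: SegmentSet, ratio: tuple[int, int] = (5, 1), seed: int = 0
) -> Split:
    """Seeded, stratified partition into train:test = ratio.

    Each class is shuffled and sliced independently so class balance is
    preserved within rounding; rerunning with the same seed reproduces the
    membership exactly.
    """
    if not segset.segments:
        raise ValueError("cannot split an empty segment set")
    r_train, r_test = ratio
    if r_train <= 0 or r_test <= 0:
        raise ValueError("ratio parts must be positive")
    by_class: dict[int, list[Segment]] = {0: [], 1: []}
    for s in segset:
        by_class[s.label].append(s)
    if not by_class[0] or not by_class[1]:
        raise ValueError("both classes must be present to split")
    total = r_train + r_test
    train_segs: list[Segment] = []
    test_segs: list[Segment] = []
    rng = random.Random(seed)
    for label in (1, 0):
        members = list(by_class[label])
        if len(members) < total:
            raise ValueError(
                f"class {label} has {len(members)} segments, fewer than ratio sum {total}"
            )
        rng.shuffle(members)
        n_test = round(len(members) * r_test / total)
        n_test = min(max(n_test, 1), len(members) - 1)
        test_segs.extend(members[:n_test])
        train_segs.extend(members[n_test:])
    meta = dict(protein=segset.protein, source_dataset=segset.source_dataset)
    return Split(
        train=SegmentSet(train_segs, **meta),
        test=SegmentSet(test_segs, **meta),
        ratio=(r_train, r_test),
        seed=seed,
    )
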
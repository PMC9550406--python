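"""Per-protein ensemble-tree classifier over concatenated feature blocks.

A model is a bagged ensemble of randomized decision trees (random forest)
trained on any combination of the feature blocks:

    ie      2L information-content lookups (positive + negative profiles)
    3mer / 4mer / 5mer   sliding-window k-mer counts (64 / 256 / 1024)
    struct  one-hot six-state secondary-structure contexts (6L)

The prediction score of a segment is the fraction of trees voting for the
binding class, so thresholding and ROC construction stay threshold-free
downstream.  The feature schema (block names and widths) travels with the
trained model and is enforced at prediction time.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .entropy import IEProfile, encode_ie
from .kmers import encode_kmer
from .segments import SegmentSet
from .structure import encode_structure

DEFAULT_N_TREES = 500

KMER_BLOCKS = {"3mer": 3, "4mer": 4, "5mer": 5}


@dataclass(frozen=True)
class FeatureContext:
    """Trained encoders needed to featurize new segments.

    The information-content profiles must come from training data only;
    they are frozen arrays, so encoding held-out segments cannot alter them.
    """

    pos_ie: IEProfile | None = None
    neg_ie: IEProfile | None = None
    kmer_normalize: bool = False


@dataclass
class FeatureMatrix:
    """Segments x features table with named, ordered feature blocks."""

    values: np.ndarray
    block_names: list[str]
    block_widths: list[int]
    segment_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != sum(self.block_widths):
            raise ValueError("column count does not match block widths")
        if self.values.shape[0] != len(self.segment_ids) or self.values.shape[0] != len(
            self.labels
        ):
            raise ValueError("row count does not match ids/labels")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def schema(self) -> list[tuple[str, int]]:
        return list(zip(self.block_names, self.block_widths))


def _encode_one(segment, blocks: list[str], context: FeatureContext) -> list[np.ndarray]:
    parts = []
    for name in blocks:
        if name == "ie":
            if context.pos_ie is None or context.neg_ie is None:
                raise ValueError("'ie' block requires trained positive/negative profiles")
            parts.append(encode_ie(segment, context.pos_ie, context.neg_ie))
        elif name in KMER_BLOCKS:
            parts.append(
                encode_kmer(segment, KMER_BLOCKS[name], normalize=context.kmer_normalize)
            )
        elif name == "struct":
            if segment.structure is None:
                raise ValueError(f"segment {segment.id!r} has no structure annotation")
            parts.append(encode_structure(segment.structure))
        else:
            raise ValueError(f"unknown feature block {name!r}")
    return parts


def assemble_features(
    segset: SegmentSet, blocks: list[str], context: FeatureContext | None = None
) -> FeatureMatrix:
    """Horizontally concatenate the requested encoder outputs, in order."""
    if not blocks:
        raise ValueError("at least one feature block is required")
    context = context or FeatureContext()
    rows = []
    widths: list[int] | None = None
    for s in segset:
        parts = _encode_one(s, blocks, context)
        if widths is None:
            widths = [p.size for p in parts]
        rows.append(np.concatenate(parts))
    assert widths is not None
    return FeatureMatrix(
        values=np.vstack(rows),
        block_names=list(blocks),
        block_widths=widths,
        segment_ids=[s.id for s in segset],
        labels=np.array(segset.labels, dtype=int),
    )


def _fingerprint(features: FeatureMatrix) -> str:
    h = hashlib.sha256()
    for sid, lab in zip(features.segment_ids, features.labels):
        h.update(f"{sid}:{lab};".encode())
    return h.hexdigest()[:16]


@dataclass
class TrainedModel:
    """Fitted forest plus the feature schema it was trained on."""

    forest: RandomForestClassifier
    schema: list[tuple[str, int]]
    seed: int
    train_fingerprint: str
    oob_score: float | None = None

    def check_schema(self, features: FeatureMatrix) -> None:
        if features.schema != self.schema:
            raise ValueError(
                f"feature schema mismatch: model trained on {self.schema}, "
                f"got {features.schema}"
            )


def train(
    features: FeatureMatrix,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> TrainedModel:
    """Fit a bagged forest; deterministic for a fixed seed.

    Per-split feature subsampling defaults to sqrt(n_features), the standard
    random-forest rule.  The out-of-bag score is recorded when computable.
    """
    labels = np.unique(features.labels)
    if labels.size < 2:
        raise ValueError("training set must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        oob_score=True,
        n_jobs=1,
    )
    oob: float | None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny sets can lack OOB coverage
        try:
            forest.fit(features.values, features.labels)
            oob = float(forest.oob_score_)
        except ValueError:
            forest.set_params(oob_score=False)
            forest.fit(features.values, features.labels)
            oob = None
    return TrainedModel(
        forest=forest,
        schema=features.schema,
        seed=seed,
        train_fingerprint=_fingerprint(features),
        oob_score=oob,
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Score each row as the fraction of trees voting for class 1."""
    model.check_schema(features)
    votes = np.zeros(features.values.shape[0], dtype=float)
    for tree in model.forest.estimators_:
        votes += tree.predict(features.values)
    return votes / len(model.forest.estimators_)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the model with its schema header to one file."""
    joblib.dump(
        {
            "schema": model.schema,
            "seed": model.seed,
            "train_fingerprint": model.train_fingerprint,
            "oob_score": model.oob_score,
            "forest": model.forest,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(
        forest=payload["forest"],
        schema=[tuple(x) for x in payload["schema"]],
        seed=payload["seed"],
        train_fingerprint=payload["train_fingerprint"],
        oob_score=payload.get("oob_score"),
    )
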
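import numpy as np
import pytest

from entrosite import Segment, SegmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_set(seqs, labels, protein="p", dataset="d", ids=None):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return SegmentSet(
        [Segment(id=i, seq=q, label=l) for i, q, l in zip(ids, seqs, labels)],
        protein=protein,
        source_dataset=dataset,
    )


@pytest.fixture
def tiny_set():
    """Four 8-nt segments, two per class."""
    return make_set(
        ["ACGTACGT", "ACGTTTTT", "GGGGACGT", "TTTTACGT"],
        [1, 1, 0, 0],
    )


def random_dot_bracket(rng, length):
    """Random balanced dot-bracket string of exactly `length` symbols."""
    out = []
    depth = 0
    for i in range(length):
        remaining = length - i
        if remaining == depth:
            c = ")"  # must spend the rest closing
        else:
            choices = ["."]
            if depth > 0:
                choices.append(")")
            if remaining >= depth + 2:
                choices.append("(")
            c = choices[rng.integers(len(choices))]
        depth += (c == "(") - (c == ")")
        out.append(c)
    assert depth == 0
    return "".join(out)
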
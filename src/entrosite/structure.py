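"""Six-state annotation of RNA secondary structure from dot-bracket strings.

Folding itself is delegated to any external tool that emits Vienna
dot-bracket notation (RNAshapes, RNAfold, ...); this module only classifies
each position into one of six structural contexts:

    S  stem            paired base
    H  hairpin loop    unpaired, in a loop closed by one helix
    I  internal loop   unpaired, in a loop bounded by exactly two helices
                       (covers bulges)
    M  multiloop       unpaired, in a loop with three or more incident
                       helices (and exterior bases between helices)
    F  dangling start  unpaired, 5' of the first paired base
    T  dangling end    unpaired, 3' of the last paired base

Pseudoknots (anything beyond '(', ')', '.') are rejected.  One-hot encoding
of the annotation yields 6 features per position (606 for 101-nt segments).
"""

from __future__ import annotations

import numpy as np

STATES = "SMHITF"
STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def pairing_table(dot_bracket: str) -> list[int]:
    """Partner index per position (-1 if unpaired); errors if unbalanced."""
    bad = set(dot_bracket) - set("().")
    if bad:
        raise ValueError(
            f"unsupported symbols {sorted(bad)} (pseudoknots are not handled)"
        )
    pair = [-1] * len(dot_bracket)
    stack: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pair[i], pair[j] = j, i
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pair


def _loop_branches(pair: list[int], a: int) -> int:
    """Number of helices branching directly off the loop closed by pair (a, pair[a])."""
    b = pair[a]
    k = a + 1
    branches = 0
    while k < b:
        if pair[k] > k:
            branches += 1
            k = pair[k] + 1
        else:
            k += 1
    return branches


def annotate(dot_bracket: str) -> str:
    """Map a dot-bracket string to its six-state annotation.

    A fully unpaired string has no helix to dangle from; it is treated as
    one long 3' dangling end (all 'T').
    """
    pair = pairing_table(dot_bracket)
    n = len(pair)
    paired = [i for i in range(n) if pair[i] >= 0]
    if not paired:
        return "T" * n
    first, last = paired[0], paired[-1]

    # enclosing open-bracket index per position (-1 at the exterior loop)
    enclosing = [-1] * n
    stack: list[int] = []
    for i, p in enumerate(pair):
        if p > i:  # '('
            enclosing[i] = stack[-1] if stack else -1
            stack.append(i)
        elif p >= 0:  # ')'
            stack.pop()
            enclosing[i] = stack[-1] if stack else -1
        else:
            enclosing[i] = stack[-1] if stack else -1

    loop_state: dict[int, str] = {}  # opening index -> state of its unpaired bases
    out = []
    for i in range(n):
        if pair[i] >= 0:
            out.append("S")
        elif i < first:
            out.append("F")
        elif i > last:
            out.append("T")
        elif enclosing[i] == -1:
            # exterior base between two helices: closest in kind to a junction
            out.append("M")
        else:
            a = enclosing[i]
            if a not in loop_state:
                branches = _loop_branches(pair, a)
                loop_state[a] = "H" if branches == 0 else ("I" if branches == 1 else "M")
            out.append(loop_state[a])
    return "".join(out)


def encode_structure(annotation: str) -> np.ndarray:
    """One-hot encode a six-state annotation: 6L vector, position-major.

    Entries [6i, 6i+6) are the indicator of position i's state in the order
    S, M, H, I, T, F; the vector sums to L.
    """
    out = np.zeros(6 * len(annotation), dtype=float)
    for i, s in enumerate(annotation):
        j = STATE_INDEX.get(s)
        if j is None:
            raise ValueError(f"unknown structure state {s!r} at position {i}")
        out[6 * i + j] = 1.0
    return out


def decode_structure(vector: np.ndarray) -> str:
    """Invert :func:`encode_structure` (exact one-hot blocks required)."""
    if vector.size % 6 != 0:
        raise ValueError("vector length must be a multiple of 6")
    blocks = np.asarray(vector).reshape(-1, 6)
    if not np.all(blocks.sum(axis=1) == 1.0):
        raise ValueError("each 6-wide block must be one-hot")
    return "".join(STATES[j] for j in blocks.argmax(axis=1))
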
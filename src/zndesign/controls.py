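"""Control-peptide sequence generation.

Two control modes validate design specificity:

* within-fragment permutation — keep the four metal-binding anchors at
  their positions and letters, and shuffle each inter-anchor segment's
  letters among themselves (the P1 -> P1C construction);
* Cys -> Ser substitution at chosen positions, including one
  metal-binding cysteine (the P2 -> P2C / P3 -> P3C construction).
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence, Union

import numpy as np

from .assembly import AssembledPeptide

__all__ = [
    "permute_within_fragments",
    "permute_sequence",
    "substitute_cys",
    "is_fragment_permutation",
]

_MAX_REDRAWS = 100


def _segments(length: int, anchors: Sequence[int]) -> list[tuple[int, int]]:
    """Half-open index ranges of the inter-anchor segments (0-based)."""
    out = []
    for a, b in zip(anchors, anchors[1:]):
        out.append((a, b - 1))  # letters strictly between the two anchors
    return out


def permute_sequence(sequence: str, anchors: Sequence[int], seed: int) -> str:
    """Seeded within-fragment permutation of ``sequence``.

    ``anchors`` are 1-based positions kept fixed; each segment strictly
    between consecutive anchors is replaced by a uniform random
    permutation of its own letters (Fisher-Yates via numpy, segments
    processed N- to C-terminal).  A permutation identical to the original
    segment is redrawn, unless the segment has fewer than two distinct
    letters, so the control differs from the design wherever possible.
    """
    anchors = sorted(anchors)
    if anchors[0] < 1 or anchors[-1] > len(sequence):
        raise ValueError("anchor positions outside the sequence")
    rng = np.random.default_rng(seed)
    letters = list(sequence)
    for lo, hi in _segments(len(sequence), anchors):
        segment = letters[lo:hi]
        if len(set(segment)) <= 1:
            continue
        for _ in range(_MAX_REDRAWS):
            perm = list(rng.permutation(segment))
            if perm != segment:
                break
        letters[lo:hi] = perm
    return "".join(letters)


def permute_within_fragments(
    peptide: Union[AssembledPeptide, tuple[str, Sequence[int]]], seed: int
) -> str:
    """Control sequence for a designed peptide (anchors fixed, segments shuffled)."""
    if isinstance(peptide, AssembledPeptide):
        return permute_sequence(peptide.sequence, peptide.anchor_positions, seed)
    sequence, anchors = peptide
    return permute_sequence(sequence, anchors, seed)


def substitute_cys(peptide_sequence: str, positions: Iterable[int]) -> str:
    """Replace cysteines at the given 1-based positions by serine.

    Every listed position must hold 'C'; anything else is an error rather
    than a silent no-op.
    """
    letters = list(peptide_sequence)
    for pos in sorted(set(positions)):
        if pos < 1 or pos > len(letters):
            raise ValueError(f"position {pos} outside sequence of length {len(letters)}")
        if letters[pos - 1] != "C":
            raise ValueError(
                f"position {pos} holds {letters[pos - 1]!r}, not 'C'; refusing to substitute"
            )
        letters[pos - 1] = "S"
    return "".join(letters)


def is_fragment_permutation(
    design_sequence: str, control_sequence: str, anchors: Sequence[int]
) -> bool:
    """Check the within-fragment-permutation contract between two sequences.

    True iff the sequences have equal length, carry identical letters at
    every anchor position, and every inter-anchor segment of the control
    is a letter-multiset permutation of the design's segment.
    """
    if len(design_sequence) != len(control_sequence):
        return False
    anchors = sorted(anchors)
    for pos in anchors:
        if design_sequence[pos - 1] != control_sequence[pos - 1]:
            return False
    for lo, hi in _segments(len(design_sequence), anchors):
        if Counter(design_sequence[lo:hi]) != Counter(control_sequence[lo:hi]):
            return False
    return True
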
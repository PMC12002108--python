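"""Mining of (H/C)-X_n-(H/C) metal-anchor fragments from structures.

A fragment is a contiguous stretch of one chain whose two terminal
residues ("anchors") are His or Cys with complete donor atoms, whose
interior length n satisfies 1 < n < 21, and whose terminal donor atoms
approach within a distance threshold (default 6.5 Angstrom, taken as the
minimum over all donor-atom pairs of the two anchors, so either His
nitrogen may satisfy it).

Fragments are directional (N- to C-terminal); the reversed residue pair is
not enumerated separately.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .structure import (
    Chain,
    Residue,
    Structure,
    donor_atoms,
    has_complete_donors,
    one_letter_sequence,
)

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "PEPTIDE_BOND_MAX",
    "min_donor_distance",
    "mine_fragments",
    "fragment_from_chain",
    "build_library",
    "library_to_tsv",
]

#: Adjacent C(i)-N(i+1) distances above this break chain contiguity (Angstrom).
PEPTIDE_BOND_MAX = 2.0

DEFAULT_MAX_DONOR_DISTANCE = 6.5
DEFAULT_N_RANGE = (2, 20)


def min_donor_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum distance over all donor-atom pairs of two anchor residues."""
    da = donor_atoms(res_a)
    db = donor_atoms(res_b)
    if not da or not db:
        raise ValueError(f"missing donor atoms on {res_a.label} or {res_b.label}")
    return min(
        float(np.linalg.norm(a.coords - b.coords)) for a, b in itertools.product(da, db)
    )


@dataclass(frozen=True)
class Fragment:
    """A B_i-X_n-B_j stretch with provenance and donor geometry."""

    source_id: str
    chain_id: str
    residues: tuple[Residue, ...]
    donor_distance: float

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise ValueError("a fragment needs two anchors and at least one interior residue")

    @property
    def anchor_start(self) -> Residue:
        return self.residues[0]

    @property
    def anchor_end(self) -> Residue:
        return self.residues[-1]

    @property
    def n_interior(self) -> int:
        return len(self.residues) - 2

    @property
    def sequence(self) -> str:
        return one_letter_sequence(list(self.residues))

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Provenance triple-plus: (source, chain, start seqnum, end seqnum)."""
        return (
            self.source_id,
            self.chain_id,
            self.anchor_start.seq_number,
            self.anchor_end.seq_number,
        )

    def validate(
        self,
        max_donor_distance: float = DEFAULT_MAX_DONOR_DISTANCE,
        n_range: tuple[int, int] = DEFAULT_N_RANGE,
    ) -> None:
        """Re-check every fragment invariant from raw data; raise on violation."""
        if not (n_range[0] <= self.n_interior <= n_range[1]):
            raise ValueError(f"interior length {self.n_interior} outside {n_range}")
        seq = self.sequence
        if len(seq) != self.n_interior + 2:
            raise ValueError("sequence length inconsistent with residue list")
        if seq[0] not in "HC" or seq[-1] not in "HC":
            raise ValueError("terminal residues must be H or C")
        if not (has_complete_donors(self.anchor_start) and has_complete_donors(self.anchor_end)):
            raise ValueError("anchor donor atoms incomplete")
        d = min_donor_distance(self.anchor_start, self.anchor_end)
        if abs(d - self.donor_distance) > 1e-6:
            raise ValueError("stored donor distance disagrees with coordinates")
        if d > max_donor_distance:
            raise ValueError(f"donor distance {d:.2f} exceeds {max_donor_distance}")
        if not _contiguous(self.residues):
            raise ValueError("fragment residues are not a contiguous peptide")


def _contiguous(residues: Sequence[Residue]) -> bool:
    """Contiguity rule: increasing numbering and every C-N bond < 2.0 A."""
    for prev, cur in zip(residues, residues[1:]):
        if (cur.seq_number, cur.insertion_code) <= (prev.seq_number, prev.insertion_code):
            return False
        c = prev.atom("C")
        n = cur.atom("N")
        if c is None or n is None:
            return False
        if np.linalg.norm(c.coords - n.coords) >= PEPTIDE_BOND_MAX:
            return False
    return True


def fragment_from_chain(
    structure: Structure, chain_id: str, start_index: int, end_index: int
) -> Fragment:
    """Slice a fragment out of a chain by residue list indices (inclusive).

    Anchors must be His/Cys with complete donors and the slice contiguous;
    the donor-distance threshold is *not* applied here — that admission
    rule belongs to :func:`mine_fragments`.
    """
    chain = structure.chain(chain_id)
    residues = tuple(chain.residues[start_index : end_index + 1])
    if len(residues) < 3:
        raise ValueError("slice too short for a fragment")
    for res in (residues[0], residues[-1]):
        if not has_complete_donors(res):
            raise ValueError(f"residue {res.label} is not a complete H/C anchor")
    if not _contiguous(residues):
        raise ValueError("slice is not a contiguous peptide")
    return Fragment(
        source_id=structure.source_id,
        chain_id=chain_id,
        residues=residues,
        donor_distance=min_donor_distance(residues[0], residues[-1]),
    )


def _chain_breaks(chain: Chain) -> list[bool]:
    """break_after[i] is True when residues i, i+1 are not peptide-bonded."""
    flags = []
    for prev, cur in zip(chain.residues, chain.residues[1:]):
        ok = (
            (cur.seq_number, cur.insertion_code) > (prev.seq_number, prev.insertion_code)
            and prev.atom("C") is not None
            and cur.atom("N") is not None
            and np.linalg.norm(prev.atom("C").coords - cur.atom("N").coords)
            < PEPTIDE_BOND_MAX
        )
        flags.append(not ok)
    return flags


def mine_fragments(
    structure: Structure,
    max_donor_distance: float = DEFAULT_MAX_DONOR_DISTANCE,
    n_range: tuple[int, int] = DEFAULT_N_RANGE,
) -> list[Fragment]:
    """Extract every admissible anchor-to-anchor fragment from a structure.

    Admission requires, for an ordered anchor pair (i, j) in one chain:
    both residues His/Cys with complete donor atoms, interior length
    within ``n_range`` (inclusive), no chain break between them, and
    minimum donor-atom distance <= ``max_donor_distance`` (inclusive).
    """
    if max_donor_distance <= 0:
        raise ValueError("max_donor_distance must be positive")
    n_min, n_max = n_range
    out: list[Fragment] = []
    for chain in structure.chains:
        breaks = _chain_breaks(chain)
        # prefix count of breaks: fast "no break in [i, j)" test
        prefix = np.concatenate([[0], np.cumsum(breaks)])
        anchors = [
            idx for idx, res in enumerate(chain.residues) if has_complete_donors(res)
        ]
        for ai, i in enumerate(anchors):
            for j in anchors[ai + 1 :]:
                n_int = j - i - 1
                if n_int < n_min:
                    continue
                if n_int > n_max:
                    break  # anchors sorted: later j only longer
                if prefix[j] - prefix[i] > 0:
                    continue
                d = min_donor_distance(chain.residues[i], chain.residues[j])
                if d <= max_donor_distance:
                    out.append(
                        Fragment(
                            source_id=structure.source_id,
                            chain_id=chain.chain_id,
                            residues=tuple(chain.residues[i : j + 1]),
                            donor_distance=d,
                        )
                    )
    return out


@dataclass
class FragmentLibrary:
    """A provenance-tagged collection of mined fragments."""

    fragments: list[Fragment] = field(default_factory=list)
    max_donor_distance: float = DEFAULT_MAX_DONOR_DISTANCE
    n_range: tuple[int, int] = DEFAULT_N_RANGE

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def __getitem__(self, idx: int) -> Fragment:
        return self.fragments[idx]


def build_library(
    structures: Iterable[Structure],
    max_donor_distance: float = DEFAULT_MAX_DONOR_DISTANCE,
    n_range: tuple[int, int] = DEFAULT_N_RANGE,
    exclude_interior_hc: bool = False,
) -> FragmentLibrary:
    """Mine all structures into one library.

    ``exclude_interior_hc`` drops fragments whose interior contains further
    His/Cys residues — the stricter variant that avoids designs with
    stray metal-binding side chains (the failure mode of designs carrying
    extra cysteines).
    """
    structures = list(structures)
    if not structures:
        raise ValueError("need at least one structure")
    frags: list[Fragment] = []
    for st in structures:
        mined = mine_fragments(st, max_donor_distance, n_range)
        if exclude_interior_hc:
            mined = [f for f in mined if not any(c in "HC" for c in f.sequence[1:-1])]
        frags.extend(mined)
    return FragmentLibrary(
        fragments=frags, max_donor_distance=max_donor_distance, n_range=n_range
    )


def library_to_tsv(library: FragmentLibrary) -> str:
    """Export a fragment library as TSV text."""
    rows = [
        {
            "source_id": f.source_id,
            "chain": f.chain_id,
            "anchor_start": f.anchor_start.seq_number,
            "anchor_end": f.anchor_end.seq_number,
            "sequence": f.sequence,
            "n_interior": f.n_interior,
            "donor_distance": round(f.donor_distance, 3),
        }
        for f in library
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "chain",
            "anchor_start",
            "anchor_end",
            "sequence",
            "n_interior",
            "donor_distance",
        ],
    ).to_csv(sep="\t", index=False)
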
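"""Two-stage merging of fragments into four-anchor peptide candidates.

Stage one overlays the end anchor of one fragment onto the start anchor of
a compatible fragment (same residue type, best backbone+donor alignment
RMSD) and concatenates them, keeping only the first copy of the shared
anchor.  Applied twice this yields three-anchor B1-Xk-B2-Xl-B3 peptides.

Stage two joins two three-anchor peptides that share their middle fragment
sequence-wise (B2-Xl-B3 of the left equals the first fragment of the
right): the right peptide is superposed over the full shared fragment
backbone and only its trailing tail is appended, producing the final
B1-Xk-B2-Xl-B3-Xm-B4 candidate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

from .mining import Fragment, FragmentLibrary
from .structure import BACKBONE_ATOMS, Residue, one_letter_sequence
from .superpose import (
    AlignmentScore,
    IncompatibleAnchorsError,
    RigidTransform,
    anchor_alignment,
    kabsch_fit,
    rmsd,
)

__all__ = [
    "AssembledPeptide",
    "MergeRejected",
    "SharedFragmentMismatchError",
    "as_peptide",
    "find_compatible",
    "merge_pair",
    "merge_final",
    "assemble_candidates",
    "enumerate_designs",
    "has_steric_clash",
]

DEFAULT_ANCHOR_MERGE_RMSD = 0.5
DEFAULT_FINAL_MERGE_RMSD = 1.0
DEFAULT_TOP_K = 10


class MergeRejected(RuntimeError):
    """Alignment RMSD above the configured merge ceiling."""


class SharedFragmentMismatchError(ValueError):
    """Stage-two inputs do not share their middle fragment sequence-wise."""


@dataclass
class AssembledPeptide:
    """A merged peptide with 1-based anchor bookkeeping and provenance."""

    residues: list[Residue]
    anchor_positions: tuple[int, ...]
    provenance: tuple[Fragment, ...]
    merge_rmsds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        pos = self.anchor_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("anchor positions must be strictly increasing")
        if pos and (pos[0] != 1 or pos[-1] != len(self.residues)):
            raise ValueError("first and last residues must be anchors")
        for p in pos:
            if self.residues[p - 1].aa_code not in "HC":
                raise ValueError(f"anchor at position {p} is not H or C")

    @property
    def sequence(self) -> str:
        return one_letter_sequence(self.residues)

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_positions)

    @property
    def stage(self) -> str:
        return {2: "fragment", 3: "3-anchor", 4: "4-anchor"}.get(
            self.n_anchors, f"{self.n_anchors}-anchor"
        )

    @property
    def anchor_residues(self) -> list[Residue]:
        return [self.residues[p - 1] for p in self.anchor_positions]

    @property
    def anchor_composition(self) -> str:
        return "".join(sorted(r.aa_code for r in self.anchor_residues))

    @property
    def total_merge_rmsd(self) -> float:
        return float(sum(self.merge_rmsds))

    @property
    def design_id(self) -> str:
        frags = "+".join(
            f"{f.source_id}:{f.chain_id}:{f.anchor_start.seq_number}-{f.anchor_end.seq_number}"
            for f in self.provenance
        )
        return frags

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for r in self.residues for a in r.atoms])


def _renumber(residues: Iterable[Residue], transform: RigidTransform | None = None) -> list[Residue]:
    out = []
    for i, res in enumerate(residues, start=1):
        new = copy.deepcopy(res)
        new.chain_id = "A"
        new.seq_number = i
        new.insertion_code = ""
        if transform is not None:
            for atom in new.atoms:
                atom.coords = transform.apply(atom.coords)
        out.append(new)
    return out


def as_peptide(obj: Union[Fragment, AssembledPeptide]) -> AssembledPeptide:
    """View a mined fragment as a two-anchor assembled peptide."""
    if isinstance(obj, AssembledPeptide):
        return obj
    return AssembledPeptide(
        residues=_renumber(obj.residues),
        anchor_positions=(1, len(obj.residues)),
        provenance=(obj,),
    )


def find_compatible(
    query: Union[Fragment, AssembledPeptide],
    library: FragmentLibrary,
    k: int = DEFAULT_TOP_K,
) -> list[tuple[Fragment, AlignmentScore]]:
    """Rank library fragments for merging onto the query's end anchor.

    Returns the ``k`` fragments whose start anchor has the query's end
    anchor type and minimises the anchor-alignment RMSD, ascending, with
    lexicographic (source, chain, start residue number) tie-breaking.
    This is the exact nearest-neighbour realisation of the top-k-by-RMSD
    contract (approximate indexing is an acceleration detail, not part of
    the contract).
    """
    pep = as_peptide(query)
    end_anchor = pep.residues[pep.anchor_positions[-1] - 1]
    scored: list[tuple[Fragment, AlignmentScore]] = []
    for frag in library:
        if frag.anchor_start.aa_code != end_anchor.aa_code:
            continue
        try:
            score = anchor_alignment(end_anchor, frag.anchor_start)
        except IncompatibleAnchorsError:
            continue
        scored.append((frag, score))
    # quantize the RMSD for ordering so exact geometric ties (identical
    # anchor contexts) break lexicographically, not by 1e-16 float noise
    scored.sort(key=lambda fs: (round(fs[1].rmsd, 9),) + fs[0].key)
    return scored[:k]


def merge_pair(
    first: Union[Fragment, AssembledPeptide],
    second: Fragment,
    score: AlignmentScore | None = None,
    max_rmsd: float = DEFAULT_ANCHOR_MERGE_RMSD,
) -> AssembledPeptide:
    """Merge ``second`` onto the end anchor of ``first``.

    The second fragment is rigidly moved by the anchor-alignment
    transform, its first residue (the duplicate shared anchor) is
    discarded, and the remainder is appended; the first component's
    coordinates are untouched.  Merged length is
    ``len(first) + len(second) - 1``.

    Raises :class:`MergeRejected` when the alignment RMSD exceeds
    ``max_rmsd`` — candidates merged that loosely are not meaningful.
    """
    pep = as_peptide(first)
    end_anchor = pep.residues[pep.anchor_positions[-1] - 1]
    if score is None:
        score = anchor_alignment(end_anchor, second.anchor_start)
    if score.rmsd > max_rmsd:
        raise MergeRejected(
            f"anchor alignment rmsd {score.rmsd:.3f} A exceeds ceiling {max_rmsd} A"
        )
    moved_tail = _renumber(second.residues[1:], transform=score.transform)
    residues = [copy.deepcopy(r) for r in pep.residues] + moved_tail
    for i, res in enumerate(residues, start=1):
        res.seq_number = i
        res.chain_id = "A"
    new_anchor = len(pep.residues) + len(second.residues) - 1
    return AssembledPeptide(
        residues=residues,
        anchor_positions=pep.anchor_positions + (new_anchor,),
        provenance=pep.provenance + (second,),
        merge_rmsds=pep.merge_rmsds + (score.rmsd,),
    )


def merge_final(
    left: AssembledPeptide,
    right: AssembledPeptide,
    max_rmsd: float = DEFAULT_FINAL_MERGE_RMSD,
) -> AssembledPeptide:
    """Join two three-anchor peptides over their shared middle fragment.

    ``left`` spans B1-Xk-B2-Xl-B3 and ``right`` spans B2-Xl-B3-Xm-B4; the
    B2-Xl-B3 stretch must match sequence-wise.  The right peptide is
    superposed over the backbone (N/CA/C) of the full shared stretch, the
    shared residues are discarded from it (the left copy provides the
    coordinates) and its tail is appended.
    """
    if left.n_anchors != 3 or right.n_anchors != 3:
        raise ValueError("final merge expects two 3-anchor peptides")
    p1, p2, p3 = left.anchor_positions
    q1, q2, q3 = right.anchor_positions
    shared_left = left.residues[p2 - 1 : p3]
    shared_right = right.residues[q1 - 1 : q2]
    seq_left = one_letter_sequence(shared_left)
    seq_right = one_letter_sequence(shared_right)
    if seq_left != seq_right:
        raise SharedFragmentMismatchError(
            f"shared fragments differ: {seq_left!r} vs {seq_right!r}"
        )

    fixed = np.array(
        [r.atom(n).coords for r in shared_left for n in BACKBONE_ATOMS]
    )
    moving = np.array(
        [r.atom(n).coords for r in shared_right for n in BACKBONE_ATOMS]
    )
    transform = kabsch_fit(fixed, moving)
    overlap_rmsd = rmsd(fixed, transform.apply(moving))
    if overlap_rmsd > max_rmsd:
        raise MergeRejected(
            f"shared-fragment overlap rmsd {overlap_rmsd:.3f} A exceeds ceiling {max_rmsd} A"
        )

    tail = _renumber(right.residues[q2:], transform=transform)
    residues = [copy.deepcopy(r) for r in left.residues] + tail
    for i, res in enumerate(residues, start=1):
        res.seq_number = i
        res.chain_id = "A"
    anchors = (p1, p2, p3, p3 + (q3 - q2))
    return AssembledPeptide(
        residues=residues,
        anchor_positions=anchors,
        provenance=left.provenance + right.provenance[1:],
        merge_rmsds=left.merge_rmsds + right.merge_rmsds + (overlap_rmsd,),
    )


def has_steric_clash(
    peptide: AssembledPeptide, cutoff: float = 2.0
) -> bool:
    """True if any non-bonded heavy-atom pair approaches within ``cutoff``.

    Pairs within one residue and the bonded C(i)-N(i+1) pair are exempt.
    Optional diagnostic; merging applies no clash filter by default.
    """
    coords = []
    meta = []  # (residue index, atom name)
    for ri, res in enumerate(peptide.residues):
        for atom in res.atoms:
            if atom.element == "H":
                continue
            coords.append(atom.coords)
            meta.append((ri, atom.name))
    pts = np.array(coords)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] >= cutoff:
                continue
            ri, ni = meta[i]
            rj, nj = meta[j]
            if ri == rj:
                continue
            if abs(ri - rj) == 1 and {ni, nj} == {"C", "N"}:
                continue
            return True
    return False


def assemble_candidates(
    library: FragmentLibrary,
    k: int = DEFAULT_TOP_K,
    anchor_merge_rmsd: float = DEFAULT_ANCHOR_MERGE_RMSD,
    final_merge_rmsd: float = DEFAULT_FINAL_MERGE_RMSD,
) -> list[AssembledPeptide]:
    """Run both merge stages over a library; return all four-anchor peptides.

    No geometric site screening is applied here — candidates carry any
    anchor composition and site shape; see :func:`enumerate_designs` for
    the screened set.  Ordering is deterministic (library order, then
    alignment rank).
    """
    three_anchor: list[AssembledPeptide] = []
    for frag in library:
        for cand, score in find_compatible(frag, library, k=k):
            try:
                three_anchor.append(
                    merge_pair(frag, cand, score=score, max_rmsd=anchor_merge_rmsd)
                )
            except MergeRejected:
                continue

    finals: list[AssembledPeptide] = []
    for left in three_anchor:
        p2, p3 = left.anchor_positions[1], left.anchor_positions[2]
        shared_seq = one_letter_sequence(left.residues[p2 - 1 : p3])
        for right in three_anchor:
            if right.provenance[0].sequence != shared_seq:
                continue
            try:
                finals.append(merge_final(left, right, max_rmsd=final_merge_rmsd))
            except (SharedFragmentMismatchError, MergeRejected):
                continue
    return finals


def enumerate_designs(
    library: FragmentLibrary,
    k: int = DEFAULT_TOP_K,
    anchor_merge_rmsd: float = DEFAULT_ANCHOR_MERGE_RMSD,
    final_merge_rmsd: float = DEFAULT_FINAL_MERGE_RMSD,
    site_window: tuple[float, float] = (1.5, 5.5),
    require_c2h2: bool = True,
    reject_clashes: bool = False,
    clash_cutoff: float = 2.0,
) -> list[AssembledPeptide]:
    """All four-anchor candidates passing the binding-site screen.

    Composition defaults to the two-Cys/two-His zinc-finger motif and all
    six pairwise donor distances must fall inside ``site_window``.
    """
    from .geometry import evaluate_site, passes_window  # local import: avoid cycle

    designs = []
    for pep in assemble_candidates(
        library,
        k=k,
        anchor_merge_rmsd=anchor_merge_rmsd,
        final_merge_rmsd=final_merge_rmsd,
    ):
        site = evaluate_site(pep)
        ok, _reasons = passes_window(site, window=site_window, require_c2h2=require_c2h2)
        if not ok:
            continue
        if reject_clashes and has_steric_clash(pep, cutoff=clash_cutoff):
            continue
        designs.append(pep)
    return designs
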
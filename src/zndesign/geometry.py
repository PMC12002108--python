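"""Binding-site geometry: donor selection, pairwise distances, windows.

A candidate {B1, B2, B3, B4} site is summarised by one donor atom per
anchor and the six pairwise distances between them.  Admission requires
every distance inside a window (default 1.5-5.5 Angstrom, inclusive) and,
for the zinc-finger motif, exactly two Cys and two His among the anchors.

His contributes two candidate nitrogens; the evaluator picks, per site,
the combination of nitrogens minimising the total pairwise donor
distance (exhaustive over the at-most 2^4 choices), since a coordinating
imidazole can present either nitrogen to the metal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .assembly import AssembledPeptide
from .structure import Atom, donor_atoms

__all__ = [
    "SiteGeometry",
    "SiteError",
    "evaluate_site",
    "passes_window",
    "tetrahedrality",
    "DEFAULT_SITE_WINDOW",
]

DEFAULT_SITE_WINDOW = (1.5, 5.5)

#: Ideal tetrahedral angle, degrees.
TETRAHEDRAL_ANGLE = 109.47122063449069

_PAIRS = list(itertools.combinations(range(4), 2))


class SiteError(ValueError):
    """Candidate site cannot be evaluated (missing donor atoms etc.)."""


@dataclass(frozen=True)
class SiteGeometry:
    """Four selected donor atoms and their six pairwise distances."""

    donor_atoms: tuple[Atom, ...]
    pairwise_distances: tuple[float, ...]
    composition: str  # sorted anchor letters, e.g. "CCHH"

    def __post_init__(self) -> None:
        if len(self.donor_atoms) != 4 or len(self.pairwise_distances) != 6:
            raise ValueError("a site has 4 donors and 6 pairwise distances")
        if any(d <= 0 for d in self.pairwise_distances):
            raise ValueError("coincident donor atoms: zero pairwise distance")

    @property
    def donor_coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.donor_atoms])

    @classmethod
    def from_points(cls, points: np.ndarray, composition: str = "CCHH") -> "SiteGeometry":
        """Build a site directly from four donor coordinates (synthetic use)."""
        pts = np.asarray(points, float)
        if pts.shape != (4, 3):
            raise ValueError("expected four 3D points")
        atoms = tuple(
            Atom(name="SG" if c == "C" else "NE2", element="S" if c == "C" else "N", coords=p)
            for c, p in zip(sorted(composition), pts)
        )
        dists = tuple(float(np.linalg.norm(pts[i] - pts[j])) for i, j in _PAIRS)
        return cls(donor_atoms=atoms, pairwise_distances=dists, composition="".join(sorted(composition)))


def _pairwise(points: np.ndarray) -> tuple[float, ...]:
    return tuple(float(np.linalg.norm(points[i] - points[j])) for i, j in _PAIRS)


def evaluate_site(peptide: AssembledPeptide) -> SiteGeometry:
    """Select donor atoms for the four anchors and measure the site.

    Raises :class:`SiteError` listing every anchor whose donor atoms are
    missing from the model.
    """
    if peptide.n_anchors != 4:
        raise SiteError(f"site evaluation needs 4 anchors, got {peptide.n_anchors}")
    anchors = peptide.anchor_residues
    candidates: list[list[Atom]] = []
    missing = []
    for pos, res in zip(peptide.anchor_positions, anchors):
        atoms = donor_atoms(res)
        if not atoms:
            missing.append(f"{res.aa_code}{pos}")
        candidates.append(atoms)
    if missing:
        raise SiteError(f"anchors with missing donor atoms: {', '.join(missing)}")

    best: tuple[float, tuple[Atom, ...]] | None = None
    for combo in itertools.product(*candidates):
        pts = np.array([a.coords for a in combo])
        total = float(sum(_pairwise(pts)))
        if best is None or total < best[0] - 1e-12:
            best = (total, combo)
    assert best is not None
    combo = best[1]
    pts = np.array([a.coords for a in combo])
    return SiteGeometry(
        donor_atoms=combo,
        pairwise_distances=_pairwise(pts),
        composition="".join(sorted(r.aa_code for r in anchors)),
    )


def passes_window(
    site: SiteGeometry,
    window: tuple[float, float] = DEFAULT_SITE_WINDOW,
    require_c2h2: bool = True,
) -> tuple[bool, list[str]]:
    """Apply the pairwise-distance window and composition rule.

    Bounds are inclusive.  Returns (verdict, reasons); reasons enumerate
    every violated pair and/or the composition mismatch.
    """
    lo, hi = window
    reasons = []
    for (i, j), d in zip(_PAIRS, site.pairwise_distances):
        if not (lo <= d <= hi):
            reasons.append(
                f"donor pair {i + 1}-{j + 1}: distance {d:.2f} A outside [{lo}, {hi}] A"
            )
    if require_c2h2 and site.composition != "CCHH":
        reasons.append(f"composition {site.composition} is not C2H2 (CCHH)")
    return (not reasons, reasons)


def tetrahedrality(site: SiteGeometry) -> float:
    """Angular variance (deg^2) of donor-centroid-donor angles about 109.47.

    Diagnostic only — never used as a filter.  Zero for a perfect
    tetrahedron centred on its donor centroid.
    """
    pts = site.donor_coordinates
    center = pts.mean(axis=0)
    v = pts - center
    v /= np.linalg.norm(v, axis=1)[:, None]
    angles = [
        float(np.degrees(np.arccos(np.clip(np.dot(v[i], v[j]), -1.0, 1.0))))
        for i, j in _PAIRS
    ]
    return float(np.mean([(a - TETRAHEDRAL_ANGLE) ** 2 for a in angles]))
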
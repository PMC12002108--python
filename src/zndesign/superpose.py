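"""Rigid-body superposition and anchor-alignment scoring.

Fragment merging overlays the shared His/Cys anchor of two fragments.  The
fit uses the Kabsch least-squares rotation on the anchor backbone
(N, Calpha, C); the reported alignment RMSD additionally includes the
metal-donor atoms (SG for Cys; ND1 and NE2 for His, matched by name), so
that two anchors only score well when both backbone conformation *and*
side-chain donor placement agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import BACKBONE_ATOMS, Residue, donor_atoms, DONOR_ATOM_NAMES

__all__ = [
    "RigidTransform",
    "AlignmentScore",
    "DegenerateGeometryError",
    "IncompatibleAnchorsError",
    "kabsch_fit",
    "rmsd",
    "anchor_alignment",
]


class DegenerateGeometryError(ValueError):
    """Point set too small or collinear for a unique superposition."""


class IncompatibleAnchorsError(ValueError):
    """Anchors differ in residue type (one Cys, one His) or lack atoms."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid transforms (det must be +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AlignmentScore:
    """A fitted transform plus the RMSD over the scoring atom set (Angstrom)."""

    transform: RigidTransform
    rmsd: float

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(fixed: np.ndarray, moving: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (Kabsch).

    Proper rotations only: if the optimal orthogonal matrix is a
    reflection, the smallest singular direction is flipped, preserving
    chirality at the cost of a slightly larger residual.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a collinear point set, where the
        rotation about the axis is not determined.
    ValueError
        If the point counts differ.
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    if fixed.shape != moving.shape:
        raise ValueError(f"point count mismatch: {fixed.shape} vs {moving.shape}")
    if fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must be (n, 3) arrays")
    if len(fixed) < 3:
        raise DegenerateGeometryError("need at least 3 points for a unique fit")

    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    f = fixed - cf
    m = moving - cm

    # Collinear inputs leave a free rotation about the common axis.
    for pts in (f, m):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError("collinear point set: rotation underdetermined")

    H = m.T @ f
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return RigidTransform(R, t)


def _scoring_atoms(residue: Residue) -> list[str]:
    return list(BACKBONE_ATOMS) + list(DONOR_ATOM_NAMES[residue.aa_code])


def anchor_alignment(shared_a: Residue, shared_b: Residue) -> AlignmentScore:
    """Superpose anchor ``shared_b`` onto ``shared_a`` and score the overlay.

    The fit uses the backbone N/CA/C only; the reported RMSD is computed
    over backbone plus donor atoms (SG, or ND1+NE2 matched by name) after
    applying the fitted transform.  Both residues must be the same anchor
    type (H or C).
    """
    if shared_a.aa_code not in DONOR_ATOM_NAMES or shared_b.aa_code not in DONOR_ATOM_NAMES:
        raise IncompatibleAnchorsError(
            f"anchors must be H or C, got {shared_a.aa_code!r} and {shared_b.aa_code!r}"
        )
    if shared_a.aa_code != shared_b.aa_code:
        raise IncompatibleAnchorsError(
            f"anchor types differ: {shared_a.label} is {shared_a.aa_code}, "
            f"{shared_b.label} is {shared_b.aa_code}"
        )
    for res in (shared_a, shared_b):
        if not res.has_atoms(BACKBONE_ATOMS):
            raise IncompatibleAnchorsError(f"residue {res.label} lacks backbone N/CA/C")
        if len(donor_atoms(res)) != len(DONOR_ATOM_NAMES[res.aa_code]):
            raise IncompatibleAnchorsError(f"residue {res.label} lacks donor atoms")

    fit_fixed = np.array([shared_a.atom(n).coords for n in BACKBONE_ATOMS])
    fit_moving = np.array([shared_b.atom(n).coords for n in BACKBONE_ATOMS])
    transform = kabsch_fit(fit_fixed, fit_moving)

    names = _scoring_atoms(shared_a)
    score_fixed = np.array([shared_a.atom(n).coords for n in names])
    score_moving = transform.apply(np.array([shared_b.atom(n).coords for n in names]))
    return AlignmentScore(transform=transform, rmsd=rmsd(score_fixed, score_moving))
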
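"""Secondary-structure assignment, the terminal-helix filter, dedup.

Candidate screening keeps only peptides that begin and end helical —
allowing a short coil, up to four residues, outside the terminal
helices — and keeps one representative per unique sequence.

The per-residue assigner used by default is a backbone-dihedral windower
(helix when (phi, psi) stays near the alpha-helical region for at least
four consecutive residues; strand near the beta region for at least
three), which is sufficient for screening idealised design models.
Per-residue labels from an external assigner (STRIDE/DSSP-style output)
can be imported instead; their seven-state alphabet is collapsed to
H/E/C in the usual way (G, H, I -> H; E, B -> E; rest -> C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import AssembledPeptide
from .structure import Residue

__all__ = [
    "SecondaryStructureString",
    "dihedral",
    "phi_psi",
    "assign_ss",
    "collapse_to_three_state",
    "import_ss_labels",
    "terminal_helix_filter",
    "dedup_sequences",
]

HELIX_CENTER = (-63.0, -42.0)
HELIX_TOL = 30.0
HELIX_MIN_RUN = 4
STRAND_CENTER = (-120.0, 135.0)
STRAND_TOL = 40.0
STRAND_MIN_RUN = 3

SEVEN_TO_THREE = {
    "G": "H", "H": "H", "I": "H",
    "E": "E", "B": "E", "b": "E",
}


@dataclass(frozen=True)
class SecondaryStructureString:
    """Per-residue labels over {H, E, C} plus their origin."""

    labels: str
    source: str = "computed"  # "computed" | "imported"

    def __post_init__(self) -> None:
        if set(self.labels) - set("HEC"):
            raise ValueError("labels must be over {H, E, C}")

    def __len__(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return self.labels


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def phi_psi(residues: Sequence[Residue]) -> list[tuple[float | None, float | None]]:
    """Backbone (phi, psi) per residue; None at termini or chain breaks."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(residues):
        if not res.has_atoms(("N", "CA", "C")):
            raise ValueError(f"residue {res.label} lacks backbone atoms")
        phi = psi = None
        if i > 0 and residues[i - 1].atom("C") is not None:
            c_prev = residues[i - 1].atom("C").coords
            if np.linalg.norm(c_prev - res.atom("N").coords) < 2.0:
                phi = dihedral(c_prev, res.atom("N").coords, res.atom("CA").coords, res.atom("C").coords)
        if i < len(residues) - 1 and residues[i + 1].atom("N") is not None:
            n_next = residues[i + 1].atom("N").coords
            if np.linalg.norm(res.atom("C").coords - n_next) < 2.0:
                psi = dihedral(res.atom("N").coords, res.atom("CA").coords, res.atom("C").coords, n_next)
        out.append((phi, psi))
    return out


def _wrap(delta: float) -> float:
    return abs((delta + 180.0) % 360.0 - 180.0)


def _in_window(
    angles: tuple[float | None, float | None], center: tuple[float, float], tol: float
) -> bool:
    phi, psi = angles
    if phi is None or psi is None:
        return False
    return _wrap(phi - center[0]) <= tol and _wrap(psi - center[1]) <= tol


def _mark_runs(mask: list[bool], min_run: int) -> list[bool]:
    out = [False] * len(mask)
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = [True] * (j - i)
            i = j
        else:
            i += 1
    return out


def assign_ss(peptide: AssembledPeptide | Sequence[Residue]) -> SecondaryStructureString:
    """Dihedral-window secondary-structure assignment.

    Helix: (phi, psi) within 30 degrees of (-63, -42) for >= 4 consecutive
    residues.  Strand: within 40 degrees of (-120, 135) for >= 3
    consecutive residues.  Everything else, including termini that lack a
    dihedral, is coil.
    """
    residues = peptide.residues if isinstance(peptide, AssembledPeptide) else list(peptide)
    angles = phi_psi(residues)
    helix = _mark_runs([_in_window(a, HELIX_CENTER, HELIX_TOL) for a in angles], HELIX_MIN_RUN)
    strand = _mark_runs([_in_window(a, STRAND_CENTER, STRAND_TOL) for a in angles], STRAND_MIN_RUN)
    labels = "".join(
        "H" if h else ("E" if e else "C") for h, e in zip(helix, strand)
    )
    return SecondaryStructureString(labels=labels, source="computed")


def collapse_to_three_state(code: str) -> str:
    """Collapse one 7-state STRIDE/DSSP code letter to H/E/C."""
    return SEVEN_TO_THREE.get(code.strip() or "C", "C")


def import_ss_labels(text: str) -> SecondaryStructureString:
    """Parse STRIDE/DSSP-style per-residue output (resnum, code columns).

    Accepts whitespace- or tab-separated lines of ``residue_number code``;
    lines starting with '#' are ignored.  Codes are collapsed to three
    states and ordered by residue number.
    """
    rows: list[tuple[int, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"cannot parse secondary-structure line: {line!r}")
        rows.append((int(parts[0]), collapse_to_three_state(parts[1])))
    rows.sort(key=lambda r: r[0])
    return SecondaryStructureString(labels="".join(c for _, c in rows), source="imported")


def terminal_helix_filter(
    ss: SecondaryStructureString | str, max_terminal_coil: int = 4
) -> bool:
    """True when the peptide starts and ends with helix, modulo short coils.

    At most ``max_terminal_coil`` non-helix residues may precede the first
    helix residue and follow the last one, and at least one helix residue
    must exist.
    """
    labels = str(ss)
    first = labels.find("H")
    if first == -1:
        return False
    last = labels.rfind("H")
    trailing = len(labels) - 1 - last
    return first <= max_terminal_coil and trailing <= max_terminal_coil


def dedup_sequences(designs: Sequence[AssembledPeptide]) -> list[AssembledPeptide]:
    """Keep one representative per exact sequence string.

    Among duplicates the representative with the lowest accumulated merge
    RMSD wins (ties resolve to earliest input order), so the output is
    deterministic and idempotent.
    """
    best: dict[str, tuple[float, int]] = {}
    for idx, pep in enumerate(designs):
        key = pep.sequence
        cand = (pep.total_merge_rmsd, idx)
        if key not in best or cand < best[key]:
            best[key] = cand
    keep = sorted(idx for _, idx in best.values())
    return [designs[i] for i in keep]
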
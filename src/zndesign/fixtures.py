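"""Synthetic test structures with controlled His/Cys donor geometry.

Nothing in the test or validation workflow downloads real structures:
every input is generated here, from ideal internal coordinates.

* :func:`build_ideal_helix` / :func:`build_chain` construct poly-peptide
  backbones (N, CA, C, O, CB) from standard bond lengths and angles with
  per-residue (phi, psi), plus idealized His/Cys side-chain stubs.
* :func:`build_design_scene` constructs whole-chain scenes whose mining,
  assembly and screening outcomes are known by construction: a positive
  scene with four anchors whose donors cluster inside the binding-site
  window, and negative scenes that each violate exactly one admission
  rule (donor too far, interior too long, wrong anchor composition,
  over-long terminal coil).
* :func:`generate_itc_data` draws per-buffer titrations from the
  proton-linkage forward model with seeded Gaussian noise.
* :func:`oracle_mine` / :func:`oracle_knn` are deliberately naive
  brute-force references (no shared code with the mining/assembly
  implementations beyond the data model) used to validate them.

Side chains here are idealized stubs (fixed internal coordinates, and in
scenes the donor groups are oriented toward a target point); they are
geometrically, not chemically, faithful — sufficient for testing the
distance and dihedral rules, which never inspect chemistry.
"""

from __future__ import annotations

import itertools
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .itc import BUFFER_IONIZATION_ENTHALPY_KCAL, BufferTitration
from .mining import Fragment, FragmentLibrary
from .structure import Atom, Chain, Residue, Structure, write_structure

__all__ = [
    "nerf",
    "build_chain",
    "build_ideal_helix",
    "build_anchor_pair_chain",
    "build_random_hc_scene",
    "build_design_scene",
    "SCENE_KINDS",
    "generate_itc_data",
    "oracle_mine",
    "oracle_knn",
    "write_fixture_set",
]

# Ideal backbone internal coordinates (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.5
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)

#: Distance from CB to the aimed donor atom of each anchor type: one S-C
#: bond for the Cys thiolate, the across-ring Nepsilon2 for His stubs.
DONOR_REACH = {"C": 1.81, "H": 3.90}

_HIS_RING_RADIUS = 1.10
_HIS_RING_CENTER = 2.80  # from CB, along the aim axis

VALID_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


def nerf(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, tau: float
) -> np.ndarray:
    """Natural-extension place of atom d bonded to c.

    ``r`` is the c-d bond length, ``theta`` the b-c-d angle and ``tau``
    the a-b-c-d torsion (degrees, IUPAC sign convention).
    """
    th = math.radians(theta)
    ta = math.radians(tau)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(th), r * math.sin(th) * math.cos(ta), r * math.sin(th) * math.sin(ta)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cys_stub(res: Residue, cb: np.ndarray, n: np.ndarray, ca: np.ndarray) -> None:
    sg = nerf(n, ca, cb, 1.81, 114.0, -60.0)
    res.atoms.append(Atom("SG", "S", sg))


def _place_his_stub(res: Residue, cb: np.ndarray, n: np.ndarray, ca: np.ndarray) -> None:
    cg = nerf(n, ca, cb, 1.50, 113.8, -60.0)
    nd1 = nerf(ca, cb, cg, 1.38, 122.7, -75.0)
    cd2 = nerf(ca, cb, cg, 1.36, 129.7, 105.0)
    ce1 = nerf(cb, cg, nd1, 1.32, 109.0, 180.0)
    ne2 = nerf(cg, nd1, ce1, 1.32, 108.5, 0.0)
    for name, el, pos in (
        ("CG", "C", cg), ("ND1", "N", nd1), ("CD2", "C", cd2), ("CE1", "C", ce1), ("NE2", "N", ne2)
    ):
        res.atoms.append(Atom(name, el, pos))


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, probe)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, probe)
    return v / np.linalg.norm(v)


def _aimed_cys_atoms(cb: np.ndarray, target: np.ndarray) -> list[Atom]:
    u = target - cb
    u = u / np.linalg.norm(u)
    return [Atom("SG", "S", cb + DONOR_REACH["C"] * u)]


def _aimed_his_atoms(
    cb: np.ndarray, target: np.ndarray, center_offset: float = 0.0
) -> list[Atom]:
    """Planar imidazole stub with NE2 on the CB->target axis."""
    u = target - cb
    u = u / np.linalg.norm(u)
    v = _any_perpendicular(u)
    center = cb + (_HIS_RING_CENTER + center_offset) * u
    atoms = []
    ring = [("NE2", "N", 0.0), ("CE1", "C", 72.0), ("ND1", "N", 144.0),
            ("CG", "C", 216.0), ("CD2", "C", 288.0)]
    for name, el, ang in ring:
        a = math.radians(ang)
        atoms.append(Atom(name, el, center + _HIS_RING_RADIUS * (math.cos(a) * u + math.sin(a) * v)))
    return atoms


def build_chain(
    sequence: str,
    torsions: list[tuple[float, float]],
    source_id: str = "fixture",
    chain_id: str = "A",
    with_side_chains: bool = True,
) -> Structure:
    """Build a chain from per-residue (phi, psi) with ideal covalent geometry.

    phi of the first and psi of the last residue have no structural effect
    (psi of the last residue only orients its carbonyl oxygen).
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - VALID_LETTERS
    if bad:
        raise ValueError(f"invalid one-letter codes: {sorted(bad)}")
    if len(torsions) != len(sequence):
        raise ValueError("need one (phi, psi) pair per residue")

    n_atoms: list[np.ndarray] = []
    ca_atoms: list[np.ndarray] = []
    c_atoms: list[np.ndarray] = []
    n_atoms.append(np.zeros(3))
    ca_atoms.append(np.array([BOND_N_CA, 0.0, 0.0]))
    ang = math.radians(180.0 - ANG_N_CA_C)
    c_atoms.append(ca_atoms[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0]))

    for i in range(1, len(sequence)):
        psi_prev = torsions[i - 1][1]
        n_i = nerf(n_atoms[i - 1], ca_atoms[i - 1], c_atoms[i - 1], BOND_C_N, ANG_CA_C_N, psi_prev)
        ca_i = nerf(ca_atoms[i - 1], c_atoms[i - 1], n_i, BOND_N_CA, ANG_C_N_CA, OMEGA)
        c_i = nerf(c_atoms[i - 1], n_i, ca_i, BOND_CA_C, ANG_N_CA_C, torsions[i][0])
        n_atoms.append(n_i)
        ca_atoms.append(ca_i)
        c_atoms.append(c_i)

    chain = Chain(chain_id=chain_id)
    for i, letter in enumerate(sequence):
        res = Residue(chain_id=chain_id, seq_number=i + 1, aa_code=letter, atoms=[])
        res.atoms.append(Atom("N", "N", n_atoms[i]))
        res.atoms.append(Atom("CA", "C", ca_atoms[i]))
        res.atoms.append(Atom("C", "C", c_atoms[i]))
        o = nerf(n_atoms[i], ca_atoms[i], c_atoms[i], BOND_C_O, ANG_CA_C_O, torsions[i][1] + 180.0)
        res.atoms.append(Atom("O", "O", o))
        if letter != "G":
            cb = nerf(n_atoms[i], c_atoms[i], ca_atoms[i], 1.53, 110.6, -122.6)
            res.atoms.append(Atom("CB", "C", cb))
            if with_side_chains and letter == "C":
                _place_cys_stub(res, cb, n_atoms[i], ca_atoms[i])
            elif with_side_chains and letter == "H":
                _place_his_stub(res, cb, n_atoms[i], ca_atoms[i])
        chain.residues.append(res)
    return Structure(source_id=source_id, chains=[chain])


def build_ideal_helix(
    sequence: str,
    phi: float = HELIX_PHI_PSI[0],
    psi: float = HELIX_PHI_PSI[1],
    source_id: str = "helix",
) -> Structure:
    """An ideal alpha-helix (or any uniform-torsion chain) for ``sequence``."""
    return build_chain(sequence, [(phi, psi)] * len(sequence), source_id=source_id)


def _residue_cb(res: Residue) -> np.ndarray:
    cb = res.atom("CB")
    if cb is None:
        raise ValueError(f"residue {res.label} lacks CB")
    return cb.coords


def _strip_side_chain(res: Residue) -> None:
    keep = {"N", "CA", "C", "O", "CB"}
    res.atoms = [a for a in res.atoms if a.name in keep]


def _aim_anchor(res: Residue, target: np.ndarray, center_offset: float = 0.0) -> None:
    """Replace an anchor's side-chain stub so its donor points at ``target``."""
    cb = _residue_cb(res)
    _strip_side_chain(res)
    if res.aa_code == "C":
        res.atoms.extend(_aimed_cys_atoms(cb, target))
    elif res.aa_code == "H":
        res.atoms.extend(_aimed_his_atoms(cb, target, center_offset=center_offset))
    else:
        raise ValueError(f"{res.label} is not an anchor residue")


def build_anchor_pair_chain(
    n_interior: int,
    donor_distance: float,
    interior_letter: str = "A",
    source_id: str | None = None,
) -> Structure:
    """A helix H-X_n-C whose minimum donor distance is exactly as requested.

    The terminal Cys SG is re-placed along the His ND1->NE2 axis so that
    its distance to ND1 equals ``donor_distance`` (to within 1e-9 A and
    never above it, so a request at an inclusive cutoff is admitted)
    while the distance to NE2 is strictly larger — exact
    boundary-condition fixtures for the fragment miner.
    """
    seq = "H" + interior_letter * n_interior + "C"
    st = build_ideal_helix(
        seq, source_id=source_id or f"pair-n{n_interior}-d{donor_distance:g}"
    )
    chain = st.chains[0]
    his, cys = chain.residues[0], chain.residues[-1]
    nd1 = his.atom("ND1").coords
    ne2 = his.atom("NE2").coords
    u = nd1 - ne2
    u = u / np.linalg.norm(u)
    sg = cys.atom("SG")
    sg.coords = nd1 + donor_distance * u
    # float guard: normalization rounding must not push the realized
    # distance a few ulp over the requested one
    for _ in range(5):
        realized = max(
            float(np.linalg.norm(sg.coords - nd1)), math.dist(sg.coords, nd1)
        )
        if realized <= donor_distance:
            break
        sg.coords = nd1 + (donor_distance / realized) * (1.0 - 1e-14) * (
            sg.coords - nd1
        )
    return st


def build_random_hc_scene(seed: int, length: tuple[int, int] = (30, 60)) -> Structure:
    """A random chain with sprinkled His/Cys in mixed conformation.

    No outcome is engineered; these scenes exist to exercise the fragment
    miner and alignment ranking against their brute-force oracles over a
    wide range of anchor spacings and geometries.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(length[0], length[1] + 1))
    other = "ADEFGIKLMNPQRSTVWY"
    letters = []
    for _ in range(n):
        roll = rng.random()
        if roll < 0.12:
            letters.append("H")
        elif roll < 0.24:
            letters.append("C")
        else:
            letters.append(other[int(rng.integers(len(other)))])
    torsions = []
    for _ in range(n):
        basin = rng.random()
        if basin < 0.45:
            phi, psi = HELIX_PHI_PSI
        elif basin < 0.75:
            phi, psi = -120.0, 135.0
        else:
            phi, psi = rng.uniform(-180, 180), rng.uniform(-180, 180)
        torsions.append((phi + rng.normal(0, 8), psi + rng.normal(0, 8)))
    return build_chain("".join(letters), torsions, source_id=f"random-{seed}")


# ---------------------------------------------------------------------------
# Engineered design scenes
#
# Each engineered scene is one contiguous chain whose anchor side chains
# are oriented so the binding-site outcome is known by construction.  The
# backbone uses a canonical fold — ideal helices joined by a frozen
# loop/coil torsion set found once by constrained least squares (maximum
# admission-rule margin) — and the per-seed variation jitters those
# torsions, re-solves the donor directions and re-verifies every
# constraint, annealing the jitter to zero if a draw lands outside the
# feasible pocket.  Donor directions are re-solved per build by least
# squares on the four "reach spheres" (all donors are one stub away from
# their CB), so every pairwise donor distance is certified inside an
# inner band of the 1.5-5.5 A admission window.

SCENE_KINDS = ("positive", "donor_far", "long_gap", "wrong_composition", "terminal_coil")

#: Anchor layout shared by the engineered scenes: anchors at 1, 5, 16, 20
#: with distinct inter-anchor filler segments (no stray H/C).
_SEG1, _SEG2, _SEG3 = "AEA", "LNRSGQDLTV", "ADE"
_ANCHOR_IDX = (0, 4, 15, 19)

#: Canonical loop torsions (phi9, psi9 ... phi12, psi12, phi13; degrees)
#: of the helix-loop-helix fold: helix residues 1-8 and 13-20, loop 9-12.
_HLH_LOOP = (-95.1, 11.9, 59.0, -142.1, -80.5, -115.6, 38.8, 163.7, -86.2)

#: Canonical coil torsions (psi12, phi12, psi11, ... phi2, psi1; degrees)
#: of the coil-helix fold used by the terminal-coil scene: residues 1-12
#: coil, 13-20 helix.
_COIL_HELIX = (
    101.9, -93.0, -17.3, -134.7, 6.4, -46.3, 106.5, 10.8, 126.3, 177.3,
    126.0, -91.7, 138.9, -46.4, 87.3, 61.1, 23.8, -20.2, -173.6, -110.9,
    30.4, 59.0, 145.0,
)

#: Donor placement band (Angstrom), an inner margin of the 1.5-5.5 window.
_DONOR_BAND = (2.4, 4.8)
#: Verification window for the evaluator-style min-sum nitrogen choice.
_SITE_LO, _SITE_HI = 1.7, 5.3

_PAIRS4 = list(itertools.combinations(range(4), 2))


def _scene_sequence(anchor_letters: str) -> str:
    b1, b2, b3, b4 = anchor_letters
    return b1 + _SEG1 + b2 + _SEG2 + b3 + _SEG3 + b4


def _hlh_torsions(loop: Sequence[float]) -> list[tuple[float, float]]:
    phi, psi = HELIX_PHI_PSI
    tors = [(phi, psi)] * 8
    tors += [(loop[0], loop[1]), (loop[2], loop[3]), (loop[4], loop[5]), (loop[6], loop[7])]
    tors += [(loop[8], psi)] + [(phi, psi)] * 7
    return tors


def _coil_helix_torsions(coil: Sequence[float]) -> list[tuple[float, float]]:
    phi, psi = HELIX_PHI_PSI
    # coil vector runs C- to N-terminal: psi12, phi12, psi11, ..., phi2, psi1
    phis = {13: phi}
    psis = {}
    k = 0
    for i in range(12, 0, -1):
        psis[i] = coil[k]
        k += 1
        if i >= 2:
            phis[i] = coil[k]
            k += 1
    tors = [(phis.get(i, 0.0), psis[i]) for i in range(1, 13)]
    tors += [(phi, psi)] * 8
    return tors


def _site_donor_check(anchor_residues: Sequence[Residue]) -> bool:
    """Re-derive the evaluator's min-sum nitrogen choice and window test."""
    cand = []
    for res in anchor_residues:
        if res.aa_code == "C":
            cand.append([res.atom("SG").coords])
        else:
            cand.append([res.atom("ND1").coords, res.atom("NE2").coords])
    best = None
    for combo in itertools.product(*cand):
        dists = [float(np.linalg.norm(combo[i] - combo[j])) for i, j in _PAIRS4]
        if best is None or sum(dists) < sum(best):
            best = dists
    return all(_SITE_LO <= d <= _SITE_HI for d in best)


def _solve_donor_directions(
    cbs: np.ndarray, reaches: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Place one donor per anchor on its reach sphere, pairwise in-band.

    Least squares over the four direction vectors with hinge residuals on
    the six pairwise distances; returns unit directions, or None when no
    in-band placement was found from eight seeded starts.
    """
    from scipy.optimize import least_squares

    lo, hi = _DONOR_BAND

    def donors(v: np.ndarray) -> np.ndarray:
        v = v.reshape(4, 3)
        u = v / np.linalg.norm(v, axis=1)[:, None]
        return cbs + reaches[:, None] * u

    def residuals(v: np.ndarray) -> list[float]:
        pts = donors(v)
        out = []
        for i, j in _PAIRS4:
            d = float(np.linalg.norm(pts[i] - pts[j]))
            out.append(d - min(max(d, lo), hi))
        # tiny regularizer keeps the direction norms near 1 (well-posed)
        out.extend(1e-4 * (np.linalg.norm(v.reshape(4, 3), axis=1) - 1.0))
        return out

    centroid = cbs.mean(axis=0)
    for _ in range(8):
        v0 = np.concatenate(
            [
                (centroid - cb) / np.linalg.norm(centroid - cb) + rng.normal(0, 0.25, 3)
                for cb in cbs
            ]
        )
        sol = least_squares(residuals, v0, method="trf", xtol=1e-14, ftol=1e-14, max_nfev=1500)
        if max(abs(r) for r in residuals(sol.x)[:6]) < 1e-9:
            v = sol.x.reshape(4, 3)
            return v / np.linalg.norm(v, axis=1)[:, None]
    return None


def _build_engineered(
    anchor_letters: str,
    base_torsions: Sequence[float],
    torsion_table,
    seed: int,
    source_id: str,
) -> Structure:
    """Jitter the canonical torsions, solve donors, verify; anneal to zero."""
    seq = _scene_sequence(anchor_letters)
    rng = np.random.default_rng(seed)
    base = np.asarray(base_torsions, float)
    for sigma in (3.0, 1.5, 0.5, 0.0):
        for _ in range(4):
            jittered = base + rng.normal(0.0, sigma, base.shape)
            st = build_chain(seq, torsion_table(jittered), source_id=source_id)
            chain = st.chains[0]
            anchors = [chain.residues[i] for i in _ANCHOR_IDX]
            cbs = np.array([_residue_cb(r) for r in anchors])
            reaches = np.array([DONOR_REACH[r.aa_code] for r in anchors])
            dirs = _solve_donor_directions(cbs, reaches, rng)
            if dirs is None:
                continue
            for res, cb, reach, u in zip(anchors, cbs, reaches, dirs):
                _aim_anchor(res, cb + reach * u)
            if _site_donor_check(anchors):
                return st
            if sigma == 0.0:
                break
    raise RuntimeError(f"could not realize scene {source_id}")  # pragma: no cover


def build_design_scene(kind: str = "positive", seed: int = 0) -> Structure:
    """Construct a scene whose pipeline outcome is known by construction.

    kinds
    -----
    positive
        Helix-loop-helix (helices 1-8 and 13-20) with anchors H1, C5,
        H16, C20 whose donors sit pairwise inside the binding-site
        window: mining yields the spanning fragments and assembly exactly
        one C2H2 design passing every screen.
    donor_far
        As positive, but the N-terminal His donor group is re-aimed away
        from the site so every fragment across that anchor fails the
        6.5 A donor rule: no four-anchor design survives.
    long_gap
        A single helix whose only anchor pair is 25 interior residues
        apart: nothing satisfies the 1 < n < 21 length bound.
    wrong_composition
        As positive with anchors H, C, H, H: the assembled site fails the
        two-Cys/two-His composition rule.
    terminal_coil
        Site-feasible, but residues 1-12 (holding anchors 1 and 5) are
        coil and only 13-20 helical: the design fails the terminal-helix
        screen with far more than four leading coil residues.
    """
    if kind not in SCENE_KINDS:
        raise ValueError(f"unknown scene kind {kind!r}; choose from {SCENE_KINDS}")
    source_id = f"scene-{kind}-{seed}"

    if kind == "long_gap":
        return build_ideal_helix("H" + "A" * 25 + "C", source_id=source_id)

    if kind == "terminal_coil":
        return _build_engineered(
            "HCHC", _COIL_HELIX, _coil_helix_torsions, seed, source_id
        )

    letters = "HCHH" if kind == "wrong_composition" else "HCHC"
    st = _build_engineered(letters, _HLH_LOOP, _hlh_torsions, seed, source_id)

    if kind == "donor_far":
        chain = st.chains[0]
        first = chain.residues[0]
        cb = _residue_cb(first)
        others = [
            a.coords
            for i in _ANCHOR_IDX[1:]
            for a in chain.residues[i].atoms
            if a.name in ("SG", "ND1", "NE2")
        ]
        site = np.mean(others, axis=0)
        away = cb - site
        away = away / np.linalg.norm(away)
        for extra in (3.0, 6.0, 10.0, 16.0):
            _aim_anchor(first, cb + 10.0 * away, center_offset=extra)
            donors = [a.coords for a in first.atoms if a.name in ("ND1", "NE2")]
            if min(float(np.linalg.norm(d - o)) for d in donors for o in others) > 6.6:
                break
        else:  # pragma: no cover - geometry always separable
            raise RuntimeError("could not pull donor beyond the distance rule")
    return st


# ---------------------------------------------------------------------------
# ITC forward model


def generate_itc_data(
    dH_bind: float,
    n_Hplus: float,
    buffers: list[tuple[str, float]] | None = None,
    sigma: float = 0.1,
    seed: int = 0,
) -> list[BufferTitration]:
    """Draw per-buffer observed enthalpies from the proton-linkage line.

    dH_obs = dH_bind + n_Hplus * dH_ion + N(0, sigma), seeded.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if buffers is None:
        buffers = list(BUFFER_IONIZATION_ENTHALPY_KCAL.items())
    rng = np.random.default_rng(seed)
    out = []
    for name, dh_ion in buffers:
        noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        out.append(
            BufferTitration(
                buffer_name=name, dH_ion=dh_ion, dH_obs=dH_bind + n_Hplus * dh_ion + noise
            )
        )
    return out


# ---------------------------------------------------------------------------
# Brute-force oracles (tests only; no shared logic with the implementations)


def _oracle_donor_positions(res: Residue) -> list[np.ndarray]:
    names = ("SG",) if res.aa_code == "C" else ("ND1", "NE2")
    return [a.coords for n in names if (a := res.atom(n)) is not None]


def oracle_mine(
    structure: Structure,
    max_donor_distance: float = 6.5,
    n_range: tuple[int, int] = (2, 20),
) -> set[tuple[str, str, int, int]]:
    """Exhaustive fragment enumeration; returns provenance keys.

    Checks every ordered residue pair of every chain against every
    admission condition directly, with no indexing, pruning or shared
    helper from the mining implementation.
    """
    found = set()
    for chain in structure.chains:
        rs = chain.residues
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                a, b = rs[i], rs[j]
                if a.aa_code not in ("H", "C") or b.aa_code not in ("H", "C"):
                    continue
                expected_a = 1 if a.aa_code == "C" else 2
                expected_b = 1 if b.aa_code == "C" else 2
                da = _oracle_donor_positions(a)
                db = _oracle_donor_positions(b)
                if len(da) != expected_a or len(db) != expected_b:
                    continue
                n_int = j - i - 1
                if n_int < n_range[0] or n_int > n_range[1]:
                    continue
                contiguous = True
                for t in range(i, j):
                    p, q = rs[t], rs[t + 1]
                    if (q.seq_number, q.insertion_code) <= (p.seq_number, p.insertion_code):
                        contiguous = False
                        break
                    cc, nn = p.atom("C"), q.atom("N")
                    if cc is None or nn is None:
                        contiguous = False
                        break
                    if math.dist(cc.coords, nn.coords) >= 2.0:
                        contiguous = False
                        break
                if not contiguous:
                    continue
                dmin = min(math.dist(x, y) for x in da for y in db)
                if dmin <= max_donor_distance:
                    found.add(
                        (structure.source_id, chain.chain_id, a.seq_number, b.seq_number)
                    )
    return found


def oracle_knn(
    fragment: Fragment, library: FragmentLibrary, k: int
) -> list[tuple[tuple[str, str, int, int], float]]:
    """Exhaustive compatibility scan ranked by alignment RMSD.

    Independent arithmetic throughout: the backbone fit comes from
    scipy's Rotation.align_vectors and the RMSD over backbone plus donor
    atoms is recomputed directly.  Returns (fragment key, rmsd) pairs.
    """
    end = fragment.anchor_end
    scored = []
    for cand in library:
        start = cand.anchor_start
        if start.aa_code != end.aa_code:
            continue
        bb = ("N", "CA", "C")
        fixed_bb = np.array([end.atom(n).coords for n in bb])
        moving_bb = np.array([start.atom(n).coords for n in bb])
        cf = fixed_bb.mean(axis=0)
        cm = moving_bb.mean(axis=0)
        rot, _ = Rotation.align_vectors(fixed_bb - cf, moving_bb - cm)
        donor_names = ("SG",) if end.aa_code == "C" else ("ND1", "NE2")
        names = bb + donor_names
        sq = 0.0
        for nm in names:
            fx = end.atom(nm).coords
            mv = rot.apply(start.atom(nm).coords - cm) + cf
            sq += float(np.sum((fx - mv) ** 2))
        scored.append((cand.key, math.sqrt(sq / len(names))))
    scored.sort(key=lambda kr: (round(kr[1], 9), kr[0]))
    return scored[:k]


# ---------------------------------------------------------------------------
# Fixture file sets


def write_fixture_set(outdir: str | Path, seed: int = 0) -> dict:
    """Write a PDB/CSV fixture collection plus a JSON manifest.

    Generates the engineered scenes, a random mining scene and a
    noiseless ITC table, all seeded; returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "structures": [], "itc": None}
    for kind in SCENE_KINDS:
        st = build_design_scene(kind, seed=seed)
        path = outdir / f"{st.source_id}.pdb"
        path.write_text(write_structure(st))
        manifest["structures"].append({"kind": kind, "file": path.name})
    rnd = build_random_hc_scene(seed)
    rnd_path = outdir / f"{rnd.source_id}.pdb"
    rnd_path.write_text(write_structure(rnd))
    manifest["structures"].append({"kind": "random", "file": rnd_path.name})

    rows = ["buffer_name,dH_ion,dH_obs"]
    for t in generate_itc_data(dH_bind=-2.9, n_Hplus=-1.8, sigma=0.1, seed=seed):
        rows.append(f"{t.buffer_name},{t.dH_ion},{t.dH_obs:.6f}")
    itc_path = outdir / "itc_synthetic.csv"
    itc_path.write_text("\n".join(rows) + "\n")
    manifest["itc"] = itc_path.name
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
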
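"""Coordinate data model and PDB-format I/O.

The design pipeline only needs a lightweight view of a protein structure:
chains of residues with named atoms and Cartesian coordinates in Angstrom.
Parsing is delegated to gemmi; this module converts the first model of a
PDB file into that view, resolving alternate locations and discarding
waters and non-peptide ligands.

Metal-donor bookkeeping lives here as well: the metal-coordinating
("donor") atoms are the Cys Sgamma thiolate sulfur and the two His
imidazole nitrogens (Ndelta1/Nepsilon2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "PDBParseError",
    "DONOR_ATOM_NAMES",
    "read_structure",
    "write_structure",
    "donor_atoms",
    "has_complete_donors",
    "one_letter_sequence",
    "write_fasta",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

#: Metal-donor atom names by residue one-letter code: the thiolate sulfur of
#: cysteine and the two imidazole nitrogens of histidine.
DONOR_ATOM_NAMES: dict[str, tuple[str, ...]] = {
    "C": ("SG",),
    "H": ("ND1", "NE2"),
}

BACKBONE_ATOMS = ("N", "CA", "C")


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class Atom:
    """A named atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    """One residue: author numbering, one-letter code and its atoms.

    ``aa_code`` is one of the 20 standard one-letter codes, or ``'X'`` for
    anything non-standard (selenomethionine and friends); non-standard
    residues are never eligible as metal anchors.
    """

    chain_id: str
    seq_number: int
    aa_code: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.aa_code not in THREE_TO_ONE.values() and self.aa_code != "X":
            raise ValueError(f"unknown aa_code {self.aa_code!r}")
        seen: set[str] = set()
        for atom in self.atoms:
            if atom.name in seen:
                raise ValueError(
                    f"residue {self.chain_id}{self.seq_number}: duplicate atom {atom.name!r}"
                )
            seen.add(atom.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: Iterable[str]) -> bool:
        return all(self.atom(n) is not None for n in names)

    @property
    def label(self) -> str:
        return f"{self.aa_code}{self.seq_number}{self.insertion_code}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """An ordered collection of chains from one source (PDB entry or fixture)."""

    source_id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in {self.source_id}")

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)


def _validate_coordinate_fields(pdb_text: str) -> None:
    # gemmi silently zeroes unparseable coordinate columns; reject them
    # up front so the caller gets an error naming the offending line.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate field {fld!r}"
                    ) from None


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties go to altloc 'A', then first seen.
    def key(a: gemmi.Atom) -> tuple[float, int]:
        return (-a.occ, 0 if a.altloc in ("", "A") else 1)

    return sorted(atoms, key=key)[0]


def read_structure(pdb_text: str, source_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first model is read (the design protocol operates on single
    conformers).  Waters and non-peptide ligands are dropped; non-standard
    amino acids are kept with ``aa_code='X'``.  For alternate locations the
    highest-occupancy conformer is kept (ties resolve to altloc 'A').

    Raises
    ------
    PDBParseError
        If the text contains no ATOM record or a coordinate field does not
        parse, naming the offending line.
    """
    if not any(line[:6] in ("ATOM  ", "HETATM") for line in pdb_text.splitlines()):
        raise PDBParseError("input contains no ATOM/HETATM record")
    _validate_coordinate_fields(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no model found in PDB input")
    st.setup_entities()

    model = st[0]
    out = Structure(source_id=source_id)
    for gchain in model:
        chain = Chain(chain_id=gchain.name or "A")
        for gres in gchain:
            info = gemmi.find_tabulated_residue(gres.name)
            if info is not None and info.is_water():
                continue
            if info is None or not info.is_amino_acid():
                if gres.name not in THREE_TO_ONE:
                    continue  # hetero ligand
            aa = THREE_TO_ONE.get(gres.name, "X")
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _best_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    )
                )
            chain.residues.append(
                Residue(
                    chain_id=chain.chain_id,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    aa_code=aa,
                    atoms=atoms,
                )
            )
        if chain.residues:
            out.chains.append(chain)
    return out


def write_structure(structure: Structure) -> str:
    """Serialize a :class:`Structure` as PDB-format text (ATOM/TER/END)."""
    lines: list[str] = []
    serial = 1
    for chain in structure.chains:
        res = None
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.aa_code, "UNK")
            for atom in res.atoms:
                name = atom.name
                # PDB column rule: 1-char element symbols start in column 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) < 2 else f"{name:<4s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {padded}{'':1s}{resname:>3s} "
                    f"{chain.chain_id:1s}{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        if res is not None:
            resname = ONE_TO_THREE.get(res.aa_code, "UNK")
            lines.append(
                f"TER   {serial:5d}      {resname:>3s} "
                f"{chain.chain_id:1s}{res.seq_number:4d}{res.insertion_code or ' ':1s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def donor_atoms(residue: Residue) -> list[Atom]:
    """Return the metal-donor atoms present on a His or Cys residue.

    Cys contributes SG; His contributes ND1 and NE2.  Atoms that are
    missing from the model are simply absent from the result, so an
    incomplete side chain yields a shorter (possibly empty) list; use
    :func:`has_complete_donors` to test completeness.

    Raises
    ------
    ValueError
        If the residue is not His or Cys.
    """
    try:
        names = DONOR_ATOM_NAMES[residue.aa_code]
    except KeyError:
        raise ValueError(
            f"residue {residue.label} ({residue.aa_code}) has no metal-donor atoms; "
            "only H and C anchors are supported"
        ) from None
    return [a for name in names if (a := residue.atom(name)) is not None]


def has_complete_donors(residue: Residue) -> bool:
    """True if the residue is His/Cys with its full donor-atom set modeled."""
    names = DONOR_ATOM_NAMES.get(residue.aa_code)
    if names is None:
        return False
    return residue.has_atoms(names)


def one_letter_sequence(chain: Chain | Sequence[Residue]) -> str:
    residues = chain.residues if isinstance(chain, Chain) else chain
    return "".join(r.aa_code for r in residues)


def write_fasta(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    """Format (header, sequence) pairs as FASTA text."""
    chunks = []
    for header, seq in records:
        body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width)) or ""
        chunks.append(f">{header}\n{body}")
    return "\n".join(chunks) + "\n"
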
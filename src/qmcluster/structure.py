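"""Atomic/residue data model and PDB/XYZ readers and writers.

The data model is deliberately small: an ordered hierarchy of
``Structure`` -> ``Residue`` -> ``Atom`` with two workflow-specific atom
flags, ``is_frozen`` (coordinate-locked during geometry optimisation) and
``is_cap`` (link hydrogen added at a truncation point).  Frozen flags are
persisted in PDB output through ``REMARK 250 FROZEN`` records so that a
written model round-trips losslessly; cap atoms are recognised by their
``HCP`` name prefix.

Coordinates are Angstrom everywhere.  No unit conversion happens in this
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueKey",
    "FormatError",
    "read_pdb",
    "write_pdb",
    "write_xyz",
    "read_xyz",
    "parse_residue_key",
    "format_residue_key",
]

#: (chain id, residue number, insertion code)
ResidueKey = tuple[str, int, str]

CAP_NAME_PREFIX = "HCP"

_VALID_ELEMENTS = frozenset(
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA SC TI V CR MN FE CO NI "
    "CU ZN GA GE AS SE BR KR RB SR Y ZR NB MO TC RU RH PD AG CD IN SN SB TE I "
    "XE CS BA".split()
)


class FormatError(ValueError):
    """Raised for malformed structure files (carries the offending line)."""


def parse_residue_key(text: str) -> ResidueKey:
    """Parse ``"A:101"`` or ``"A:101:B"`` into a residue key tuple."""
    parts = str(text).split(":")
    if len(parts) == 2:
        chain, num = parts
        icode = ""
    elif len(parts) == 3:
        chain, num, icode = parts
    else:
        raise ValueError(f"cannot parse residue key {text!r}")
    return (chain, int(num), icode)


def format_residue_key(key: ResidueKey) -> str:
    chain, num, icode = key
    return f"{chain}:{num}:{icode}" if icode else f"{chain}:{num}"


@dataclass
class Atom:
    """A single atom with workflow flags.

    Parameters
    ----------
    serial : int
        Unique integer id within a structure.
    name : str
        PDB-style atom name (e.g. ``CA``, ``OD1``).
    element : str
        Element symbol; validated against the periodic table.
    position : numpy.ndarray
        Cartesian coordinates, Angstrom, shape ``(3,)``.
    residue_key : ResidueKey
        Owning residue ``(chain, number, insertion code)``.
    is_frozen : bool
        True for coordinate-locked centres.
    is_cap : bool
        True for link hydrogens added at truncation points; a cap atom
        must be hydrogen.
    """

    serial: int
    name: str
    element: str
    position: np.ndarray
    residue_key: ResidueKey = ("A", 1, "")
    is_frozen: bool = False
    is_cap: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.element.upper() not in _VALID_ELEMENTS:
            raise ValueError(f"atom {self.name}: invalid element {self.element!r}")
        if self.is_cap and self.element.upper() != "H":
            raise ValueError(f"cap atom {self.name} must be hydrogen")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    """A named group of atoms (amino acid, water, or ligand)."""

    name: str
    key: ResidueKey
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"residue {self.name} {self.key}: duplicate atom names {dup}")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {format_residue_key(self.key)} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]

    def copy(self) -> "Residue":
        return Residue(self.name, self.key, [a.copy() for a in self.atoms])


@dataclass
class Structure:
    """Ordered residues plus hetero (ligand) residues.

    Every atom belongs to exactly one residue; atom serials are unique
    across the whole structure (renumbered on write).
    """

    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    title: str = ""
    #: bookkeeping from read_pdb: {"records": n, "skipped": n}
    parse_log: dict = field(default_factory=dict)

    def all_residues(self) -> list[Residue]:
        return list(self.residues) + list(self.ligands)

    def atoms(self) -> list[Atom]:
        return [a for r in self.all_residues() for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms())

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.all_residues():
            if r.key == key:
                return r
        raise KeyError(f"no residue with key {format_residue_key(key)}")

    def has_residue(self, key: ResidueKey) -> bool:
        return any(r.key == key for r in self.all_residues())

    def positions(self) -> np.ndarray:
        atoms = self.atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms])

    def copy(self) -> "Structure":
        return Structure(
            [r.copy() for r in self.residues],
            [r.copy() for r in self.ligands],
            self.title,
            dict(self.parse_log),
        )

    def renumber(self) -> None:
        """Assign consecutive serials in residue order starting at 1."""
        for i, a in enumerate(self.atoms(), start=1):
            a.serial = i

    def validate(self) -> None:
        serials = [a.serial for a in self.atoms()]
        if len(serials) != len(set(serials)):
            raise ValueError("duplicate atom serials")
        keys = [r.key for r in self.all_residues()]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys")


# ---------------------------------------------------------------------------
# PDB I/O


def _guess_element(name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().capitalize()
    # standard PDB names: column 13 blank => single-letter element in col 14
    stripped = name.strip()
    if stripped[:1].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN") and len(name) == 4:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ATOM records populate ``residues``; HETATM records populate
    ``ligands``.  Alternate locations are resolved to the highest
    occupancy (ties go to the first listed); dropped altloc records are
    counted in ``parse_log["skipped"]``.  ``REMARK 250 FROZEN`` records
    restore frozen flags written by :func:`write_pdb`.
    """
    frozen_serials: set[int] = set()
    # (residue key, resname, hetero) in file order -> {atom name: (atom, occupancy)}
    order: list[tuple] = []
    groups: dict[tuple, dict[str, tuple[Atom, float]]] = {}
    n_records = 0
    n_skipped = 0
    title = ""

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            rec = line[:6].strip()
            if rec == "TITLE":
                title = (title + " " + line[10:].strip()).strip()
            elif rec == "REMARK" and line[7:10].strip() == "250" and "FROZEN" in line:
                for tok in line.split("FROZEN", 1)[1].split():
                    frozen_serials.add(int(tok))
            elif rec in ("ATOM", "HETATM"):
                n_records += 1
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    altloc = line[16]
                    resname = line[17:20].strip() or line[17:21].strip()
                    chain = line[21].strip() or "A"
                    resseq = int(line[22:26])
                    icode = line[26].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    occ_text = line[54:60].strip()
                    occupancy = float(occ_text) if occ_text else 1.0
                    element = _guess_element(line[12:16], line[76:78] if len(line) >= 77 else "")
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"{path}: unparsable {rec} record at line {lineno}: {exc}") from exc
                key = (chain, resseq, icode)
                atom = Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    position=np.array([x, y, z]),
                    residue_key=key,
                    is_cap=name.startswith(CAP_NAME_PREFIX),
                )
                gkey = (key, resname, rec == "HETATM")
                if gkey not in groups:
                    groups[gkey] = {}
                    order.append(gkey)
                prev = groups[gkey].get(name)
                if prev is None:
                    groups[gkey][name] = (atom, occupancy)
                elif altloc != " " and occupancy > prev[1]:
                    groups[gkey][name] = (atom, occupancy)
                    n_skipped += 1
                else:
                    n_skipped += 1  # lower/equal-occupancy altloc, or duplicate

    if n_records == 0:
        raise FormatError(f"{path}: no ATOM or HETATM records")

    structure = Structure(title=title)
    for key, resname, hetero in order:
        atoms = [a for a, _occ in groups[(key, resname, hetero)].values()]
        res = Residue(resname, key, atoms)
        (structure.ligands if hetero else structure.residues).append(res)
    for a in structure.atoms():
        if a.serial in frozen_serials:
            a.is_frozen = True
    structure.parse_log = {"records": n_records, "skipped": n_skipped}
    structure.validate()
    return structure


def _pdb_atom_name(name: str) -> str:
    # standard alignment: element in columns 13-14 -> names of <4 chars padded left
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(structure: Structure, path) -> None:
    """Write ``structure`` as PDB with 3-decimal coordinates.

    Frozen atoms are listed in ``REMARK 250 FROZEN`` records keyed by
    serial so the flag survives a round trip.  Raises on an empty
    structure or more atoms than the fixed-column format can number.
    """
    atoms = structure.atoms()
    if not atoms:
        raise ValueError("refusing to write an empty structure")
    if len(atoms) > 99999:
        raise ValueError(f"{len(atoms)} atoms exceed the PDB serial limit (99999)")
    structure.renumber()

    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    frozen = [a.serial for a in structure.atoms() if a.is_frozen]
    for i in range(0, len(frozen), 10):
        chunk = " ".join(str(s) for s in frozen[i : i + 10])
        lines.append(f"REMARK 250 FROZEN {chunk}")

    def record(res: Residue, hetero: bool) -> None:
        tag = "HETATM" if hetero else "ATOM  "
        chain, num, icode = res.key
        for a in res.atoms:
            x, y, z = a.position
            lines.append(
                f"{tag}{a.serial:>5d} {_pdb_atom_name(a.name)} {res.name:<3.3s} "
                f"{chain[:1]}{num:>4d}{icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element.upper():>2.2s}"
            )

    for res in structure.residues:
        record(res, hetero=False)
    if structure.residues:
        lines.append("TER")
    for res in structure.ligands:
        record(res, hetero=True)
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ I/O


def write_xyz(structure: Structure, path) -> None:
    """Write plain XYZ: count line, title line, then element + coordinates."""
    atoms = structure.atoms()
    with open(path, "w") as fh:
        fh.write(f"{len(atoms)}\n{structure.title}\n")
        for a in atoms:
            x, y, z = a.position
            fh.write(f"{a.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def read_xyz(path) -> Structure:
    """Read XYZ into a single-residue structure (names ``E1, E2, ...``)."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise FormatError(f"{path}: empty XYZ file")
    try:
        count = int(raw[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad XYZ count line") from exc
    title = raw[1] if len(raw) > 1 else ""
    atoms = []
    for i, line in enumerate(raw[2 : 2 + count], start=1):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: bad XYZ atom line {i + 2}")
        atoms.append(
            Atom(
                serial=i,
                name=f"{parts[0].capitalize()}{i}",
                element=parts[0].capitalize(),
                position=np.array([float(p) for p in parts[1:4]]),
                residue_key=("A", 1, ""),
            )
        )
    if len(atoms) != count:
        raise FormatError(f"{path}: count line says {count}, found {len(atoms)} atoms")
    return Structure(residues=[Residue("XYZ", ("A", 1, ""), atoms)], title=title)
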
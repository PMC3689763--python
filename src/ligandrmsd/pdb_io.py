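"""Reading PDB-format structures and extracting bound ligands.

Proteins deposited in the PDB carry their small-molecule ligands as HETATM
records.  This module turns a PDB file into protein :class:`Chain` objects
(with one-letter sequences) and heavy-atom :class:`LigandInstance` objects —
one per bound copy of a chemical component — and applies the dataset
blacklist (tiny compounds, common cofactors/detergents/solutes).

Conventions used throughout:

* hydrogens are dropped everywhere (X-ray structures usually lack them, and
  all downstream atom counts and RMSDs are over non-hydrogen atoms);
* for alternate locations the highest-occupancy altloc is kept
  (tie break: altloc ``A``, then blank);
* waters and modified residues that are covalently part of a polymer chain
  are not ligands.

Coordinate parsing is delegated to :mod:`gemmi`; CONECT connectivity, which
gemmi does not retain, is read by a small fixed-column scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Atom",
    "Chain",
    "LigandInstance",
    "BlacklistConfig",
    "PDBParseError",
    "parse_structure",
    "extract_ligands",
    "infer_bonds",
    "is_blacklisted",
    "ligand_inventory",
    "write_ligand_pdb",
]

#: Residue names treated as water.
WATER_NAMES = {"HOH", "DOD", "WAT"}

#: Extra tolerance added to the sum of covalent radii when inferring bonds
#: from geometry (standard crystallographic heuristic).
COVALENT_TOLERANCE = 0.45

#: Maximum heavy-atom distance accepted as a peptide C–N linkage when
#: deciding whether a modified residue is part of the polymer.
PEPTIDE_BOND_MAX = 1.9


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Chain:
    chain_id: str
    #: ordered (residue name, author residue number, atoms)
    residues: list[tuple[str, int, list[Atom]]]
    sequence: str


@dataclass
class LigandInstance:
    pdb_id: str
    chem_comp_id: str
    chain_id: str
    residue_number: int
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.pdb_id, self.chain_id, self.residue_number)


@dataclass
class BlacklistConfig:
    """Which ligands to exclude from a drug–target dataset.

    A ligand is blacklisted if it has ``max_heavy_atoms`` or fewer heavy
    atoms, or its chemical component id is in ``excluded_comp_ids`` (the
    editable list of common cofactors, detergents and solutes shipped in
    ``data/blacklist.yaml``).
    """

    max_heavy_atoms: int = 5
    excluded_comp_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.max_heavy_atoms < 0:
            raise ValueError("max_heavy_atoms must be >= 0")
        self.excluded_comp_ids = {c.upper() for c in self.excluded_comp_ids}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BlacklistConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            max_heavy_atoms=int(data.get("max_heavy_atoms", 5)),
            excluded_comp_ids=set(data.get("excluded_comp_ids", [])),
        )

    @classmethod
    def default(cls) -> "BlacklistConfig":
        return cls.from_yaml(Path(__file__).parent / "data" / "blacklist.yaml")


# ---------------------------------------------------------------------------
# parsing


def _validate_coordinate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtext = line[lo:hi].strip()
            try:
                float(fieldtext)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {fieldtext!r}"
                ) from None


def _parse_conect(text: str) -> dict[int, set[int]]:
    conect: dict[int, set[int]] = {}
    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        serials = []
        for lo in range(6, min(len(line), 31), 5):
            fieldtext = line[lo : lo + 5].strip()
            if fieldtext:
                serials.append(int(fieldtext))
        if len(serials) < 2:
            continue
        base = serials[0]
        for other in serials[1:]:
            if other == base:
                continue
            conect.setdefault(base, set()).add(other)
            conect.setdefault(other, set()).add(base)
    return conect


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy; ties prefer altloc 'A', then blank, then lexicographic
    def key(a: gemmi.Atom):
        alt = a.altloc if a.altloc not in ("\0",) else ""
        rank = 0 if alt == "A" else (1 if alt == "" else 2)
        return (-a.occ, rank, alt)

    return sorted(atoms, key=key)[0]


def _residue_atoms(res: gemmi.Residue) -> list[Atom]:
    """Heavy atoms of a residue with altlocs resolved."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        if a.element.is_hydrogen:
            continue
        by_name.setdefault(a.name, []).append(a)
    atoms = []
    for name in by_name:
        a = _best_altloc(by_name[name])
        alt = a.altloc if a.altloc not in ("\0",) else ""
        atoms.append(
            Atom(
                serial=a.serial,
                name=name,
                element=a.element.name,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                occupancy=a.occ,
                altloc=alt,
            )
        )
    atoms.sort(key=lambda at: at.serial)
    return atoms


def _is_amino(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code
    return code.upper() if code.isalpha() and info.is_standard() else "X"


def _atom_named(atoms: list[Atom], name: str) -> Atom | None:
    for a in atoms:
        if a.name == name:
            return a
    return None


def _peptide_linked(atoms: list[Atom], neighbours: list[list[Atom]]) -> bool:
    """Is a residue covalently tied into a polymer via a C–N peptide bond?"""
    n, c = _atom_named(atoms, "N"), _atom_named(atoms, "C")
    if n is None and c is None:
        return False
    for other in neighbours:
        oc, on = _atom_named(other, "C"), _atom_named(other, "N")
        if n is not None and oc is not None:
            if np.linalg.norm(n.coords - oc.coords) <= PEPTIDE_BOND_MAX:
                return True
        if c is not None and on is not None:
            if np.linalg.norm(c.coords - on.coords) <= PEPTIDE_BOND_MAX:
                return True
    return False


def parse_structure(
    pdb_text: str, pdb_id: str = ""
) -> tuple[list[Chain], list[LigandInstance], dict[int, set[int]]]:
    """Parse PDB-format text into chains, ligand instances and CONECT map.

    Every non-water HETATM residue that is not a covalently linked modified
    residue of a polymer chain becomes one :class:`LigandInstance` (bonds not
    yet inferred; see :func:`infer_bonds` / :func:`extract_ligands`).

    Raises
    ------
    PDBParseError
        on empty input or malformed coordinate fields (names line number).
    """
    if not any(line[:6] in ("ATOM  ", "HETATM") for line in pdb_text.splitlines()):
        raise PDBParseError("input contains no ATOM or HETATM records")
    _validate_coordinate_lines(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    conect = _parse_conect(pdb_text)

    chains: list[Chain] = []
    ligands: list[LigandInstance] = []
    if len(st) == 0:
        raise PDBParseError("no model found")
    model = st[0]
    for ch in model:
        residues = [(res.name, res.seqid.num, _residue_atoms(res)) for res in ch]
        polymer_idx: list[int] = []
        ligand_idx: list[int] = []
        for i, (resname, _num, atoms) in enumerate(residues):
            het = ch[i].het_flag == "H"
            if resname in WATER_NAMES:
                continue
            if not atoms:
                continue
            if not het:
                polymer_idx.append(i)
            elif _is_amino(resname):
                # modified residue: polymer when peptide-linked to a neighbour
                nbr = [residues[j][2] for j in (i - 1, i + 1) if 0 <= j < len(residues)]
                if _peptide_linked(atoms, nbr):
                    polymer_idx.append(i)
                else:
                    ligand_idx.append(i)
            else:
                ligand_idx.append(i)
        if polymer_idx:
            poly = [residues[i] for i in polymer_idx]
            seq = "".join(_one_letter(rn) for rn, _n, _a in poly)
            chains.append(Chain(chain_id=ch.name, residues=poly, sequence=seq))
        for i in ligand_idx:
            resname, num, atoms = residues[i]
            ligands.append(
                LigandInstance(
                    pdb_id=pdb_id,
                    chem_comp_id=resname,
                    chain_id=ch.name,
                    residue_number=num,
                    atoms=atoms,
                )
            )
    return chains, ligands, conect


def infer_bonds(
    ligand: LigandInstance, conect: Mapping[int, set[int]] | None = None
) -> list[tuple[int, int]]:
    """Bond list (atom-index pairs) for a ligand.

    CONECT records win when they cover the ligand; otherwise bonds are
    created between atom pairs closer than the sum of covalent radii plus
    0.45 Å.  Pairs are deduplicated and returned with ``i < j``.
    """
    if ligand.n_heavy_atoms < 1:
        raise ValueError("ligand has no atoms")
    serial_to_idx = {a.serial: i for i, a in enumerate(ligand.atoms)}
    bonds: set[tuple[int, int]] = set()
    if conect:
        for serial, partners in conect.items():
            i = serial_to_idx.get(serial)
            if i is None:
                continue
            for p in partners:
                j = serial_to_idx.get(p)
                if j is not None and i != j:
                    bonds.add((min(i, j), max(i, j)))
    if not bonds:
        coords = ligand.coords
        radii = [gemmi.Element(a.element).covalent_r for a in ligand.atoms]
        for i, j in itertools.combinations(range(len(coords)), 2):
            cutoff = radii[i] + radii[j] + COVALENT_TOLERANCE
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.add((i, j))
    return sorted(bonds)


def extract_ligands(
    pdb_text: str, pdb_id: str = ""
) -> tuple[list[Chain], list[LigandInstance]]:
    """Parse a structure and return chains plus ligands with bonds inferred."""
    chains, ligands, conect = parse_structure(pdb_text, pdb_id)
    for lig in ligands:
        lig.bonds = infer_bonds(lig, conect)
    return chains, ligands


def is_blacklisted(ligand: LigandInstance, config: BlacklistConfig) -> bool:
    """True iff the ligand is too small or on the excluded-component list."""
    return (
        ligand.n_heavy_atoms <= config.max_heavy_atoms
        or ligand.chem_comp_id.upper() in config.excluded_comp_ids
    )


def ligand_inventory(
    ligands: Iterable[LigandInstance], config: BlacklistConfig | None = None
) -> pd.DataFrame:
    """Tabulate ligand instances with their blacklist verdicts."""
    config = config or BlacklistConfig()
    rows = [
        {
            "pdb_id": lig.pdb_id,
            "chem_comp_id": lig.chem_comp_id,
            "chain_id": lig.chain_id,
            "residue_number": lig.residue_number,
            "n_heavy_atoms": lig.n_heavy_atoms,
            "blacklisted": is_blacklisted(lig, config),
        }
        for lig in ligands
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pdb_id",
            "chem_comp_id",
            "chain_id",
            "residue_number",
            "n_heavy_atoms",
            "blacklisted",
        ],
    )


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: element symbol right-justified in columns 13-14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_ligand_pdb(ligand: LigandInstance) -> str:
    """Serialize one ligand instance as HETATM + CONECT records."""
    lines = []
    for a in ligand.atoms:
        lines.append(
            "HETATM%5d %s%1s%3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
            % (
                a.serial,
                _format_atom_name(a.name, a.element),
                (a.altloc or " "),
                ligand.chem_comp_id[:3],
                (ligand.chain_id or "A")[:1],
                ligand.residue_number,
                a.coords[0],
                a.coords[1],
                a.coords[2],
                a.occupancy,
                0.0,
                a.element.rjust(2),
            )
        )
    for i, j in ligand.bonds:
        lines.append("CONECT%5d%5d" % (ligand.atoms[i].serial, ligand.atoms[j].serial))
    lines.append("END")
    return "\n".join(lines) + "\n"
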
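"""Receptor structure handling: PDB parsing, residue index, reference points.

Structures are predicted enzyme models (e.g. AlphaFold output with the FAD
cofactor placed); only atom identities and coordinates matter downstream.
Parsing is delegated to gemmi after a light fixed-column validation pass
that reports malformed coordinate fields with their line number.  Only the
first model of a multi-model file is kept and altloc 'A' (or blank) is
preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "parse_structure",
    "resolve_selector",
    "write_pseudo_atom_pdb",
]


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain: str
    position: np.ndarray  # (3,) float, Angstrom
    hetero: bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: invalid coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")
        object.__setattr__(self, "position", pos)


ResidueKey = tuple[str, int, str]  # (chain, residue_number, insertion_code)


@dataclass
class Structure:
    """Atoms plus a residue index; hetero groups (FAD etc.) kept separate."""

    atoms: list[AtomRecord]
    residue_index: dict[ResidueKey, list[int]] = field(default_factory=dict)
    hetero_groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residue_index and not self.hetero_groups:
            self._build_index()

    def _build_index(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.hetero:
                self.hetero_groups.setdefault(a.residue_name, []).append(i)
            else:
                key = (a.chain, a.residue_number, a.insertion_code)
                self.residue_index.setdefault(key, []).append(i)

    @property
    def protein_coords(self) -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms) if not a.hetero]
        if not idx:
            return np.empty((0, 3))
        return np.array([self.atoms[i].position for i in idx])

    @property
    def all_coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms])

    def residue_atoms(self, chain: str, number: int, icode: str = "") -> list[AtomRecord]:
        return [self.atoms[i] for i in self.residue_index.get((chain, number, icode), [])]


def _validate_pdb_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise ValueError(f"line {lineno}: truncated coordinate record")
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise ValueError(
                    f"line {lineno}: malformed {label} coordinate {fieldtxt!r}"
                ) from None


def parse_structure(pdb_text: str) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Raises ``ValueError`` (with the line number) on malformed coordinate
    fields.  HETATM records are grouped by residue name as hetero groups
    and excluded from the protein residue index.
    """
    _validate_pdb_lines(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetero = residue.het_flag == "H"
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name or "C",
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        hetero=hetero,
                    )
                )
    if not atoms:
        raise ValueError("no atoms parsed from PDB input")
    return Structure(atoms=atoms)


def resolve_selector(structure: Structure, selector: str) -> np.ndarray:
    """Resolve ``"chain/resnum/atomname"`` to a reference coordinate.

    The atom name ``centroid`` means: the midpoint of the two carboxylate
    oxygens for Asp/Glu (the electrophile-stabilising acid reference),
    otherwise the mean of the residue's atoms.  A plain atom name returns
    that atom's position (so ``A/79/NZ`` is the catalytic-lysine terminal
    nitrogen).
    """
    parts = selector.split("/")
    if len(parts) != 3:
        raise ValueError(
            f"selector {selector!r} is not of the form chain/resnum/atomname"
        )
    chain, resnum_s, atom_name = parts
    try:
        resnum = int(resnum_s)
    except ValueError:
        raise ValueError(f"selector {selector!r}: residue number not an integer")
    residue = structure.residue_atoms(chain, resnum)
    if not residue:
        raise ValueError(f"selector {selector!r}: residue not found")
    if atom_name == "centroid":
        if residue[0].residue_name in ("ASP", "GLU"):
            oxy = [a for a in residue if a.name in ("OD1", "OD2", "OE1", "OE2")]
            if len(oxy) >= 2:
                return (oxy[0].position + oxy[1].position) / 2.0
        return np.mean([a.position for a in residue], axis=0)
    for a in residue:
        if a.name == atom_name:
            return a.position
    raise ValueError(f"selector {selector!r}: atom {atom_name!r} not in residue")


def structure_to_pdb(structure: Structure) -> str:
    """Serialise a :class:`Structure` as fixed-column PDB text.

    Coordinates are written at the format's 3-decimal precision, so a
    write→parse roundtrip preserves them to 1e-3 Å.
    """
    lines = []
    for a in structure.atoms:
        record = "HETATM" if a.hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{a.serial % 100000:5d} {name:<4.4s}"
            f"{a.residue_name:>4.3s} {a.chain:1.1s}{a.residue_number:4d}"
            f"{a.insertion_code:1.1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"  1.00  0.00          {a.element:>2.2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pseudo_atom_pdb(points: np.ndarray, residue_name: str = "PKT") -> str:
    """Render grid points as HETATM pseudo-atoms for visualisation."""
    lines = []
    for i, p in enumerate(np.asarray(points, dtype=float), start=1):
        lines.append(
            f"HETATM{i % 100000:5d}  C   {residue_name} X{1:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
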
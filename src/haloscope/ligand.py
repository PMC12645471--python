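"""Ligand connectivity: aromaticity, halogenation-eligible sites, symmetry.

FDHs brominate aromatic C–H positions, so the only atoms that matter for
substrate/regiochemistry calls are aromatic carbons bearing at least one
hydrogen.  Symmetry classes (graph-automorphism orbits, computed from
RDKit's canonical ranking with ties preserved) let the classifier fold
equivalent positions into one predicted product — a C2-symmetric
substrate halogenated at either para position gives a single compound.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = ["LigandTopology", "parse_ligand", "eligible_sites"]


@dataclass
class LigandTopology:
    """Connectivity, aromaticity and symmetry classes for one compound."""

    mol: Chem.Mol
    elements: list[str]
    bonds: list[tuple[int, int, float]]
    aromatic: list[bool]
    symmetry_class: list[int]
    num_hydrogens: list[int]  # total (implicit + explicit) H per atom

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def class_members(self, cls: int) -> list[int]:
        return [i for i, c in enumerate(self.symmetry_class) if c == cls]


def parse_ligand(molfile_or_smiles: str) -> LigandTopology:
    """Parse an SDF/MOL V2000 block or a SMILES string.

    Aromaticity: explicit aromatic bond flags in a connection table are
    trusted; otherwise RDKit's ring perception + Hückel-style model is
    applied during sanitisation.  Explicit hydrogens are folded into
    per-heavy-atom hydrogen counts so docking outputs (which usually drop
    nonpolar H) can be mapped by heavy-atom order.
    """
    text = molfile_or_smiles.strip()
    if "V2000" in text or "\n" in text:
        mol = Chem.MolFromMolBlock(molfile_or_smiles, sanitize=True, removeHs=True)
        source = "molblock"
    else:
        mol = Chem.MolFromSmiles(text)
        source = "smiles"
    if mol is None:
        raise ValueError(f"unparsable ligand ({source} input)")
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    return LigandTopology(
        mol=mol,
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        bonds=[
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ],
        aromatic=[a.GetIsAromatic() for a in mol.GetAtoms()],
        symmetry_class=ranks,
        num_hydrogens=[a.GetTotalNumHs() for a in mol.GetAtoms()],
    )


def eligible_sites(topology: LigandTopology) -> list[int]:
    """Indices of halogenation-eligible atoms: aromatic carbons with ≥1 H.

    An empty list is valid — such a molecule cannot be a substrate.
    """
    return [
        i
        for i in range(topology.n_atoms)
        if topology.elements[i] == "C"
        and topology.aromatic[i]
        and topology.num_hydrogens[i] >= 1
    ]
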
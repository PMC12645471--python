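"""Docked-pose parsing and halogenation-site geometry.

Docking engines emit multi-pose files (the AutoDock/Vina PDBQT dialect,
or a multi-model PDB with a sidecar energy table).  For each pose the
geometric quantities that drive candidacy and regiochemistry are the
distances from the predicted halogenation carbon — the eligible aromatic
carbon nearest the catalytic-lysine reference — to the K79 side-chain
nitrogen and the D307 carboxylate midpoint.  Distances are measured from
the ring carbon itself, not its hydrogen, which keeps the measurement
stable when docking outputs omit nonpolar hydrogens.

Energies are stored internally in kJ/mol (negative = favourable);
kcal/mol inputs are converted by the exact factor 4.184.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ligand import LigandTopology, eligible_sites

__all__ = [
    "KCAL_TO_KJ",
    "DockedPose",
    "SiteAssignment",
    "parse_poses",
    "assign_site",
    "group_degenerate_poses",
]

KCAL_TO_KJ = 4.184

#: PDBQT atom types mapped to elements (docking dialect).
_PDBQT_ELEMENTS = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H", "P": "P", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I",
}


@dataclass
class DockedPose:
    """One docked orientation of a compound with its binding energy."""

    compound_id: str
    pose_id: str
    coordinates: np.ndarray  # (n_topology_atoms, 3); NaN rows = H omitted
    binding_energy: float    # kJ/mol

    def __post_init__(self) -> None:
        if not np.isfinite(self.binding_energy):
            raise ValueError(
                f"pose {self.compound_id}/{self.pose_id}: non-finite energy"
            )


@dataclass(frozen=True)
class SiteAssignment:
    """The predicted halogenation site of one pose with its key distances."""

    compound_id: str
    pose_id: str
    site_atom_index: int
    site_symmetry_class: int
    d_k79: float  # Å
    d_d307: float  # Å


def _convert_energy(value: float, unit: str) -> float:
    unit = unit.lower().replace(" ", "")
    if unit in ("kcal/mol", "kcal"):
        return value * KCAL_TO_KJ
    if unit in ("kj/mol", "kj"):
        return value
    raise ValueError(f"unknown energy unit {unit!r}")


def _map_heavy_atoms(
    records: list[tuple[str, np.ndarray]],
    topology: LigandTopology,
    where: str,
) -> np.ndarray:
    """Map pose atoms onto topology indices by heavy-atom order.

    Nonpolar-hydrogen records are dropped (docking dialect); the remaining
    elements must agree with the topology in order — a mismatch is fatal,
    never guessed.
    """
    heavy = [(el, xyz) for el, xyz in records if el != "H"]
    if len(heavy) != topology.n_atoms:
        raise ValueError(
            f"{where}: {len(heavy)} heavy atoms vs {topology.n_atoms} in topology"
        )
    coords = np.full((topology.n_atoms, 3), np.nan)
    for i, (el, xyz) in enumerate(heavy):
        if el != topology.elements[i]:
            raise ValueError(
                f"{where}: atom {i} element {el!r} != topology "
                f"{topology.elements[i]!r}"
            )
        coords[i] = xyz
    return coords


def parse_poses(
    pose_text: str,
    topology: LigandTopology,
    energy_unit: str = "kcal/mol",
    compound_id: str = "compound",
    energy_table: pd.DataFrame | None = None,
) -> list[DockedPose]:
    """Parse a multi-pose PDBQT-dialect (or multi-model PDB) file.

    Per-pose energies are read from ``REMARK VINA RESULT`` lines unless an
    ``energy_table`` with columns (compound_id, pose_id, energy, unit) is
    supplied.  ``energy_unit`` applies to remark energies.
    """
    poses: list[DockedPose] = []
    model_id: str | None = None
    records: list[tuple[str, np.ndarray]] = []
    remark_energy: float | None = None
    n_models = 0

    def flush() -> None:
        nonlocal records, remark_energy
        if not records:
            return
        pid = model_id if model_id is not None else str(n_models)
        where = f"{compound_id}/pose {pid}"
        coords = _map_heavy_atoms(records, topology, where)
        if energy_table is not None:
            row = energy_table[
                (energy_table["compound_id"].astype(str) == str(compound_id))
                & (energy_table["pose_id"].astype(str) == str(pid))
            ]
            if row.empty:
                raise ValueError(f"{where}: no energy-table entry")
            energy = _convert_energy(
                float(row.iloc[0]["energy"]), str(row.iloc[0].get("unit", "kJ/mol"))
            )
        elif remark_energy is not None:
            energy = _convert_energy(remark_energy, energy_unit)
        else:
            raise ValueError(f"{where}: no energy remark and no energy table")
        poses.append(
            DockedPose(
                compound_id=compound_id,
                pose_id=pid,
                coordinates=coords,
                binding_energy=energy,
            )
        )
        records = []
        remark_energy = None

    for line in pose_text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
            n_models += 1
            model_id = line[6:].strip() or str(n_models)
        elif rec == "ENDMDL":
            flush()
            model_id = None
        elif rec == "REMARK" and "RESULT" in line.upper():
            fields = line.replace(":", " ").split()
            nums = [f for f in fields if _is_number(f)]
            if nums:
                remark_energy = float(nums[0])
        elif rec in ("ATOM", "HETATM"):
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            # PDBQT puts the AutoDock atom type in the last column; plain
            # PDB puts the element there
            tail = line[76:].split()
            token = tail[-1].upper() if tail else line[12:16].strip()[:1]
            element = _PDBQT_ELEMENTS.get(token, token.capitalize())
            records.append((element, xyz))
    flush()
    if not poses:
        raise ValueError(f"{compound_id}: no poses parsed")
    return poses


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def assign_site(
    pose: DockedPose,
    topology: LigandTopology,
    k79_ref: np.ndarray,
    d307_ref: np.ndarray,
) -> SiteAssignment | None:
    """Pick the pose's halogenation site: the eligible carbon nearest K79.

    Ties are broken by symmetry class then lowest atom index.  Returns
    ``None`` ("no site") when the molecule has no eligible aromatic C–H.
    """
    sites = eligible_sites(topology)
    if not sites:
        return None
    k79_ref = np.asarray(k79_ref, dtype=float)
    d307_ref = np.asarray(d307_ref, dtype=float)
    best = min(
        sites,
        key=lambda i: (
            float(np.linalg.norm(pose.coordinates[i] - k79_ref)),
            topology.symmetry_class[i],
            i,
        ),
    )
    return SiteAssignment(
        compound_id=pose.compound_id,
        pose_id=pose.pose_id,
        site_atom_index=best,
        site_symmetry_class=topology.symmetry_class[best],
        d_k79=float(np.linalg.norm(pose.coordinates[best] - k79_ref)),
        d_d307=float(np.linalg.norm(pose.coordinates[best] - d307_ref)),
    )


def group_degenerate_poses(
    poses_with_assignments: list[tuple[DockedPose, SiteAssignment]],
    delta_e_tol: float = 2.5,
) -> list[tuple[DockedPose, SiteAssignment]]:
    """Collapse near-degenerate poses into distinct predicted outcomes.

    Poses within ``delta_e_tol`` kJ/mol of the best (most negative)
    energy are retained; retained poses sharing a site symmetry class are
    collapsed to the best-energy representative.  Output is sorted by
    energy, so two surviving entries mean two predicted regioisomers.
    """
    if not poses_with_assignments:
        raise ValueError("no poses with assignments")
    best_e = min(p.binding_energy for p, _ in poses_with_assignments)
    retained = [
        (p, a)
        for p, a in poses_with_assignments
        if p.binding_energy <= best_e + delta_e_tol
    ]
    by_class: dict[int, tuple[DockedPose, SiteAssignment]] = {}
    for p, a in retained:
        cur = by_class.get(a.site_symmetry_class)
        if cur is None or p.binding_energy < cur[0].binding_energy:
            by_class[a.site_symmetry_class] = (p, a)
    return sorted(by_class.values(), key=lambda pa: pa[0].binding_energy)
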
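"""Synthetic benchmark generators with recorded ground truth.

Every input the pipeline consumes can be generated here with a known
answer: protein sequences with planted motifs, additive distance
matrices from known trees, toy receptors with carved cavities and
channels, and docked-pose sets with assigned energies and controlled
site geometry.  Each generator is a pure function of (spec, seed) and
returns its artifact together with a :class:`SyntheticTruth` that alone
suffices to score pipeline output.

What is and is not emulated
---------------------------
Receptors are blocks of carbon pseudo-atoms on a jittered lattice with
explicit wall shells placed so that carved free volumes match their
analytic values; there are no side chains, so only occupancy geometry is
realistic.  Pose energies are *assigned*, not computed — the spatial
arrangement of ligand atoms is a geometric stand-in that satisfies the
requested site distances, not a physical binding mode.  A deliberately
non-physical toy scorer is included for tutorials only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .ligand import LigandTopology, eligible_sites, parse_ligand
from .motifs import AMINO_ACIDS, DEFAULT_MOTIFS, MotifPattern, ProteinSequence, compile_motif
from .phylo import DistanceMatrix, PhyloTree
from .poses import KCAL_TO_KJ, DockedPose
from .structure import AtomRecord, Structure

__all__ = [
    "SyntheticTruth",
    "gen_sequences",
    "random_binary_tree",
    "gen_distances_from_tree",
    "ReceptorSpec",
    "CavityBox",
    "gen_receptor",
    "gen_pose_set",
    "write_pdbqt",
    "gen_screen",
    "ScreenFixture",
    "toy_score",
]


@dataclass
class SyntheticTruth:
    """Serializable ground truth for one generated artifact."""

    kind: str
    seed: int
    data: dict

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "data": self.data},
            indent=2, sort_keys=True, default=_jsonable,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(kind=obj["kind"], seed=obj["seed"], data=obj["data"])


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return np.round(o, 6).tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------
# sequences


def gen_sequences(
    n: int,
    length: int,
    plant_spec: str | list[tuple[str, int]] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinSequence], SyntheticTruth]:
    """I.i.d.-uniform sequences with motif instances overwritten at
    recorded positions.

    ``plant_spec`` is either ``None`` (pure background), an explicit list
    of ``(pattern_text, start)`` planted in every sequence, or
    ``"random"`` — the three default FDH motifs planted at random
    non-overlapping ascending positions per sequence.  Wildcard positions
    within a planted motif are randomised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    planted: list[dict] = []
    seqs: list[ProteinSequence] = []

    def instantiate(pat: MotifPattern, r: np.random.Generator) -> str:
        out = []
        for tok in pat.tokens:
            if isinstance(tok, int):
                out.extend(r.choice(aa, size=tok))
            else:
                out.append(tok)
        return "".join(out)

    compiled = {p: compile_motif(p) for p in DEFAULT_MOTIFS}

    for i in range(n):
        sid = f"seq{i:04d}"
        residues = list(rng.choice(aa, size=length))
        plants: list[tuple[MotifPattern, int]] = []
        if plant_spec == "random":
            spans = [compiled[p].min_length for p in DEFAULT_MOTIFS]
            if length < sum(spans):
                raise ValueError("length too short for the three default motifs")
            # pick ascending non-overlapping starts by splitting the slack
            slack = length - sum(spans)
            cuts = np.sort(rng.integers(0, slack + 1, size=3))
            pos = 0
            for k, p in enumerate(DEFAULT_MOTIFS):
                start = int(cuts[k]) + sum(spans[:k])
                plants.append((compiled[p], start))
        elif isinstance(plant_spec, list):
            pats = [
                (compiled.get(p) or compile_motif(p), s) for p, s in plant_spec
            ]
            occupied: set[int] = set()
            for pat, s in pats:
                span = range(s, s + pat.min_length)
                if s < 0 or s + pat.min_length > length:
                    raise ValueError(f"plant of {pat.name} at {s} out of range")
                if occupied & set(span):
                    raise ValueError(f"plant of {pat.name} at {s} overlaps")
                occupied.update(span)
            plants = pats
        elif plant_spec is not None:
            raise ValueError(f"unknown plant_spec {plant_spec!r}")
        for pat, s in plants:
            inst = instantiate(pat, rng)
            residues[s : s + len(inst)] = list(inst)
            planted.append(
                {"sequence_id": sid, "motif": pat.name, "start": s, "matched": inst}
            )
        seqs.append(ProteinSequence(id=sid, residues="".join(residues)))

    truth = SyntheticTruth(
        kind="sequences", seed=seed,
        data={"n": n, "length": length, "planted": planted},
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# trees and distances


def random_binary_tree(n_taxa: int, seed: int = 0,
                       branch_range: tuple[float, float] = (0.05, 0.5)) -> PhyloTree:
    """A random unrooted binary tree with uniform branch lengths."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    lo, hi = branch_range

    leaf_names = {i: f"t{i}" for i in range(n_taxa)}
    edges: dict[frozenset[int], float] = {}
    # start from a 3-star, then attach each new leaf to a random edge
    center = n_taxa
    next_id = n_taxa + 1
    for leaf in range(3):
        edges[frozenset((leaf, center))] = float(rng.uniform(lo, hi))
    for leaf in range(3, n_taxa):
        target = sorted(edges)[int(rng.integers(0, len(edges)))]
        u, v = sorted(target)
        L = edges.pop(target)
        mid = next_id
        next_id += 1
        f = float(rng.uniform(0.2, 0.8))
        edges[frozenset((u, mid))] = L * f
        edges[frozenset((v, mid))] = L * (1 - f)
        edges[frozenset((leaf, mid))] = float(rng.uniform(lo, hi))
    return PhyloTree(leaf_names=leaf_names, edges=edges)


def gen_distances_from_tree(
    tree: PhyloTree,
    seed: int = 0,
    noise: float = 0.0,
    allow_multifurcation: bool = False,
) -> tuple[DistanceMatrix, SyntheticTruth]:
    """Additive path-length distances from a tree, optionally perturbed.

    In exact mode (noise 0) a non-binary tree is rejected unless
    ``allow_multifurcation`` (star trees are useful as a limit case).
    Noise adds a bounded symmetric uniform perturbation.
    """
    if any(L < 0 for L in tree.edges.values()):
        raise ValueError("tree has negative branch lengths")
    if not allow_multifurcation:
        adj = tree._adjacency()
        for node, nbrs in adj.items():
            if node not in tree.leaf_names and len(nbrs) != 3 and len(adj) > 2:
                raise ValueError(f"internal node {node} is not binary")
    D = tree.path_lengths()
    d = D.d.copy()
    if noise > 0:
        rng = np.random.default_rng(seed)
        pert = rng.uniform(-noise, noise, size=d.shape)
        pert = np.triu(pert, 1)
        d = np.clip(d + pert + pert.T, 0.0, None)
        np.fill_diagonal(d, 0.0)
    out = DistanceMatrix(taxa=D.taxa, d=d)
    truth = SyntheticTruth(
        kind="distances", seed=seed,
        data={
            "taxa": list(D.taxa),
            "splits": [sorted(s) for s in tree.splits()],
            "noise": noise,
        },
    )
    return out, truth


# ---------------------------------------------------------------------------
# receptors

_LATTICE = 2.0
_JITTER = 0.2
_ATOM_R = 1.7
_PROBE_R = 1.4
_WALL_GAP = _ATOM_R + _PROBE_R  # atom-center offset that puts the free
                                # boundary exactly on the nominal surface


@dataclass(frozen=True)
class CavityBox:
    """An axis-aligned cubic cavity."""

    center: tuple[float, float, float]
    side: float

    @property
    def volume(self) -> float:
        return self.side ** 3


@dataclass(frozen=True)
class ReceptorSpec:
    """A carved-block receptor: cavities, optional channel, Lys/Asp refs.

    The channel runs along +z from the first cavity's +z face to the
    block surface; the catalytic Lys NZ sits ``lys_gap`` outside the
    first cavity's −x face and the Asp carboxylate midpoint is offset
    from it in +y.
    """

    block_half: float = 12.0
    cavities: tuple[CavityBox, ...] = (CavityBox((0.0, 0.0, 0.0), 10.0),)
    channel_radius: float = 1.5
    with_channel: bool = True
    lys_gap: float = 4.0
    asp_offset: float = 6.0

    def __post_init__(self) -> None:
        for c in self.cavities:
            for k in range(3):
                if abs(c.center[k]) + c.side / 2 + _WALL_GAP > self.block_half:
                    raise ValueError(f"cavity {c} does not fit inside the block")


def gen_receptor(
    spec: ReceptorSpec = ReceptorSpec(), seed: int = 0
) -> tuple[Structure, SyntheticTruth]:
    """Build the carved-block receptor with recorded analytic geometry.

    Lattice pseudo-atoms (all carbon, 2.0 Å spacing, ±0.2 Å jitter) form
    the solid; explicit wall-shell atoms are placed ``_WALL_GAP`` outside
    every cavity face and around the channel so detected free volumes
    track the analytic cavity volumes.
    """
    rng = np.random.default_rng(seed)
    main = spec.cavities[0]
    ccen = np.array(main.center, dtype=float)
    chalf = main.side / 2

    def in_cavity_carve(p: np.ndarray, margin: float) -> bool:
        for c in spec.cavities:
            if np.all(np.abs(p - np.array(c.center, dtype=float)) < c.side / 2 + margin):
                return True
        return False

    def in_channel_carve(p: np.ndarray, margin: float) -> bool:
        if not spec.with_channel:
            return False
        r = np.hypot(p[0] - ccen[0], p[1] - ccen[1])
        return r < spec.channel_radius + margin and p[2] > ccen[2] + chalf - margin

    carve_margin = _WALL_GAP + _JITTER * np.sqrt(3)
    positions: list[np.ndarray] = []
    n_side = int(np.floor(spec.block_half / _LATTICE))
    axis = _LATTICE * np.arange(-n_side, n_side + 1)
    for x in axis:
        for y in axis:
            for z in axis:
                p = np.array([x, y, z]) + rng.uniform(-_JITTER, _JITTER, size=3)
                if in_cavity_carve(p, carve_margin) or in_channel_carve(p, carve_margin):
                    continue
                positions.append(p)

    # explicit wall shells: atoms exactly _WALL_GAP outside each cavity face
    shell_spacing = 1.2
    for c in spec.cavities:
        cen = np.array(c.center, dtype=float)
        h = c.side / 2 + _WALL_GAP
        ticks = np.arange(-h, h + 1e-9, shell_spacing)
        for axis_k in range(3):
            for sign in (-1, 1):
                for a in ticks:
                    for b in ticks:
                        p = cen.copy()
                        p[axis_k] += sign * h
                        p[(axis_k + 1) % 3] += a
                        p[(axis_k + 2) % 3] += b
                        if in_channel_carve(p, _WALL_GAP):
                            continue  # keep the channel mouth open
                        if any(
                            np.all(np.abs(p - np.array(c2.center)) < c2.side / 2 + _WALL_GAP - 1e-6)
                            for c2 in spec.cavities
                        ):
                            continue
                        positions.append(p)
    # channel wall: rings of atoms at radius channel_radius + _WALL_GAP
    channel_length = 0.0
    start_point = None
    if spec.with_channel:
        rw = spec.channel_radius + _WALL_GAP
        z0 = ccen[2] + chalf
        z1 = spec.block_half
        for z in np.arange(z0 + _WALL_GAP, z1 + 1e-9, 1.0):
            for theta in np.arange(0, 2 * np.pi, shell_spacing / rw):
                positions.append(
                    np.array(
                        [ccen[0] + rw * np.cos(theta), ccen[1] + rw * np.sin(theta), z]
                    )
                )
        start_point = np.array([ccen[0], ccen[1], z1 - 1.0])
        channel_length = float(start_point[2] - z0)

    atoms: list[AtomRecord] = []
    serial = 1
    for p in positions:
        atoms.append(
            AtomRecord(
                serial=serial, name="C", element="C", residue_name="BLK",
                residue_number=serial, insertion_code="", chain="A",
                position=p, hetero=False,
            )
        )
        serial += 1

    # catalytic references on the first cavity wall
    lys_nz = ccen + np.array([-(chalf + spec.lys_gap), 0.0, 0.0])
    lys_num = serial
    atoms.append(
        AtomRecord(serial=serial, name="NZ", element="N", residue_name="LYS",
                   residue_number=lys_num, insertion_code="", chain="A",
                   position=lys_nz, hetero=False)
    )
    serial += 1
    asp_mid = lys_nz + np.array([0.0, spec.asp_offset, 0.0])
    asp_num = serial
    for name, off in (("OD1", np.array([0.0, 0.0, 0.6])),
                      ("OD2", np.array([0.0, 0.0, -0.6]))):
        atoms.append(
            AtomRecord(serial=serial, name=name, element="O", residue_name="ASP",
                       residue_number=asp_num, insertion_code="", chain="A",
                       position=asp_mid + off, hetero=False)
        )
        serial += 1

    structure = Structure(atoms=atoms)
    truth = SyntheticTruth(
        kind="receptor", seed=seed,
        data={
            "cavity_volumes": [c.volume for c in spec.cavities],
            "cavity_centers": [list(c.center) for c in spec.cavities],
            "cavity_sides": [c.side for c in spec.cavities],
            "channel_length": channel_length,
            "channel_start": None if start_point is None else start_point,
            "expected_tunnel_length": (
                None if start_point is None
                else float(np.linalg.norm(start_point - ccen))
            ),
            "lys_nz": lys_nz,
            "lys_residue": lys_num,
            "asp_mid": asp_mid,
            "asp_residue": asp_num,
            "main_cavity": 0,
        },
    )
    return structure, truth


# ---------------------------------------------------------------------------
# poses


def _place_site(
    k79: np.ndarray, d307: np.ndarray, d_k79: float, d_d307: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A point at the requested distances from both references."""
    u = d307 - k79
    L = float(np.linalg.norm(u))
    if not (abs(d_k79 - d_d307) <= L <= d_k79 + d_d307):
        raise ValueError(
            f"requested distances d_K79={d_k79}, d_D307={d_d307} violate the "
            f"triangle constraint with reference separation {L:.2f}"
        )
    u /= L
    x = (d_k79 ** 2 - d_d307 ** 2 + L ** 2) / (2 * L)
    r = float(np.sqrt(max(d_k79 ** 2 - x ** 2, 0.0)))
    # deterministic-but-seeded azimuth around the reference axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    phi = float(rng.uniform(0, 2 * np.pi))
    return k79 + x * u + r * (np.cos(phi) * e1 + np.sin(phi) * e2)


def gen_pose_set(
    topology: LigandTopology,
    sites: list[int],
    energies_kj: list[float],
    d_k79: list[float],
    d_d307: list[float],
    k79_ref: np.ndarray,
    d307_ref: np.ndarray,
    seed: int = 0,
    compound_id: str = "compound",
) -> tuple[list[DockedPose], SyntheticTruth]:
    """Pose set with controlled site geometry and assigned energies.

    For pose *i* the true-site carbon ``sites[i]`` is placed exactly
    ``d_k79[i]``/``d_d307[i]`` Å from the two references and every other
    heavy atom strictly farther from the K79 reference, so nearest-carbon
    site assignment must recover the plant.  Raises when the requested
    distances are geometrically infeasible.
    """
    if not (len(sites) == len(energies_kj) == len(d_k79) == len(d_d307)):
        raise ValueError("per-pose spec lists must have equal length")
    elig = set(eligible_sites(topology))
    rng = np.random.default_rng(seed)
    k79_ref = np.asarray(k79_ref, dtype=float)
    d307_ref = np.asarray(d307_ref, dtype=float)
    poses: list[DockedPose] = []
    records = []
    for i, (site, e, dk, dd) in enumerate(zip(sites, energies_kj, d_k79, d_d307)):
        if site is not None and site not in elig:
            raise ValueError(f"pose {i}: atom {site} is not an eligible site")
        coords = np.zeros((topology.n_atoms, 3))
        if site is None:
            # no-site compounds: a line of atoms, geometry irrelevant
            base = k79_ref + np.array([dk, 0.0, 0.0])
            for j in range(topology.n_atoms):
                coords[j] = base + np.array([0.0, 1.4 * j, 0.0])
        else:
            p = _place_site(k79_ref, d307_ref, dk, dd, rng)
            v = p - k79_ref
            v /= np.linalg.norm(v)
            e1 = np.cross(v, [0.0, 0.0, 1.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(v, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            coords[site] = p
            others = [j for j in range(topology.n_atoms) if j != site]
            for rank, j in enumerate(others, start=1):
                # strictly increasing distance from the K79 reference
                coords[j] = p + v * (0.6 + 0.45 * rank) + e1 * 0.2 * np.sin(rank)
        poses.append(
            DockedPose(
                compound_id=compound_id, pose_id=str(i + 1),
                coordinates=coords, binding_energy=float(e),
            )
        )
        records.append(
            {"pose_id": str(i + 1), "site": site,
             "site_class": None if site is None else topology.symmetry_class[site],
             "energy_kj": float(e), "d_k79": dk, "d_d307": dd}
        )
    truth = SyntheticTruth(
        kind="poses", seed=seed,
        data={"compound_id": compound_id, "poses": records,
              "k79_ref": k79_ref, "d307_ref": d307_ref},
    )
    return poses, truth


_PDBQT_TYPE = {"C": "C", "N": "N", "O": "OA", "S": "SA", "P": "P",
               "F": "F", "Cl": "Cl", "Br": "Br", "I": "I"}


def write_pdbqt(poses: list[DockedPose], topology: LigandTopology) -> str:
    """Serialise poses in the Vina PDBQT dialect (energies in kcal/mol)."""
    out = []
    for m, pose in enumerate(poses, start=1):
        out.append(f"MODEL {m}")
        kcal = pose.binding_energy / KCAL_TO_KJ
        out.append(f"REMARK VINA RESULT:  {kcal:9.4f}      0.000      0.000")
        for i in range(topology.n_atoms):
            el = topology.elements[i]
            atype = "A" if (el == "C" and topology.aromatic[i]) else _PDBQT_TYPE.get(el, el.upper())
            x, y, z = pose.coordinates[i]
            name = f"{el}{i + 1}"[:4]
            out.append(
                f"ATOM  {i + 1:5d} {name:<4.4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  0.00  0.00     0.000 {atype:<2s}"
            )
        out.append("ENDMDL")
    return "\n".join(out) + "\n"


def toy_score(structure: Structure, coordinates: np.ndarray,
              c: float = 2.0, cutoff: float = 4.0) -> float:
    """Deliberately non-physical tutorial scorer.

    E = −c × (number of receptor atoms within ``cutoff`` of any ligand
    atom), kJ/mol.  Illustrates pipeline plumbing only; never used by the
    classifier or the generators' assigned energies.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(structure.all_coords)
    coords = np.asarray(coordinates, dtype=float)
    coords = coords[np.all(np.isfinite(coords), axis=1)]
    hits = set()
    for p in coords:
        hits.update(tree.query_ball_point(p, cutoff))
    return -c * len(hits)


# ---------------------------------------------------------------------------
# full screen


#: Aromatic, modestly bulky biaryl-flavoured chemotypes for screens.
SMILES_LIBRARY: tuple[tuple[str, str], ...] = (
    ("6-hydroxyquinoline", "Oc1ccc2ncccc2c1"),
    ("5-amino-3-methyl-1-phenylpyrazole", "Cc1cc(N)n(-c2ccccc2)n1"),
    ("2-(1H-indol-2-yl)aniline", "Nc1ccccc1-c1cc2ccccc2[nH]1"),
    ("2-methyl-8-quinolinol", "Cc1ccc2cccc(O)c2n1"),
    ("4,4'-dihydroxybenzophenone", "Oc1ccc(cc1)C(=O)c1ccc(O)cc1"),
    ("chrysin", "O=C1C=C(c2ccccc2)Oc2cc(O)cc(O)c12"),
    ("2-(isoxazol-5-yl)phenol", "Oc1ccccc1-c1ccno1"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    ("4-phenylphenol", "Oc1ccc(-c2ccccc2)cc1"),
    ("2-phenylphenol", "Oc1ccccc1-c1ccccc1"),
    ("4-(pyridin-2-yl)aniline", "Nc1ccc(-c2ccccn2)cc1"),
    ("4-(furan-2-yl)phenol", "Oc1ccc(-c2ccco2)cc1"),
    ("4-(thiophen-2-yl)phenol", "Oc1ccc(-c2cccs2)cc1"),
    ("4-phenylpyridine", "c1ccc(-c2ccncc2)cc1"),
    ("2-(p-tolyl)phenol", "Cc1ccc(-c2ccccc2O)cc1"),
    ("4,4'-biphenol", "Oc1ccc(-c2ccc(O)cc2)cc1"),
)

#: Fully substituted ring: no aromatic C–H, hence never a substrate.
NO_SITE_SMILES = ("hexamethylbenzene", "Cc1c(C)c(C)c(C)c(C)c1C")

_FAILURE_MODES = ("too_weak", "too_tight", "d307_out", "no_site")


@dataclass
class CompoundFixture:
    compound_id: str
    name: str
    smiles: str
    topology: LigandTopology
    poses: list[DockedPose]
    truth: dict


@dataclass
class ScreenFixture:
    """A complete synthetic screen: receptor, references, pose sets, truth."""

    receptor: Structure
    receptor_truth: SyntheticTruth
    k79_ref: np.ndarray
    d307_ref: np.ndarray
    compounds: list[CompoundFixture]
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        """Write the fixture in the pipeline's own input formats."""
        from pathlib import Path
        from .structure import structure_to_pdb

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "receptor.pdb").write_text(structure_to_pdb(self.receptor))
        (out / "truth.json").write_text(self.truth.to_json())
        lines = ["compound_id\tname\tsmiles"]
        for c in self.compounds:
            (out / f"{c.compound_id}.pdbqt").write_text(
                write_pdbqt(c.poses, c.topology)
            )
            lines.append(f"{c.compound_id}\t{c.name}\t{c.smiles}")
        (out / "compounds.tsv").write_text("\n".join(lines) + "\n")
        refs = {"k79_ref": self.k79_ref, "d307_ref": self.d307_ref}
        (out / "references.json").write_text(
            json.dumps(refs, default=_jsonable, indent=2)
        )


def gen_screen(
    n_total: int = 53, n_substrate: int = 7, seed: int = 0
) -> ScreenFixture:
    """A full screen fixture mirroring a 53-compound challenge panel.

    ``n_substrate`` compounds receive in-window energies with in-range
    geometry; the rest draw a failure mode from {too_weak, too_tight,
    d307 out of range, no eligible site}, round-robin first so every
    gate is exercised even in small fixtures.
    """
    if not (0 <= n_substrate <= n_total):
        raise ValueError("need 0 <= n_substrate <= n_total")
    rng = np.random.default_rng(seed)
    receptor, rec_truth = gen_receptor(ReceptorSpec(), seed=seed)
    k79 = np.array(rec_truth.data["lys_nz"], dtype=float)
    d307 = np.array(rec_truth.data["asp_mid"], dtype=float)

    labels = ["substrate"] * n_substrate + ["non_substrate"] * (n_total - n_substrate)
    order = rng.permutation(n_total)
    labels = [labels[i] for i in order]

    n_fail = n_total - n_substrate
    modes_pool = list(_FAILURE_MODES) * (n_fail // 4 + 1)
    fail_modes = modes_pool[:n_fail]
    rng.shuffle(fail_modes)

    compounds: list[CompoundFixture] = []
    truth_rows = []
    fail_i = 0
    topo_cache: dict[str, LigandTopology] = {}
    for i in range(n_total):
        cid = f"C{i + 1:02d}"
        label = labels[i]
        mode = None
        if label == "non_substrate":
            mode = fail_modes[fail_i]
            fail_i += 1
        if mode == "no_site":
            name, smi = NO_SITE_SMILES
        else:
            name, smi = SMILES_LIBRARY[i % len(SMILES_LIBRARY)]
        topo = topo_cache.get(smi)
        if topo is None:
            topo = parse_ligand(smi)
            topo_cache[smi] = topo

        if mode == "no_site":
            site = None
        else:
            elig = eligible_sites(topo)
            site = int(elig[rng.integers(0, len(elig))])

        if label == "substrate":
            best_e = float(rng.uniform(-35.0, -21.5))
            dd = float(rng.uniform(6.0, 10.5))
        elif mode == "too_weak":
            best_e = float(rng.uniform(-19.5, -12.0))
            dd = float(rng.uniform(6.0, 10.5))
        elif mode == "too_tight":
            best_e = float(rng.uniform(-45.0, -38.0))
            dd = float(rng.uniform(6.0, 10.5))
        elif mode == "d307_out":
            best_e = float(rng.uniform(-35.0, -21.5))
            dd = float(rng.uniform(12.5, 14.0))
        else:  # no_site
            best_e = float(rng.uniform(-35.0, -21.5))
            dd = float(rng.uniform(6.0, 10.5))
        dk = float(np.clip(dd + rng.uniform(-2.0, 2.0), 6.0, 10.5)) \
            if mode != "d307_out" else float(dd - rng.uniform(3.5, 5.5))

        # two decoy poses, clearly outside the degeneracy tolerance
        decoys = [best_e + float(rng.uniform(3.5, 8.0)) for _ in range(2)]
        sites = [site] * 3
        energies = [best_e] + decoys
        dks = [dk, dk + 0.5, dk + 1.0]
        dds = [dd, min(dd + 0.5, 10.5 if mode != "d307_out" else 15.0), dd]
        poses, _ = gen_pose_set(
            topo, sites, energies, dks, dds, k79, d307,
            seed=int(rng.integers(0, 2 ** 31 - 1)), compound_id=cid,
        )
        row = {
            "compound_id": cid, "name": name, "smiles": smi, "label": label,
            "failure_mode": mode, "true_site": site,
            "true_site_class": None if site is None else topo.symmetry_class[site],
            "best_energy_kj": best_e, "d_k79": dk, "d_d307": dd,
        }
        truth_rows.append(row)
        compounds.append(
            CompoundFixture(
                compound_id=cid, name=name, smiles=smi,
                topology=topo, poses=poses, truth=row,
            )
        )

    truth = SyntheticTruth(
        kind="screen", seed=seed,
        data={
            "n_total": n_total, "n_substrate": n_substrate,
            "k79_ref": k79, "d307_ref": d307,
            "compounds": truth_rows,
        },
    )
    return ScreenFixture(
        receptor=receptor, receptor_truth=rec_truth,
        k79_ref=k79, d307_ref=d307, compounds=compounds, truth=truth,
    )
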
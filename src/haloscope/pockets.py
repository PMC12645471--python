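"""Grid-based cavity detection, HOX-tunnel search, and binding-pocket triage.

The substrate site of an FDH is an interior cavity that must simultaneously
(a) sit near the catalytic lysine that hands over the electrophilic
hypohalous acid, (b) be reachable from the flavin region through the HOX
tunnel (a channel on the ~10 Å scale), and (c), when docking evidence is
available, actually bind ligands with negative energy.  This module finds
candidate cavities with a LIGSITE-style axis scan, searches the free-space
grid for the tunnel with Dijkstra, and applies the three-way triage.

Occupancy convention: a grid point is *free* iff its distance to the
nearest atom center exceeds ``atom_radius + probe_radius`` (defaults
1.7 + 1.4 Å).  All cavity and tunnel geometry is computed on these free
points; clearance at a point is (distance to nearest atom center −
atom_radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .structure import Structure, resolve_selector

__all__ = [
    "GridParams",
    "PocketModel",
    "TunnelPath",
    "detect_pockets",
    "lining_residues",
    "find_tunnel",
    "select_binding_pocket",
]

#: The 7 LIGSITE scan axes: 3 Cartesian plus 4 cube diagonals.
_SCAN_AXES = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 1),
        (1, -1, 1),
        (1, 1, -1),
        (1, -1, -1),
    ],
    dtype=int,
)


@dataclass(frozen=True)
class GridParams:
    """Shared cavity/tunnel grid parameters (all Å)."""

    spacing: float = 1.0
    probe_radius: float = 1.4
    atom_radius: float = 1.7
    range_cutoff: float = 12.0
    enclosure_axes: int = 5  # of the 7 scan axes
    min_volume: float = 50.0
    pad: float = 4.0  # > atom_radius + probe_radius, so the exterior
                      # band next to the box is collision-free

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")


@dataclass
class PocketModel:
    """A detected cavity: member grid points, volume, centroid, lining."""

    grid_points: np.ndarray  # (m, 3) world coordinates
    volume: float            # Å^3, = m * spacing^3
    centroid: np.ndarray
    lining_residues: list[tuple[str, int, str]] = field(default_factory=list)
    rank_score: float = 0.0
    spacing: float = 1.0


@dataclass
class TunnelPath:
    waypoints: np.ndarray    # (k, 3) ordered world coordinates
    length: float            # Å, sum of consecutive waypoint distances
    bottleneck_radius: float  # Å, min clearance along waypoints


class _Grid:
    """Regular grid over the structure bounding box with free/clearance maps."""

    def __init__(self, structure: Structure, params: GridParams):
        coords = structure.all_coords
        if coords.shape[0] == 0:
            raise ValueError("structure has no atoms")
        self.params = params
        lo = coords.min(axis=0) - params.pad
        hi = coords.max(axis=0) + params.pad
        s = params.spacing
        self.origin = lo
        self.shape = tuple(int(np.floor((hi[k] - lo[k]) / s)) + 1 for k in range(3))
        axes = [lo[k] + s * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        self.points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        tree = cKDTree(coords)
        nearest, _ = tree.query(self.points, k=1)
        self.clearance = (nearest - params.atom_radius).reshape(self.shape)
        self.free = self.clearance > params.probe_radius

    def world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + self.params.spacing * np.asarray(idx, dtype=float)

    def cell_of(self, point: np.ndarray) -> tuple[int, int, int]:
        rel = (np.asarray(point, dtype=float) - self.origin) / self.params.spacing
        cell = np.clip(np.round(rel).astype(int), 0, np.array(self.shape) - 1)
        return tuple(cell)


def _shift(arr: np.ndarray, d: np.ndarray) -> np.ndarray:
    """``out[i] = arr[i + d]`` with False beyond the boundary."""
    out = np.zeros_like(arr)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k in range(3):
        if d[k] > 0:
            src[k] = slice(d[k], None)
            dst[k] = slice(None, -d[k])
        elif d[k] < 0:
            src[k] = slice(None, d[k])
            dst[k] = slice(-d[k], None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _enclosure_count(free: np.ndarray, params: GridParams) -> np.ndarray:
    """Per-cell count of scan axes blocked by protein on *both* sides."""
    occupied = ~free
    counts = np.zeros(free.shape, dtype=np.int8)
    for axis in _SCAN_AXES:
        step_len = params.spacing * float(np.linalg.norm(axis))
        nsteps = max(1, int(np.floor(params.range_cutoff / step_len)))
        hits = []
        for sign in (1, -1):
            d = sign * axis
            cur = occupied
            hit = np.zeros_like(free)
            for _ in range(nsteps):
                cur = _shift(cur, d)
                hit |= cur
            hits.append(hit)
        counts += (hits[0] & hits[1]).astype(np.int8)
    return counts


def detect_pockets(
    structure: Structure,
    grid_spacing: float = 1.0,
    probe_radius: float = 1.4,
    min_volume: float = 50.0,
    params: GridParams | None = None,
) -> list[PocketModel]:
    """Detect interior cavities, ranked by volume (descending).

    A free grid point is *enclosed* when protein blocks at least
    ``enclosure_axes`` of the 7 scan axes (both directions, within the
    range cutoff); 6-connected components of enclosed points with volume
    ≥ ``min_volume`` become pockets.  Deterministic for fixed inputs.
    """
    if params is None:
        params = GridParams(
            spacing=grid_spacing, probe_radius=probe_radius, min_volume=min_volume
        )
    grid = _Grid(structure, params)
    counts = _enclosure_count(grid.free, params)
    enclosed = grid.free & (counts >= params.enclosure_axes)
    labels, nlab = ndimage.label(enclosed)
    pockets: list[PocketModel] = []
    cell_vol = params.spacing ** 3
    for lab in range(1, nlab + 1):
        idx = np.argwhere(labels == lab)
        vol = len(idx) * cell_vol
        if vol < params.min_volume:
            continue
        pts = grid.world(idx)
        pockets.append(
            PocketModel(
                grid_points=pts,
                volume=vol,
                centroid=pts.mean(axis=0),
                rank_score=vol,
                spacing=params.spacing,
            )
        )
    pockets.sort(key=lambda p: -p.volume)
    return pockets


def lining_residues(
    structure: Structure, pocket: PocketModel, cutoff: float = 4.5
) -> list[tuple[str, int, str]]:
    """Protein residues with ≥1 atom within ``cutoff`` of a pocket point,
    sorted by chain then residue number."""
    tree = cKDTree(pocket.grid_points)
    found: set[tuple[str, int, str]] = set()
    lining: list[tuple[str, int, str]] = []
    for a in structure.atoms:
        if a.hetero:
            continue
        if tree.query_ball_point(a.position, cutoff):
            key = (a.chain, a.residue_number, a.residue_name)
            if key not in found:
                found.add(key)
                lining.append(key)
    lining.sort(key=lambda k: (k[0], k[1]))
    pocket.lining_residues = lining
    return lining


def _neighbor_offsets() -> np.ndarray:
    """26-neighbourhood offsets, one representative per +/- pair."""
    offs = []
    for raw in np.ndindex(3, 3, 3):
        d = tuple(np.array(raw) - 1)
        if any(d) and d > tuple(-x for x in d):
            offs.append(d)
    return np.array(offs, dtype=int)


_NEIGHBOR_OFFSETS = _neighbor_offsets()


def find_tunnel(
    structure: Structure,
    start: np.ndarray,
    pocket: PocketModel,
    probe_radius: float = 1.4,
    params: GridParams | None = None,
) -> TunnelPath | None:
    """Shortest clearance-weighted path from ``start`` into the pocket core.

    Dijkstra on the free grid with edge cost
    ``step_length * (1 + 1 / clearance)`` (clearance averaged over the
    edge's endpoints).  The target is the pocket's *core* — the
    reachable pocket cell of maximal clearance — rather than the pocket
    cell nearest the start: with axis-scan enclosure an access channel
    is itself part of the pocket component, so a nearest-member target
    would terminate at the channel mouth instead of traversing it.
    Returns ``None`` when no collision-free path exists — a blocked
    channel, distinct from malformed input which raises.
    """
    if params is None:
        params = GridParams(probe_radius=probe_radius, spacing=pocket.spacing)
    grid = _Grid(structure, params)
    start = np.asarray(start, dtype=float)
    start_cell = grid.cell_of(start)
    if not grid.free[start_cell]:
        raise ValueError("start point is not collision-free at the probe radius")

    free_idx = np.argwhere(grid.free)
    flat = np.ravel_multi_index(free_idx.T, grid.shape)
    node_of = -np.ones(int(np.prod(grid.shape)), dtype=np.int64)
    node_of[flat] = np.arange(len(flat))
    clear_flat = grid.clearance.ravel()

    rows, cols, costs = [], [], []
    shape = np.array(grid.shape)
    for off in _NEIGHBOR_OFFSETS:
        nb = free_idx + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, grid.shape)
        nb_node = node_of[nb_flat]
        valid = nb_node >= 0
        src = np.arange(len(free_idx))[ok][valid]
        dst = nb_node[valid]
        step = params.spacing * float(np.linalg.norm(off))
        cmean = 0.5 * (clear_flat[flat[src]] + clear_flat[nb_flat[valid]])
        w = step * (1.0 + 1.0 / np.maximum(cmean, 1e-6))
        rows.append(src)
        cols.append(dst)
        costs.append(w)
    n = len(free_idx)
    graph = coo_matrix(
        (np.concatenate(costs), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    start_node = node_of[np.ravel_multi_index(start_cell, grid.shape)]
    dist, pred = dijkstra(
        graph, directed=False, indices=start_node, return_predecessors=True
    )

    # candidate targets: pocket cells snapped onto this grid, restricted to
    # the pocket core (maximal clearance, quarter-cell tolerance)
    target_nodes: dict[int, float] = {}
    for p in pocket.grid_points:
        cell = grid.cell_of(p)
        fl = np.ravel_multi_index(cell, grid.shape)
        node = node_of[fl]
        if node >= 0:
            target_nodes[int(node)] = float(clear_flat[fl])
    if not target_nodes:
        return None
    max_clear = max(target_nodes.values())
    core = [t for t, c in target_nodes.items() if c >= max_clear - 0.25 * params.spacing]
    reachable = [t for t in core if np.isfinite(dist[t])]
    if not reachable:
        return None
    end = min(reachable, key=lambda t: dist[t])

    path_nodes = [end]
    while path_nodes[-1] != start_node:
        path_nodes.append(int(pred[path_nodes[-1]]))
    path_nodes.reverse()
    waypoints = grid.world(free_idx[path_nodes])
    length = float(np.sum(np.linalg.norm(np.diff(waypoints, axis=0), axis=1)))
    bottleneck = float(np.min(clear_flat[flat[path_nodes]]))
    return TunnelPath(waypoints=waypoints, length=length, bottleneck_radius=bottleneck)


def select_binding_pocket(
    pockets: list[PocketModel],
    structure: Structure,
    lys_ref: str | np.ndarray,
    flavin_start: np.ndarray,
    energy_evidence: dict[int, float] | None = None,
    proximity_cutoff: float = 8.0,
    probe_radius: float = 1.4,
) -> tuple[PocketModel | None, list[dict]]:
    """Triage candidate pockets into the catalytically plausible site.

    A pocket qualifies iff (a) the catalytic-lysine reference atom lies
    within ``proximity_cutoff`` of some pocket grid point, (b) a tunnel
    from ``flavin_start`` reaches it, and (c), if per-pocket best docking
    energies are supplied, its best energy is negative (kJ/mol).  Among
    qualifiers the largest pocket wins.  Returns ``(chosen, report)``
    where ``chosen`` is ``None`` for an explicit "no plausible site"
    outcome; the report lists, per pocket, which criteria failed.
    Criteria are evaluated on grid points, never centroids.
    """
    if not pockets:
        raise ValueError("no pockets supplied")
    if isinstance(lys_ref, str):
        lys_point = resolve_selector(structure, lys_ref)
    else:
        lys_point = np.asarray(lys_ref, dtype=float)
    report = []
    qualifiers = []
    for i, pocket in enumerate(pockets):
        failed = []
        d_lys = float(np.min(np.linalg.norm(pocket.grid_points - lys_point, axis=1)))
        if d_lys > proximity_cutoff:
            failed.append("lysine_proximity")
        tunnel = find_tunnel(structure, flavin_start, pocket, probe_radius)
        if tunnel is None:
            failed.append("hox_tunnel")
        if energy_evidence is not None:
            best_e = energy_evidence.get(i)
            if best_e is None or not best_e < 0.0:
                failed.append("binding_energy")
        report.append(
            {
                "pocket_index": i,
                "volume_A3": pocket.volume,
                "d_lys_A": d_lys,
                "tunnel_length_A": None if tunnel is None else tunnel.length,
                "failed": failed,
            }
        )
        if not failed:
            qualifiers.append(pocket)
    chosen = max(qualifiers, key=lambda p: p.volume) if qualifiers else None
    return chosen, report
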
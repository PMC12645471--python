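"""Substrate candidacy and regiochemistry calls.

The decision rule combines a binding-energy window with a geometric gate:

* energy window — poses binding weaker than ``e_weak`` (−20.92 kJ/mol)
  are non-binders; tighter than ``e_tight`` (−35.56 kJ/mol) risks
  product inhibition.  The window endpoints are the exact kJ/mol images
  of −5.0 and −8.5 kcal/mol.  Boundaries are inclusive, and a narrow
  ``borderline_tight`` band (default 1.0 kJ/mol past the tight bound)
  is accepted by default: the best-performing known substrate of the
  reference enzyme sits 0.42 kJ/mol past the tight bound, so a hard
  cutoff would reject a confirmed substrate.  Sign convention: energies
  are negative, "more than −35.56" means tighter (more negative).

* geometry gate — the carbon to be halogenated must lie within
  ``d307_max`` (11.5 Å) of the catalytic-aspartate reference.  The K79
  distance is reported and compared across poses (it orders regioisomer
  consumption) but is not an accept/reject gate; a soft warning is
  emitted when it exceeds 11.5 Å.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .ligand import LigandTopology, eligible_sites
from .poses import DockedPose, SiteAssignment, group_degenerate_poses

__all__ = [
    "EnergyClass",
    "CandidacyThresholds",
    "PredictedSite",
    "SubstrateCall",
    "classify_energy",
    "classify_candidate",
    "predict_regiochemistry",
    "summarize_screen",
]

# energy classes, in sweep order from tight to weak
TOO_TIGHT = "too_tight"
BORDERLINE_TIGHT = "borderline_tight"
OPTIMAL = "optimal"
TOO_WEAK = "too_weak"
EnergyClass = str


@dataclass(frozen=True)
class CandidacyThresholds:
    """Decision parameters of the candidacy rule (energies kJ/mol, distances Å)."""

    e_weak: float = -20.92
    e_tight: float = -35.56
    d307_max: float = 11.5
    delta_e_tol: float = 2.5
    tight_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not (self.e_tight < self.e_weak < 0):
            raise ValueError("require e_tight < e_weak < 0")
        if self.d307_max <= 0:
            raise ValueError("d307_max must be positive")
        if self.delta_e_tol < 0 or self.tight_tolerance < 0:
            raise ValueError("tolerances must be >= 0")

    @classmethod
    def from_file(cls, path: str) -> "CandidacyThresholds":
        """Load from JSON or ``key = value`` text."""
        with open(path) as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = float(val.strip())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class PredictedSite:
    """One retained regiochemical outcome."""

    symmetry_class: int
    atom_index: int
    d_k79: float
    d_d307: float
    energy: float  # kJ/mol


@dataclass
class SubstrateCall:
    """Per-compound verdict with the evidence that produced it."""

    compound_id: str
    label: str  # "substrate" | "non_substrate"
    energy_class: EnergyClass | None
    failed_gates: list[str] = field(default_factory=list)
    predicted_sites: list[PredictedSite] = field(default_factory=list)
    symmetric: bool = False
    best_energy: float | None = None
    dihalogenation_plausible: bool = False
    warnings: list[str] = field(default_factory=list)
    reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def classify_energy(e: float, thresholds: CandidacyThresholds | None = None) -> EnergyClass:
    """Place a binding energy (kJ/mol) in the candidacy window.

    Sweeping e from −50 to 0 visits too_tight → borderline_tight →
    optimal → too_weak exactly once each; window boundaries inclusive.
    """
    th = thresholds or CandidacyThresholds()
    if e > th.e_weak:
        return TOO_WEAK
    if th.e_tight <= e <= th.e_weak:
        return OPTIMAL
    if th.e_tight - th.tight_tolerance <= e < th.e_tight:
        return BORDERLINE_TIGHT
    return TOO_TIGHT


def classify_candidate(
    compound_id: str,
    poses_with_assignments: list[tuple[DockedPose, SiteAssignment]],
    topology: LigandTopology | None = None,
    thresholds: CandidacyThresholds | None = None,
    accept_borderline_tight: bool = True,
) -> SubstrateCall:
    """Apply the candidacy gates to one compound's pose set.

    Gates, all evaluated on the best-energy retained pose set:
    G1 — energy class optimal (borderline_tight also accepted when
    ``accept_borderline_tight``); G2 — predicted site within ``d307_max``
    of the D307 reference.  A compound with no pose or no eligible site
    is a non-substrate with the reason recorded; every outcome is a
    structured call, never an exception.
    """
    th = thresholds or CandidacyThresholds()
    if topology is not None and not eligible_sites(topology):
        return SubstrateCall(
            compound_id=compound_id, label="non_substrate",
            energy_class=None, reason="no_site", failed_gates=["no_site"],
        )
    usable = [(p, a) for p, a in poses_with_assignments if a is not None]
    if not usable:
        reason = "no_site" if poses_with_assignments else "no_pose"
        return SubstrateCall(
            compound_id=compound_id, label="non_substrate",
            energy_class=None, reason=reason, failed_gates=[reason],
        )

    retained = group_degenerate_poses(usable, th.delta_e_tol)
    best_pose, _ = retained[0]
    e_class = classify_energy(best_pose.binding_energy, th)
    failed: list[str] = []
    ok_classes = {OPTIMAL} | ({BORDERLINE_TIGHT} if accept_borderline_tight else set())
    if e_class not in ok_classes:
        failed.append("G1_energy_window")
    in_range = [(p, a) for p, a in retained if a.d_d307 <= th.d307_max]
    if not in_range:
        failed.append("G2_d307_distance")

    warnings = [
        f"pose {a.pose_id}: d_K79 {a.d_k79:.1f} A exceeds 11.5 A"
        for _, a in retained
        if a.d_k79 > 11.5
    ]

    if failed:
        return SubstrateCall(
            compound_id=compound_id, label="non_substrate",
            energy_class=e_class, failed_gates=failed,
            best_energy=best_pose.binding_energy, warnings=warnings,
        )

    sites = [
        PredictedSite(
            symmetry_class=a.site_symmetry_class,
            atom_index=a.site_atom_index,
            d_k79=a.d_k79,
            d_d307=a.d_d307,
            energy=p.binding_energy,
        )
        for p, a in in_range
    ]
    symmetric = False
    if topology is not None:
        symmetric = any(
            len(topology.class_members(s.symmetry_class)) >= 2 for s in sites
        )
    # qualitative only: in-pocket rotation or exit/re-entry can put a second
    # halogen on an equivalent or near-degenerate site
    dihal = symmetric or len(sites) >= 2
    return SubstrateCall(
        compound_id=compound_id, label="substrate", energy_class=e_class,
        predicted_sites=sites, symmetric=symmetric,
        best_energy=best_pose.binding_energy,
        dihalogenation_plausible=dihal, warnings=warnings,
    )


def predict_regiochemistry(call: SubstrateCall, topology: LigandTopology) -> list[dict]:
    """One entry per retained outcome; ≥2 entries = regioisomer mixture.

    A symmetry class spanning equivalent positions (size ≥ 2) yields a
    single product from either member and is annotated ``symmetric``.
    """
    if call.label != "substrate":
        raise ValueError(f"{call.compound_id}: regiochemistry of a non-substrate")
    report = []
    for site in call.predicted_sites:
        members = topology.class_members(site.symmetry_class)
        report.append(
            {
                "symmetry_class": site.symmetry_class,
                "atom_indices": members,
                "symmetric": len(members) >= 2,
                "d_k79": site.d_k79,
                "energy_kj_mol": site.energy,
            }
        )
    return report


def summarize_screen(calls: list[SubstrateCall]) -> dict:
    """Screen-level summary: counts by label/energy class, one-line verdicts."""
    if not calls:
        raise ValueError("no calls to summarize")
    ids = [c.compound_id for c in calls]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes}")
    ordered = sorted(calls, key=lambda c: c.compound_id)
    by_label: dict[str, int] = {}
    by_energy: dict[str, int] = {}
    for c in ordered:
        by_label[c.label] = by_label.get(c.label, 0) + 1
        key = c.energy_class or "none"
        by_energy[key] = by_energy.get(key, 0) + 1
    verdicts = [
        {
            "compound_id": c.compound_id,
            "label": c.label,
            "energy_class": c.energy_class,
            "best_energy_kj_mol": c.best_energy,
            "n_predicted_sites": len(c.predicted_sites),
            "symmetric": c.symmetric,
            "failed_gates": list(c.failed_gates),
        }
        for c in ordered
    ]
    return {
        "n_compounds": len(ordered),
        "n_substrates": by_label.get("substrate", 0),
        "by_label": by_label,
        "by_energy_class": by_energy,
        "verdicts": verdicts,
    }
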
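"""End-to-end orchestration of the discovery workflow.

Stages run in order — mine → pockets → poses → classify → screen — over
a run directory.  Each stage's inputs (files + the config) are hashed;
an up-to-date stage (same hashes, outputs present) is skipped, so a
rerun without changes is a no-op with byte-identical outputs.  Per-
compound failures during pose analysis are quarantined, not fatal: one
corrupt pose file must not sink a 53-compound screen.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    CandidacyThresholds,
    classify_candidate,
    summarize_screen,
)
from .ligand import parse_ligand
from .motifs import DEFAULT_MOTIFS, ProteinSequence, compile_motif, scan_motifs, screen_halogenase_candidates
from .pockets import detect_pockets, find_tunnel, select_binding_pocket
from .poses import assign_site, parse_poses
from .structure import parse_structure, resolve_selector

logger = logging.getLogger("haloscope")

__all__ = ["PipelineConfig", "run_pipeline"]

_CONFIG_KEYS = {
    "motifs", "fasta", "receptor_pdb", "compounds_tsv", "poses_dir",
    "references", "k79_selector", "d307_selector", "flavin_start",
    "grid_spacing", "probe_radius", "min_volume", "thresholds",
    "accept_borderline_tight", "seed", "energy_unit",
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    fasta: str | None = None
    receptor_pdb: str | None = None
    compounds_tsv: str | None = None
    poses_dir: str | None = None
    references: str | None = None          # JSON with k79_ref/d307_ref coords
    k79_selector: str | None = None        # e.g. "A/79/NZ"
    d307_selector: str | None = None       # e.g. "A/307/centroid"
    flavin_start: tuple[float, float, float] | None = None
    grid_spacing: float = 1.0
    probe_radius: float = 1.4
    min_volume: float = 50.0
    thresholds: dict = field(default_factory=dict)
    accept_borderline_tight: bool = True
    seed: int = 0
    energy_unit: str = "kcal/mol"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "motifs" in data:
            data["motifs"] = tuple(data["motifs"])
        if "flavin_start" in data and data["flavin_start"] is not None:
            data["flavin_start"] = tuple(data["flavin_start"])
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()[:16]


def _header(config: PipelineConfig) -> str:
    return f"# config_hash={config.hash()} seed={config.seed}\n"


def _read_fasta(path: str) -> list[ProteinSequence]:
    from Bio import SeqIO

    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run all configured stages; returns the manifest.

    The manifest records, per stage, the input hash, outputs, and status
    (``done`` / ``skipped`` / ``failed``); the run's exit status is the
    worst stage outcome and a failing stage halts everything downstream.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "MANIFEST.json"
    previous = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest: dict = {"config_hash": config.hash(), "stages": {}}
    halted = False

    def run_stage(name: str, input_paths: list[Path], outputs: list[Path], fn):
        nonlocal halted
        if halted:
            manifest["stages"][name] = {"status": "not_run"}
            return
        in_hash = _hash_files([p for p in input_paths if p.exists()]) + config.hash()
        prev = previous.get("stages", {}).get(name, {})
        if prev.get("input_hash") == in_hash and all(p.exists() for p in outputs):
            logger.info("stage=%s level=INFO message=skipped (up to date)", name)
            manifest["stages"][name] = {**prev, "status": "skipped"}
            return
        try:
            fn()
            manifest["stages"][name] = {
                "status": "done",
                "input_hash": in_hash,
                "outputs": [str(p) for p in outputs],
            }
            logger.info("stage=%s level=INFO message=done", name)
        except Exception as exc:  # quarantine the stage, halt downstream
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            logger.error("stage=%s level=ERROR message=%s", name, exc)
            halted = True

    # --- stage: mine -------------------------------------------------------
    if config.fasta:
        fasta_p = Path(config.fasta)
        hits_p = out / "hits.tsv"
        cand_p = out / "candidates.txt"

        def mine():
            seqs = _read_fasta(str(fasta_p))
            patterns = [compile_motif(m) for m in config.motifs]
            rows = [_header(config).rstrip(),
                    "sequence_id\tmotif\tstart_1based\tmatched"]
            for s in seqs:
                for h in scan_motifs(s, patterns):
                    rows.append(f"{h.sequence_id}\t{h.motif_name}\t{h.start + 1}\t{h.matched}")
            hits_p.write_text("\n".join(rows) + "\n")
            selected = screen_halogenase_candidates(seqs, tuple(patterns))
            cand_p.write_text(_header(config) + "\n".join(selected) + "\n")

        run_stage("mine", [fasta_p], [hits_p, cand_p], mine)

    # --- stage: pockets ----------------------------------------------------
    chosen_pocket = None
    structure = None
    if config.receptor_pdb:
        pdb_p = Path(config.receptor_pdb)
        pockets_p = out / "pockets.json"

        def pockets_stage():
            nonlocal chosen_pocket, structure
            structure = parse_structure(pdb_p.read_text())
            pockets = detect_pockets(
                structure, config.grid_spacing, config.probe_radius,
                config.min_volume,
            )
            payload = {
                "config_hash": config.hash(), "seed": config.seed,
                "pockets": [
                    {"volume_A3": p.volume, "centroid": np.round(p.centroid, 3).tolist()}
                    for p in pockets
                ],
            }
            if pockets and config.k79_selector and config.flavin_start:
                chosen, report = select_binding_pocket(
                    pockets, structure, config.k79_selector,
                    np.array(config.flavin_start), probe_radius=config.probe_radius,
                )
                payload["triage"] = report
                payload["chosen"] = (
                    None if chosen is None
                    else next(i for i, p in enumerate(pockets) if p is chosen)
                )
                chosen_pocket = chosen
            pockets_p.write_text(json.dumps(payload, indent=2))

        run_stage("pockets", [pdb_p], [pockets_p], pockets_stage)

    # --- stage: classify (poses -> calls -> screen) -------------------------
    if config.compounds_tsv and config.poses_dir:
        comp_p = Path(config.compounds_tsv)
        poses_dir = Path(config.poses_dir)
        screen_json = out / "screen.json"
        screen_tsv = out / "screen.tsv"

        def classify_stage():
            comp = pd.read_csv(comp_p, sep="\t", comment="#")
            if config.references:
                refs = json.loads(Path(config.references).read_text())
                k79 = np.array(refs["k79_ref"], dtype=float)
                d307 = np.array(refs["d307_ref"], dtype=float)
            else:
                if structure is None:
                    raise ValueError("no references and no receptor structure")
                k79 = resolve_selector(structure, config.k79_selector)
                d307 = resolve_selector(structure, config.d307_selector)
            th = CandidacyThresholds(**config.thresholds)
            calls = []
            failures = []
            for _, row in comp.iterrows():
                cid = str(row["compound_id"])
                try:
                    topo = parse_ligand(str(row["smiles"]))
                    pose_file = poses_dir / f"{cid}.pdbqt"
                    poses = parse_poses(
                        pose_file.read_text(), topo,
                        energy_unit=config.energy_unit, compound_id=cid,
                    )
                    pwa = [(p, assign_site(p, topo, k79, d307)) for p in poses]
                    calls.append(
                        classify_candidate(
                            cid, pwa, topo, th, config.accept_borderline_tight
                        )
                    )
                except Exception as exc:
                    # quarantine this compound only
                    logger.error(
                        "stage=classify level=ERROR message=compound %s failed: %s",
                        cid, exc,
                    )
                    failures.append({"compound_id": cid, "error": str(exc)})
            report = summarize_screen(calls)
            report["config_hash"] = config.hash()
            report["seed"] = config.seed
            report["failures"] = failures
            screen_json.write_text(json.dumps(report, indent=2))
            rows = [_header(config).rstrip(),
                    "compound_id\tlabel\tenergy_class\tbest_E_kJ\tn_sites\tsymmetric\tfailed_gates"]
            for v in report["verdicts"]:
                rows.append(
                    f"{v['compound_id']}\t{v['label']}\t{v['energy_class']}\t"
                    f"{'' if v['best_energy_kj_mol'] is None else round(v['best_energy_kj_mol'], 2)}\t"
                    f"{v['n_predicted_sites']}\t{v['symmetric']}\t"
                    f"{','.join(v['failed_gates'])}"
                )
            screen_tsv.write_text("\n".join(rows) + "\n")

        inputs = [comp_p] + sorted(poses_dir.glob("*.pdbqt"))
        run_stage("classify", inputs, [screen_json, screen_tsv], classify_stage)

    worst = "ok"
    for st in manifest["stages"].values():
        if st["status"] == "failed":
            worst = "failed"
    manifest["status"] = worst
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
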
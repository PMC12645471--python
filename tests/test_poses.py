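"""Docked-pose parsing, site assignment, and degenerate-pose grouping."""

import io

import numpy as np
import pandas as pd
import pytest

from haloscope.ligand import eligible_sites, parse_ligand
from haloscope.poses import (
    KCAL_TO_KJ,
    DockedPose,
    assign_site,
    group_degenerate_poses,
    parse_poses,
)
from haloscope.synthetic import gen_pose_set, write_pdbqt


@pytest.mark.parametrize(
    "kcal,kj", [(-5.00, -20.92), (-8.50, -35.56), (-5.90, -24.69)]
)
def test_kcal_to_kj_conversion(kcal, kj):
    """The candidacy window endpoints are the kcal→kJ images at the
    printed 2-decimal precision."""
    assert round(kcal * KCAL_TO_KJ, 2) == pytest.approx(kj)


def test_energy_conversion_roundtrip():
    for e in (-35.98, -24.69, -0.001, -50.0):
        assert (e / KCAL_TO_KJ) * KCAL_TO_KJ == pytest.approx(e, rel=1e-12)


def _pdbqt_text(energy_kcal=-5.0):
    """A 7-heavy-atom (phenol-shaped) single-pose PDBQT block."""
    lines = ["MODEL 1",
             f"REMARK VINA RESULT:  {energy_kcal:9.4f}      0.000      0.000"]
    types = ["OA"] + ["A"] * 6
    for i, t in enumerate(types):
        x = 1.4 * i
        lines.append(
            f"ATOM  {i + 1:5d} {('X' + str(i + 1)):<4.4s} LIG A   1    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  0.00  0.00     0.000 {t:<2s}"
        )
    lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


def test_parse_pdbqt_remark_energy(phenol):
    poses = parse_poses(_pdbqt_text(-5.0), phenol, compound_id="x")
    assert len(poses) == 1
    assert poses[0].binding_energy == pytest.approx(-20.92)


def test_parse_kj_passthrough(phenol):
    poses = parse_poses(_pdbqt_text(-24.69), phenol,
                        energy_unit="kJ/mol", compound_id="x")
    assert poses[0].binding_energy == pytest.approx(-24.69)


def test_parse_energy_table(phenol):
    table = pd.read_csv(
        io.StringIO("compound_id\tpose_id\tenergy\tunit\nx\t1\t-6.0\tkcal/mol\n"),
        sep="\t",
    )
    text = _pdbqt_text().replace("REMARK VINA RESULT", "REMARK NO ENERGY HERE")
    poses = parse_poses(text, phenol, compound_id="x", energy_table=table)
    assert poses[0].binding_energy == pytest.approx(-25.104)


def test_atom_count_mismatch_is_fatal(phenol, benzene):
    with pytest.raises(ValueError, match="pose"):
        parse_poses(_pdbqt_text(), benzene, compound_id="x")


def test_element_mismatch_is_fatal(phenol):
    text = _pdbqt_text().replace("0.000 OA", "0.000 N ")
    with pytest.raises(ValueError, match="element"):
        parse_poses(text, phenol, compound_id="x")


def test_pdbqt_writer_roundtrip(phenol, refs):
    k79, d307 = refs
    sites = eligible_sites(phenol)
    poses, _ = gen_pose_set(phenol, [sites[0]], [-30.0], [8.0], [9.0],
                            k79, d307, seed=3)
    text = write_pdbqt(poses, phenol)
    back = parse_poses(text, phenol, compound_id="compound")
    assert back[0].binding_energy == pytest.approx(-30.0, abs=1e-3)
    assert np.allclose(back[0].coordinates, poses[0].coordinates, atol=1.5e-3)


def test_assign_site_constructed_distance(phenol, refs):
    """An eligible carbon placed 8.5 A from the K79 reference is chosen
    with exactly that distance (the scale of the para-isomer geometry)."""
    k79, d307 = refs
    sites = eligible_sites(phenol)
    target = sites[2]
    coords = np.full((phenol.n_atoms, 3), 50.0)
    coords[target] = [8.5, 0.0, 0.0]
    pose = DockedPose("c", "1", coords, -25.0)
    a = assign_site(pose, phenol, k79, d307)
    assert a.site_atom_index == target
    assert a.d_k79 == pytest.approx(8.5)


def test_assign_site_brute_force_oracle(phenol, refs):
    """Nearest-eligible-carbon selection agrees with exhaustive search."""
    k79, d307 = refs
    sites = eligible_sites(phenol)
    rng = np.random.default_rng(12)
    for _ in range(200):
        coords = rng.uniform(-15, 15, size=(phenol.n_atoms, 3))
        pose = DockedPose("c", "1", coords, -25.0)
        a = assign_site(pose, phenol, k79, d307)
        dists = [np.linalg.norm(coords[i] - k79) for i in sites]
        assert a.site_atom_index == sites[int(np.argmin(dists))]
        assert a.d_k79 == pytest.approx(min(dists))
        assert a.d_d307 == pytest.approx(
            np.linalg.norm(coords[a.site_atom_index] - d307)
        )


def test_assign_site_isometry_invariance(phenol, refs):
    k79, d307 = refs
    rng = np.random.default_rng(5)
    coords = rng.uniform(-10, 10, size=(phenol.n_atoms, 3))
    pose = DockedPose("c", "1", coords, -25.0)
    a1 = assign_site(pose, phenol, k79, d307)

    # random rigid rotation + translation applied to pose and references
    q = rng.normal(size=(3, 3))
    R, _ = np.linalg.qr(q)
    if np.linalg.det(R) < 0:
        R[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    pose2 = DockedPose("c", "1", coords @ R.T + t, -25.0)
    a2 = assign_site(pose2, phenol, R @ k79 + t, R @ d307 + t)
    assert a2.site_atom_index == a1.site_atom_index
    assert a2.d_k79 == pytest.approx(a1.d_k79, abs=1e-9)
    assert a2.d_d307 == pytest.approx(a1.d_d307, abs=1e-9)


def test_assign_site_no_eligible_site(refs):
    k79, d307 = refs
    topo = parse_ligand("OC1CCCCC1")
    pose = DockedPose("c", "1", np.zeros((topo.n_atoms, 3)), -25.0)
    assert assign_site(pose, topo, k79, d307) is None


def _pose_at(topology, site, energy, d, k79, d307, seed):
    poses, _ = gen_pose_set(topology, [site], [energy], [d], [d + 0.5],
                            k79, d307, seed=seed)
    return poses[0]


def test_group_degenerate_retains_near_degenerate_pair(phenol, refs):
    """Two orientations 2.10 kJ/mol apart at distinct sites are both kept:
    the two-regioisomer situation."""
    k79, d307 = refs
    sites = eligible_sites(phenol)
    # distinct symmetry classes: meta vs para positions
    s_ortho, s_para = sites[0], sites[2]
    assert phenol.symmetry_class[s_ortho] != phenol.symmetry_class[s_para]
    p1 = _pose_at(phenol, s_ortho, -24.69, 10.2, k79, d307, 1)
    p2 = _pose_at(phenol, s_para, -22.59, 8.5, k79, d307, 2)
    pwa = [(p, assign_site(p, phenol, k79, d307)) for p in (p1, p2)]
    kept = group_degenerate_poses(pwa, delta_e_tol=2.5)
    assert len(kept) == 2
    # sorted by energy: best first
    assert kept[0][0].binding_energy == pytest.approx(-24.69)


def test_group_collapses_same_symmetry_class(phenol, refs):
    k79, d307 = refs
    sites = eligible_sites(phenol)
    cls = phenol.symmetry_class
    pair = [(i, j) for i in sites for j in sites if i < j and cls[i] == cls[j]][0]
    p1 = _pose_at(phenol, pair[0], -30.0, 8.0, k79, d307, 1)
    p2 = _pose_at(phenol, pair[1], -29.0, 8.0, k79, d307, 2)
    pwa = [(p, assign_site(p, phenol, k79, d307)) for p in (p1, p2)]
    kept = group_degenerate_poses(pwa, delta_e_tol=2.5)
    assert len(kept) == 1
    assert kept[0][0].binding_energy == pytest.approx(-30.0)


def test_group_tolerance_zero_keeps_best_only(phenol, refs):
    k79, d307 = refs
    sites = eligible_sites(phenol)
    p1 = _pose_at(phenol, sites[0], -24.69, 10.2, k79, d307, 1)
    p2 = _pose_at(phenol, sites[2], -22.59, 8.5, k79, d307, 2)
    pwa = [(p, assign_site(p, phenol, k79, d307)) for p in (p1, p2)]
    kept = group_degenerate_poses(pwa, delta_e_tol=0.0)
    assert len(kept) == 1
    assert kept[0][1].site_atom_index == sites[0]
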
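"""Energy-window classification, candidacy gates, regiochemistry calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haloscope.classify import (
    BORDERLINE_TIGHT,
    OPTIMAL,
    TOO_TIGHT,
    TOO_WEAK,
    CandidacyThresholds,
    classify_candidate,
    classify_energy,
    predict_regiochemistry,
    summarize_screen,
)
from haloscope.ligand import eligible_sites
from haloscope.poses import assign_site
from haloscope.synthetic import gen_pose_set


@pytest.mark.parametrize(
    "e,expected",
    [
        (-24.69, OPTIMAL),
        (-31.80, OPTIMAL),
        (-35.98, BORDERLINE_TIGHT),
        (-20.92, OPTIMAL),   # boundaries inclusive
        (-35.56, OPTIMAL),
        (-15.0, TOO_WEAK),
        (-22.59, OPTIMAL),
        (-36.6, TOO_TIGHT),
        (-50.0, TOO_TIGHT),
    ],
)
def test_energy_window_worked_examples(e, expected):
    assert classify_energy(e) == expected


def test_energy_class_sweep_is_monotone():
    """From −50 to 0 kJ/mol the class sequence visits each class once."""
    sweep = [classify_energy(e) for e in np.arange(-50, 0, 0.01)]
    order = [TOO_TIGHT, BORDERLINE_TIGHT, OPTIMAL, TOO_WEAK]
    transitions = [s for i, s in enumerate(sweep) if i == 0 or s != sweep[i - 1]]
    assert transitions == order


@settings(deadline=None, derandomize=True)
@given(e=st.floats(min_value=-60, max_value=-0.01))
def test_energy_class_total(e):
    assert classify_energy(e) in {TOO_TIGHT, BORDERLINE_TIGHT, OPTIMAL, TOO_WEAK}


def test_threshold_validation():
    with pytest.raises(ValueError):
        CandidacyThresholds(e_weak=-35.56, e_tight=-20.92)
    with pytest.raises(ValueError):
        CandidacyThresholds(d307_max=-1.0)


def test_threshold_files(tmp_path):
    p = tmp_path / "t.json"
    p.write_text('{"e_weak": -19.0, "d307_max": 10.0}')
    th = CandidacyThresholds.from_file(str(p))
    assert th.e_weak == -19.0 and th.d307_max == 10.0
    q = tmp_path / "t.cfg"
    q.write_text("e_weak = -19.0\nd307_max = 10.0  # gate\n")
    assert CandidacyThresholds.from_file(str(q)) == th
    bad = tmp_path / "bad.json"
    bad.write_text('{"nonsense": 1}')
    with pytest.raises(ValueError):
        CandidacyThresholds.from_file(str(bad))


def _one_compound(topology, refs, energy, d_d307, d_k79=8.0, site_rank=0, seed=0):
    k79, d307 = refs
    sites = eligible_sites(topology)
    poses, _ = gen_pose_set(
        topology, [sites[site_rank]], [energy], [d_k79], [d_d307],
        k79, d307, seed=seed,
    )
    return [(p, assign_site(p, topology, k79, d307)) for p in poses]


def test_substrate_call_in_window_in_range(phenol, refs):
    pwa = _one_compound(phenol, refs, -31.80, 9.0)
    call = classify_candidate("c5", pwa, phenol)
    assert call.label == "substrate"
    assert call.energy_class == OPTIMAL
    assert call.failed_gates == []
    assert len(call.predicted_sites) == 1


def test_d307_gate_rejects(phenol, refs):
    pwa = _one_compound(phenol, refs, -24.69, 12.5, d_k79=8.0)
    call = classify_candidate("x", pwa, phenol)
    assert call.label == "non_substrate"
    assert call.failed_gates == ["G2_d307_distance"]


def test_borderline_tight_accepted_by_default(phenol, refs):
    """The best-performing known substrate sits just past the tight bound;
    default policy keeps it."""
    pwa = _one_compound(phenol, refs, -35.98, 9.0, d_k79=7.8)
    call = classify_candidate("chrysin", pwa, phenol)
    assert call.label == "substrate"
    assert call.energy_class == BORDERLINE_TIGHT
    strict = classify_candidate("chrysin", pwa, phenol,
                                accept_borderline_tight=False)
    assert strict.label == "non_substrate"
    assert "G1_energy_window" in strict.failed_gates


def test_no_site_compound(refs):
    from haloscope.ligand import parse_ligand

    topo = parse_ligand("Cc1c(C)c(C)c(C)c(C)c1C")
    call = classify_candidate("hmb", [], topo)
    assert call.label == "non_substrate"
    assert call.reason == "no_site"


def test_no_pose_compound(phenol):
    call = classify_candidate("empty", [], phenol)
    assert call.label == "non_substrate"
    assert call.reason == "no_pose"


def test_window_shrink_never_creates_substrates(phenol, refs):
    """Raising e_tight toward e_weak can only lose substrates."""
    energies = np.linspace(-45, -15, 13)
    wide = CandidacyThresholds()
    narrow = CandidacyThresholds(e_tight=-30.0, tight_tolerance=0.0)
    for i, e in enumerate(energies):
        pwa = _one_compound(phenol, refs, float(e), 9.0, seed=i)
        lab_wide = classify_candidate("c", pwa, phenol, wide).label
        lab_narrow = classify_candidate("c", pwa, phenol, narrow).label
        if lab_narrow == "substrate":
            assert lab_wide == "substrate"


def test_predicted_sites_respect_gates(phenol, refs):
    th = CandidacyThresholds()
    pwa = _one_compound(phenol, refs, -30.0, 10.0)
    call = classify_candidate("c", pwa, phenol, th)
    elig = set(eligible_sites(phenol))
    for s in call.predicted_sites:
        assert s.atom_index in elig
        assert s.d_d307 <= th.d307_max


def test_regiochemistry_two_isomers(phenol, refs):
    k79, d307 = refs
    sites = eligible_sites(phenol)
    poses, _ = gen_pose_set(
        phenol, [sites[0], sites[2]], [-24.69, -22.59],
        [10.2, 8.5], [9.0, 9.5], k79, d307, seed=0,
    )
    pwa = [(p, assign_site(p, phenol, k79, d307)) for p in poses]
    call = classify_candidate("c7", pwa, phenol)
    assert call.label == "substrate"
    report = predict_regiochemistry(call, phenol)
    assert len(report) == 2  # regioisomer mixture predicted


def test_regiochemistry_symmetric_single_product(dihydroxybenzophenone, refs):
    topo = dihydroxybenzophenone
    pwa = _one_compound(topo, refs, -31.80, 9.0)
    call = classify_candidate("c5", pwa, topo)
    assert call.label == "substrate"
    assert call.symmetric
    report = predict_regiochemistry(call, topo)
    assert len(report) == 1
    assert report[0]["symmetric"]
    assert len(report[0]["atom_indices"]) >= 2


def test_regiochemistry_rejected_for_non_substrate(phenol, refs):
    pwa = _one_compound(phenol, refs, -10.0, 9.0)
    call = classify_candidate("c", pwa, phenol)
    with pytest.raises(ValueError):
        predict_regiochemistry(call, phenol)


def test_summarize_counts_partition(phenol, refs):
    calls = []
    for i, (e, dd) in enumerate([(-30, 9), (-15, 9), (-40, 9), (-25, 13)]):
        pwa = _one_compound(phenol, refs, float(e), float(dd), seed=i)
        calls.append(classify_candidate(f"c{i}", pwa, phenol))
    rep = summarize_screen(calls)
    assert rep["n_compounds"] == 4
    assert sum(rep["by_label"].values()) == 4
    assert rep["n_substrates"] == 1
    assert [v["compound_id"] for v in rep["verdicts"]] == sorted(
        c.compound_id for c in calls
    )


def test_summarize_rejects_duplicates(phenol, refs):
    pwa = _one_compound(phenol, refs, -30.0, 9.0)
    call = classify_candidate("dup", pwa, phenol)
    with pytest.raises(ValueError):
        summarize_screen([call, call])
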
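"""Amalgamation, NCS assembly detection, prediction and completion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import truths_and_models
from mrpilot.analysis import (KnownAssembly, _orbit_slots, amalgamate,
                              assemblies_as_models, complete_known_assembly,
                              detect_assemblies, predict_missing,
                              update_ncs)
from mrpilot.symmetry import (Placement, UnitCell, build_space_group,
                              rotation_angle_between,
                              rotation_from_angle_axis)

CELL = UnitCell(60, 60, 60)
P1 = build_space_group("P1")


def _orbit(group, rng, n_members=None, axis=(0, 0, 1.0),
           center=(30.0, 30, 30), radius=14.0):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    base = Rotation.random(random_state=rng).as_matrix()
    seedp = Placement("A", "m", base, center + radius * np.array([1.0, 0, 0]))
    slots, _ = _orbit_slots(seedp, axis, center, group)
    return slots[:n_members] if n_members else slots


# -- detection ---------------------------------------------------------------

@pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
def test_cyclic_detection_exact(n):
    rng = np.random.default_rng(n)
    axis = rng.normal(size=3)
    pls = _orbit(f"C{n}", rng, axis=axis)
    hyps = detect_assemblies(pls, CELL, sg=P1)
    assert len(hyps) == 1
    h = hyps[0]
    assert h.group_label == f"C{n}"
    assert sorted(h.member_indices) == list(range(n))
    cosang = abs(float(np.asarray(h.axis)
                       @ (axis / np.linalg.norm(axis))))
    assert np.degrees(np.arccos(min(1.0, cosang))) < 1.0


def test_dihedral_absorbs_subgroups():
    rng = np.random.default_rng(10)
    pls = _orbit("D2", rng)
    hyps = detect_assemblies(pls, CELL, sg=P1)
    assert [h.group_label for h in hyps] == ["D2"]
    assert len(hyps[0].member_indices) == 4


def test_generic_screw_rejected():
    p1 = Placement("A", "m", np.eye(3), np.array([10.0, 10, 10]))
    R = rotation_from_angle_axis(100.0, [0, 0, 1.0])
    p2 = Placement("A", "m", R, R @ p1.trans + np.array([0, 0, 8.0]))
    assert detect_assemblies([p1, p2], CELL, sg=P1) == []


def test_detection_tolerates_small_noise():
    rng = np.random.default_rng(11)
    pls = _orbit("C5", rng)
    noisy = [Placement("A", "m",
                       p.rot @ Rotation.from_rotvec(
                           np.radians(rng.normal(0, 1.0, 3))).as_matrix(),
                       p.trans + rng.normal(0, 0.3, 3)) for p in pls]
    hyps = detect_assemblies(noisy, CELL, sg=P1)
    assert any(h.group_label == "C5" and len(h.member_indices) == 5
               for h in hyps)


# -- prediction --------------------------------------------------------------

def test_predict_missing_counts():
    rng = np.random.default_rng(12)
    full = _orbit("C5", rng)
    partial = [full[0], full[2], full[3], full[4]]
    hyps = detect_assemblies(partial, CELL, sg=P1)
    assert hyps and hyps[0].group_label == "C5"
    preds = predict_missing(hyps[0], partial, P1, CELL)
    assert len(preds) == 1
    d = np.linalg.norm(preds[0].placement.trans - full[1].trans)
    assert d < 0.5

    hyps_full = detect_assemblies(full, CELL, sg=P1)
    assert predict_missing(hyps_full[0], full, P1, CELL) == []


# -- NCS refresh -------------------------------------------------------------

def test_update_ncs_stable_and_demotion():
    rng = np.random.default_rng(13)
    pls = _orbit("C4", rng)
    hyps = detect_assemblies(pls, CELL, sg=P1)
    same = update_ncs(pls, hyps, CELL, sg=P1)
    assert len(same) == 1
    assert np.allclose(same[0].axis, hyps[0].axis, atol=1e-9)

    # gently perturbed members: the refreshed axis stays close
    moved = [Placement("A", "m", p.rot, p.trans + rng.normal(0, 0.3, 3))
             for p in pls]
    fresh = update_ncs(moved, hyps, CELL, sg=P1)
    assert fresh
    cosang = abs(float(np.asarray(fresh[0].axis) @ np.asarray(hyps[0].axis)))
    assert np.degrees(np.arccos(min(1.0, cosang))) < 5.0

    # one member refined far away: the hypothesis is demoted
    broken = list(pls)
    broken[2] = broken[2].shifted(np.array([10.0, 0, 0]))
    assert update_ncs(broken, hyps, CELL, sg=P1) == []


# -- amalgamation ------------------------------------------------------------

def test_amalgamate_with_common_parent_is_union():
    rng = np.random.default_rng(14)
    parent = [Placement("A", "m",
                        Rotation.random(random_state=rng).as_matrix(),
                        rng.uniform(0, 20, 3))]
    a = [Placement("A", "m", np.eye(3), np.array([5.0, 5, 5]))]
    b = [Placement("A", "m", np.eye(3), np.array([15.0, 15, 15]))]
    sg = build_space_group("P212121")
    cands = amalgamate(parent, a, b, sg, CELL)
    assert len(cands) == 1
    assert len(cands[0].placements) == 2
    assert not cands[0].needs_translation_search


def test_amalgamate_empty_parent_nonpolar_tries_all_shifts():
    sg = build_space_group("P212121")
    a = [Placement("A", "m", np.eye(3), np.array([5.0, 5, 5]))]
    b = [Placement("A", "m", np.eye(3), np.array([15.0, 15, 15]))]
    cands = amalgamate([], a, b, sg, CELL)
    assert len(cands) == len(sg.origin_shifts) == 8
    # the shift variants move B's addition by each discrete origin shift
    deltas = {tuple(np.round(c.placements[1].trans - b[0].trans, 6))
              for c in cands}
    expected = {tuple(np.round(CELL.orth @ np.asarray(s), 6))
                for s in sg.origin_shifts}
    assert deltas == expected


def test_amalgamate_empty_parent_polar_reuses_rotation_only():
    sg = build_space_group("P21")
    a = [Placement("A", "m", np.eye(3), np.array([5.0, 5, 5]))]
    brot = rotation_from_angle_axis(30.0, [1, 0, 0])
    b = [Placement("A", "m", brot, np.array([15.0, 15, 15]))]
    cands = amalgamate([], a, b, sg, CELL)
    assert len(cands) == 1
    c = cands[0]
    assert c.needs_translation_search
    assert c.placements == tuple(a)           # only A's additions kept
    assert np.allclose(np.array(c.orientation_only[0]).reshape(3, 3), brot)


def test_amalgamate_origin_shift_recovery(small_crystal):
    """A sibling expressed in a shifted origin frame is recovered."""
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    sg, cell = cry.sg, cry.cell
    shift = cell.orth @ np.asarray(sg.origin_shifts[5])
    b_shifted = [pls[1].shifted(shift)]       # B solved in another origin
    cands = amalgamate([], [pls[0]], b_shifted, sg, cell)
    best = None
    for c in cands:
        passes, _n = cry.packing_check(list(c.placements), models)
        if not passes:
            continue
        rep = cry.score(list(c.placements), models)
        if best is None or rep.llg > best[0]:
            best = (rep.llg, c)
    assert best is not None
    both = cry.score(pls, models).llg
    assert best[0] == pytest.approx(both, rel=1e-6)


# -- known assemblies --------------------------------------------------------

def test_known_assembly_completion(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    # describe the true pair as a user assembly, anchored on copy 1;
    # member transforms live in the assembly (member-1) frame
    R_rel = pls[0].rot.T @ pls[1].rot
    t_rel = pls[0].rot.T @ (pls[1].trans - pls[0].trans)
    ka = KnownAssembly(name="pair", members=(
        ("A", tuple(np.eye(3).ravel()), (0.0, 0.0, 0.0)),
        ("A", tuple(R_rel.ravel()), tuple(t_rel)),
    ))
    preds = complete_known_assembly(ka, [pls[0]], [models[0]], cry)
    assert len(preds) == 1
    d = np.linalg.norm(preds[0].placement.trans - pls[1].trans)
    assert d < 1.0


def test_known_assembly_local_search_recovers_offset(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    R_rel = pls[0].rot.T @ pls[1].rot
    t_rel = pls[0].rot.T @ (pls[1].trans + np.array([3.0, 0.0, 0.0])
                            - pls[0].trans)
    ka = KnownAssembly(name="off", members=(
        ("A", tuple(np.eye(3).ravel()), (0.0, 0.0, 0.0)),
        ("A", tuple(R_rel.ravel()), tuple(t_rel)),
    ))
    preds = complete_known_assembly(ka, [pls[0]], [models[0]], cry)
    assert len(preds) == 1
    d = np.linalg.norm(preds[0].placement.trans - pls[1].trans)
    assert d < 1.5                     # the 3 A user error is recovered


def test_known_assembly_without_anchor():
    ka = KnownAssembly(name="x", members=(
        ("B", tuple(np.eye(3).ravel()), (0.0, 0.0, 0.0)),))

    class _B:
        sg = P1
        cell = CELL
    assert complete_known_assembly(ka, [], [], _B()) == []


# -- composite search models -------------------------------------------------

def test_composite_model_expansion(small_crystal):
    rng = np.random.default_rng(15)
    pls = _orbit("C5", rng)
    hyps = detect_assemblies(pls, CELL, sg=P1)

    class _M:
        def __init__(self, i):
            self.model_id = f"m{i}"
            self.component_id = "A"
            self.coords = np.zeros((4, 3))
            self.resids = np.arange(4)
            self.weight = 100.0
            self.source_template_id = "t"

        def __len__(self):
            return 4

    models = [_M(i) for i in range(5)]
    comp = assemblies_as_models(hyps[0], pls, models)
    assert len(comp.composite_members) == 5
    assert comp.weight == pytest.approx(500.0)
    # placing the composite at member 0's own pose reproduces the orbit
    expanded = comp.expand(pls[0])
    for e, p in zip(expanded, [pls[i] for i in hyps[0].member_indices]):
        assert rotation_angle_between(e.rot, p.rot) < 1e-4
        assert np.linalg.norm(e.trans - p.trans) < 1e-6
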
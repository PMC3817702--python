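"""Synthetic crystals and the mock scoring backend."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import truths_and_models
from mrpilot.composition import MATTHEWS_PROTEIN_CONST
from mrpilot.symmetry import (Placement, apply_symop, build_space_group,
                              rotation_angle_between,
                              rotation_from_angle_axis)
from mrpilot.toycrystal import (ComponentGen, GenSpec, GenerationError,
                                compact_chain, generate_crystal,
                                make_model_variants, so3_grid, truth_models)


# -- generation --------------------------------------------------------------

def test_generated_solvent_close_to_target(small_crystal):
    cry = small_crystal.crystal
    mass = sum(cry.weights[c] for c, _p in cry.truths)
    vm = cry.cell.volume / (cry.sg.n_ops * mass)
    solvent = 1.0 - MATTHEWS_PROTEIN_CONST / vm
    assert solvent == pytest.approx(0.5, abs=0.02)


def test_generated_truths_pack(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    passes, _n = cry.packing_check(pls, models)
    assert passes


def test_assembly_orbit_exactness():
    gs = GenSpec(components=(ComponentGen("A", 16, 5, assembly="C5",
                                          assembly_axis=(0, 0, 1)),),
                 space_group="P1", epsilon=0.0)
    case = generate_crystal(gs, seed=2)
    pls = [p for _c, p in case.crystal.truths]
    assert len(pls) == 5
    # consecutive members are exact 72 degree rotations of each other
    for i in range(5):
        j = (i + 1) % 5
        rel = pls[j].rot @ pls[i].rot.T
        angle = rotation_angle_between(np.eye(3), rel)
        assert angle == pytest.approx(72.0, abs=1e-6)


def test_orbit_size_mismatch_rejected():
    gs = GenSpec(components=(ComponentGen("A", 16, 4, assembly="C5"),),
                 space_group="P1")
    with pytest.raises(GenerationError):
        generate_crystal(gs, seed=0)


def test_compact_chain_geometry():
    rng = np.random.default_rng(0)
    pts = compact_chain(30, rng)
    bonds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    assert np.allclose(bonds, 3.8, atol=1e-9)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, 10.0)
    assert d.min() >= 3.4 - 1e-9


def test_make_model_variants(small_crystal):
    tmpl = small_crystal.templates["A"]
    variants = make_model_variants(tmpl, 13, noise=0.5, seed=1)
    assert len(variants) == 13
    assert len({m.source_template_id for m in variants}) == 1
    assert len({m.model_id for m in variants}) == 13
    assert all(m.coverage == tmpl.coverage for m in variants)

    frozen = make_model_variants(tmpl, 2, noise=0.0, seed=1)
    assert np.allclose(frozen[0].coords, tmpl.coords)

    a = make_model_variants(tmpl, 2, noise=0.5, seed=1)
    b = make_model_variants(tmpl, 2, noise=0.5, seed=2)
    assert not np.allclose(a[0].coords, b[0].coords)
    assert a[0].coverage == b[0].coverage


# -- the mock LLG ------------------------------------------------------------

def test_empty_solution_scores_zero(small_crystal):
    rep = small_crystal.crystal.score([], [])
    assert rep.llg == 0.0 and rep.clash_count == 0


def test_exact_truth_scores_weight(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    rep = cry.score([pls[0]], [models[0]])
    assert rep.per_placement_overlap[0] == pytest.approx(1.0, abs=1e-9)
    assert rep.llg == pytest.approx(cry.weights["A"], rel=1e-9)


@pytest.mark.parametrize("op_index,shift_index", [(1, 0), (2, 3), (3, 7)])
def test_score_invariance_global_op_and_origin(small_crystal, op_index,
                                               shift_index):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    base = cry.score(pls, models).llg
    op = cry.sg.ops[op_index]
    dt = cry.cell.orth @ np.asarray(cry.sg.origin_shifts[shift_index])
    moved = [apply_symop(p, op, cry.cell).shifted(dt) for p in pls]
    assert cry.score(moved, models).llg == pytest.approx(base, rel=1e-6)


def test_score_not_invariant_under_independent_moves(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    base = cry.score(pls, models).llg
    moved = [pls[0], pls[1].shifted(np.array([6.0, -4.0, 5.0]))]
    assert cry.score(moved, models).llg < base - 0.2 * cry.weights["A"]


def test_comparable_score_contract(small_crystal):
    """Uniformly closer placements never score lower (noiseless)."""
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    offsets = [4.0, 2.0, 1.0, 0.5, 0.0]
    direction = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    scores = []
    for off in offsets:
        p = pls[0].shifted(off * direction)
        scores.append(cry.score([p], [models[0]]).llg)
    assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))


def test_score_determinism(noisy_crystal):
    cry = noisy_crystal.crystal
    pls, models = truths_and_models(noisy_crystal)
    a = cry.score(pls, models)
    b = cry.score(pls, models)
    assert a.llg == b.llg            # bit-for-bit
    assert a.per_placement_overlap == b.per_placement_overlap


def test_noise_is_keyed_on_pose_bins(noisy_crystal):
    cry = noisy_crystal.crystal
    pls, models = truths_and_models(noisy_crystal)
    base = cry.score([pls[0]], [models[0]]).llg
    # a sub-bin nudge (0.05 A) stays in the same noise bin
    nudged = cry.score([pls[0].shifted(np.array([0.05, 0, 0]))],
                       [models[0]]).llg
    noiseless = small = None
    assert abs(nudged - base) < 0.05 * cry.weights["A"]


# -- rotation search ---------------------------------------------------------

def test_so3_grid_size_scales_with_step():
    assert len(so3_grid(15.0)) > len(so3_grid(30.0))
    q = so3_grid(20.0)
    assert np.allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)


def test_rotation_search_finds_truth_orientation(small_crystal):
    cry = small_crystal.crystal
    pls, _models = truths_and_models(small_crystal)
    tmpl = small_crystal.templates["A"]
    top = cry.rotation_search(tmpl, n_keep=5)
    best_angle = min(
        rotation_angle_between(top[0][0], Rh @ p.rot)
        for _c, p in cry.truths
        for Rh, _t in cry.sg.ops_orth(cry.cell))
    assert best_angle <= 15.0        # within one grid step
    assert len(cry.rotation_search(tmpl, n_keep=1)) == 1


def test_rotation_search_flat_when_no_truths_left(noisy_crystal):
    cry = noisy_crystal.crystal
    pls, models = truths_and_models(noisy_crystal)
    tmpl = noisy_crystal.templates["A"]
    # both truths matched: the landscape is pure noise
    top = cry.rotation_search(tmpl, pls, models)
    assert top[0][1] < 6.0


# -- translation search ------------------------------------------------------

def test_translation_peak_on_truth(small_crystal):
    cry = small_crystal.crystal
    pls, _models = truths_and_models(small_crystal)
    tmpl = small_crystal.templates["A"]
    peaks = cry.translation_search(tmpl, pls[0].rot, grid_step=2.0)
    best = peaks[0]
    dmin = min(np.linalg.norm(best.placement.trans - p.trans)
               for _c, p in cry.truths)
    assert dmin <= 2.0
    others = [p.tfz for p in peaks[1:]]
    assert best.tfz > 7.0
    assert not others or best.tfz > max(others)


def test_translation_landscape_flat_without_truths(noisy_crystal):
    cry = noisy_crystal.crystal
    pls, models = truths_and_models(noisy_crystal)
    tmpl = noisy_crystal.templates["A"]
    peaks = cry.translation_search(tmpl, pls[0].rot, pls, models,
                                   grid_step=2.5)
    assert max(p.tfz for p in peaks) < 5.5


# -- packing -----------------------------------------------------------------

def test_packing_single_and_coincident(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    passes, n = cry.packing_check([pls[0]], [models[0]])
    assert passes and n == 0
    passes, n = cry.packing_check([pls[0], pls[0]], [models[0], models[0]])
    assert not passes and n > 0


# -- rigid refinement --------------------------------------------------------

def test_refine_leaves_truth_in_place(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    refined, rep, warn = cry.rigid_refine([pls[0]], [models[0]])
    assert np.linalg.norm(refined[0].trans - pls[0].trans) < 1e-2
    assert rotation_angle_between(refined[0].rot, pls[0].rot) < 0.1


def test_refine_recovers_perturbed_truth(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    pert = Placement("A", models[0].model_id,
                     pls[0].rot @ rotation_from_angle_axis(5.0, [0, 0, 1]),
                     pls[0].trans + np.array([1.5, 0.8, -0.7]))
    refined, rep, warn = cry.rigid_refine([pert], [models[0]])
    assert np.linalg.norm(refined[0].trans - pls[0].trans) < 0.2
    assert rotation_angle_between(refined[0].rot, pls[0].rot) < 1.0


def test_refine_scope_last_keeps_first_placement(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    pert = pls[1].shifted(np.array([1.0, 0.5, 0.0]))
    refined, _rep, _w = cry.rigid_refine([pls[0], pert], models,
                                         scope="last")
    assert np.allclose(refined[0].trans, pls[0].trans)
    assert np.allclose(refined[0].rot, pls[0].rot)
    assert np.linalg.norm(refined[1].trans - pls[1].trans) < 0.3


# -- background z-score ------------------------------------------------------

def test_background_z_high_on_truth(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    z = cry.background_zscore([], [], [pls[0]], [models[0]], seed=1)
    assert z > 7.0


def test_background_z_low_for_random_pose(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    rng = np.random.default_rng(9)
    rand = Placement("A", models[0].model_id,
                     Rotation.random(random_state=rng).as_matrix(),
                     cry.cell.orth @ rng.random(3))
    z = cry.background_zscore([], [], [rand], [models[0]], seed=1)
    assert abs(z) < 4.0


def test_background_z_sample_floor(small_crystal):
    cry = small_crystal.crystal
    pls, models = truths_and_models(small_crystal)
    with pytest.raises(ValueError):
        cry.background_zscore([], [], [pls[0]], [models[0]], n_samples=20)


# -- enantiomorph sensitivity ------------------------------------------------

def test_wrong_enantiomorph_scores_lower():
    gs = GenSpec(components=(ComponentGen("A", 24, 1),),
                 space_group="P41", epsilon=0.0)
    case = generate_crystal(gs, seed=6)
    cry = case.crystal
    pls, models = truths_and_models(case)
    right = cry.score(pls, models, "P41").llg
    wrong = cry.score(pls, models, "P43").llg
    assert right == pytest.approx(cry.weights["A"], rel=1e-5)
    assert wrong < 0.6 * right
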
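"""Space-group machinery, superposition and spatial equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mrpilot.symmetry import (DegenerateSuperpositionError, Placement,
                              UnitCell, UnsupportedSpaceGroupError,
                              allowed_origin_moves, apply_symop,
                              build_space_group, kabsch_superpose,
                              min_image_distance, orthogonalization_matrix,
                              rotation_angle_axis, rotation_angle_between,
                              rotation_from_angle_axis, spatially_equivalent)

ALL_GROUPS = ["P1", "P21", "C2", "P212121", "P21212", "P41", "P43"]


# -- catalogue ---------------------------------------------------------------

@pytest.mark.parametrize("symbol,n_ops,polar,n_shifts,enant", [
    ("P1", 1, (True, True, True), 1, None),
    ("P21", 2, (False, True, False), 4, None),
    ("C2", 4, (False, True, False), 2, None),
    ("P212121", 4, (False, False, False), 8, None),
    ("P21212", 4, (False, False, False), 8, None),
    ("P41", 4, (False, False, True), 2, "P43"),
    ("P43", 4, (False, False, True), 2, "P41"),
])
def test_catalogue_tables(symbol, n_ops, polar, n_shifts, enant):
    sg = build_space_group(symbol)
    assert sg.n_ops == n_ops
    assert sg.polar_axes == polar
    assert len(sg.origin_shifts) == n_shifts
    assert sg.enantiomorph == enant
    assert sg.ops[0].is_identity


@pytest.mark.parametrize("spelling", ["P 21 21 21", "P212121", "P2₁"
                                      "2₁2₁", "p21 21 21"])
def test_symbol_spellings(spelling):
    assert build_space_group(spelling).symbol == "P212121"


def test_unsupported_symbol_rejected():
    with pytest.raises(UnsupportedSpaceGroupError):
        build_space_group("X9")
    with pytest.raises(UnsupportedSpaceGroupError):
        build_space_group("P6122")


@pytest.mark.parametrize("symbol", ALL_GROUPS)
def test_group_closure(symbol):
    """Composing any two catalogue operators stays in the group."""
    sg = build_space_group(symbol)
    keys = {op.key() for op in sg.ops}
    for a in sg.ops:
        assert abs(np.linalg.det(a.rot) - 1) < 1e-9
        for b in sg.ops:
            assert a.compose(b).key() in keys


@pytest.mark.parametrize("symbol", ALL_GROUPS)
def test_origin_moves_conjugate_group_onto_itself(symbol):
    """Every returned origin move maps each operator onto a group op."""
    sg = build_space_group(symbol)
    shifts, polar = allowed_origin_moves(sg)
    lattice = sg.lattice_translations
    eye = np.eye(3)
    probes = list(shifts)
    for axis in range(3):
        if polar[axis]:
            v = np.zeros(3)
            v[axis] = 0.237  # arbitrary continuous move along a polar axis
            probes.append(v)
    for s in probes:
        for op in sg.ops:
            delta = (eye - op.rot) @ s
            ok = any(np.allclose(delta - lat - np.round(delta - lat), 0,
                                 atol=1e-9) for lat in lattice)
            assert ok, (symbol, s, op.key())


# -- orthogonalization -------------------------------------------------------

def test_orthogonal_cell_matrix_is_diagonal():
    m = orthogonalization_matrix(UnitCell(10, 10, 10))
    assert np.allclose(m, np.diag([10.0, 10.0, 10.0]))
    frac = np.array([0.5, 0.5, 0.5])
    assert np.allclose(m @ frac, [5.0, 5.0, 5.0])


def test_monoclinic_orthogonalization_closed_form():
    a, b, c, beta = 10.0, 12.0, 14.0, 105.0
    m = orthogonalization_matrix(UnitCell(a, b, c, 90.0, beta, 90.0))
    cb = np.cos(np.radians(beta))
    expected = np.array([[a, 0.0, c * cb],
                         [0.0, b, 0.0],
                         [0.0, 0.0, c * np.sqrt(1 - cb * cb)]])
    assert np.allclose(m, expected, atol=1e-9)


def test_degenerate_cell_rejected():
    with pytest.raises(ValueError):
        UnitCell(10, 10, 0.0)
    with pytest.raises(ValueError):
        UnitCell(10, 10, 10, 180.0, 90, 90)


# -- operator application ----------------------------------------------------

def _random_placement(rng, comp="A"):
    return Placement(comp, "m",
                     Rotation.random(random_state=rng).as_matrix(),
                     rng.uniform(0, 30, 3))


def test_identity_op_returns_placement_unchanged():
    rng = np.random.default_rng(0)
    cell = UnitCell(30, 35, 40)
    sg = build_space_group("P212121")
    p = _random_placement(rng)
    q = apply_symop(p, sg.ops[0], cell)
    assert np.allclose(q.rot, p.rot) and np.allclose(q.trans, p.trans)


def test_screw_applied_twice_is_lattice_translation():
    """The 2_1 screw composed with itself translates by one b vector."""
    cell = UnitCell(20, 26, 32)
    sg = build_space_group("P21")
    screw = next(op for op in sg.ops if not op.is_identity)
    rng = np.random.default_rng(1)
    p = _random_placement(rng)
    q = apply_symop(apply_symop(p, screw, cell), screw, cell)
    assert np.allclose(q.rot, p.rot, atol=1e-9)
    assert np.allclose(q.trans, p.trans + cell.orth @ [0, 1, 0], atol=1e-9)


def test_op_composition_equals_sequential_application():
    cell = UnitCell(20, 26, 32)
    sg = build_space_group("P212121")
    rng = np.random.default_rng(2)
    p = _random_placement(rng)
    op1, op2 = sg.ops[1], sg.ops[2]
    seq = apply_symop(apply_symop(p, op1, cell), op2, cell)
    combined = op2.compose(op1)
    one = apply_symop(p, combined, cell)
    assert rotation_angle_between(seq.rot, one.rot) < 1e-6
    assert min_image_distance(seq.trans - one.trans, cell, sg) < 1e-6


# -- Kabsch superposition ----------------------------------------------------

def test_kabsch_identity_and_exact_rotation():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(10, 3))
    rot, trans, rmsd = kabsch_superpose(A, A)
    assert rmsd < 1e-12 and np.allclose(rot, np.eye(3), atol=1e-9)

    Rz = rotation_from_angle_axis(90.0, [0, 0, 1])
    B = A @ Rz  # = Rz.T applied to rows -> recover Rz
    rot, trans, rmsd = kabsch_superpose(A, B)
    assert rmsd < 1e-9
    assert rotation_angle_between(rot, Rz) < 1e-6


def test_kabsch_recovery_property():
    """Noiseless transforms are recovered to machine precision."""
    rng = np.random.default_rng(4)
    for _ in range(1000):
        A = rng.normal(size=(6, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-50, 50, 3)
        B = (A - t) @ R  # so that R @ B + t = A
        rot, trans, rmsd = kabsch_superpose(A, B)
        assert np.radians(rotation_angle_between(rot, R)) < 1e-6
        assert np.linalg.norm(trans - t) < 1e-6
        assert rmsd < 1e-9


def test_kabsch_noisy_recovery():
    rng = np.random.default_rng(5)
    A = rng.normal(scale=8.0, size=(10, 3))
    R = Rotation.random(random_state=rng).as_matrix()
    t = np.array([3.0, -2.0, 7.0])
    B = (A - t) @ R + 0.0
    noise = 0.1 * rng.normal(size=A.shape)
    rot, trans, rmsd = kabsch_superpose(A + noise, B)
    assert rotation_angle_between(rot, R) < 1.0
    assert np.linalg.norm(trans - t) < 0.2
    assert rmsd < 0.3


def test_kabsch_degenerate_inputs_rejected():
    with pytest.raises(DegenerateSuperpositionError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(DegenerateSuperpositionError):
        kabsch_superpose(line, line)


# -- angle/axis decomposition ------------------------------------------------

def test_angle_axis_examples():
    d = rotation_angle_axis(np.eye(3))
    assert d.theta == pytest.approx(0.0, abs=1e-9)
    d = rotation_angle_axis(rotation_from_angle_axis(180.0, [0, 0, 1]))
    assert d.theta == pytest.approx(180.0, abs=1e-6)
    assert np.allclose(np.abs(d.axis), [0, 0, 1], atol=1e-9)


def test_c5_closure_through_angle_axis():
    rng = np.random.default_rng(6)
    axis = rng.normal(size=3)
    R = rotation_from_angle_axis(72.0, axis)
    acc = np.eye(3)
    for _ in range(5):
        acc = R @ acc
    assert rotation_angle_axis(acc).theta == pytest.approx(0.0, abs=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_angle_axis_round_trip(seed):
    R = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
    d = rotation_angle_axis(R)
    back = rotation_from_angle_axis(d.theta, d.axis)
    assert np.radians(rotation_angle_between(R, back)) < 1e-6
    assert abs(np.linalg.norm(d.axis) - 1.0) < 1e-9


# -- spatial equivalence -----------------------------------------------------

@pytest.fixture(scope="module")
def equiv_setup():
    rng = np.random.default_rng(7)
    cell = UnitCell(30, 34, 38)
    sg = build_space_group("P212121")
    sol = [Placement("A", "m",
                     Rotation.random(random_state=rng).as_matrix(),
                     rng.uniform(0, 25, 3)) for _ in range(2)]
    return cell, sg, sol


def test_equivalence_reflexive(equiv_setup):
    cell, sg, sol = equiv_setup
    assert spatially_equivalent(sol, sol, sg, cell)


@pytest.mark.parametrize("op_index", [1, 2, 3])
def test_equivalence_under_catalogue_ops(equiv_setup, op_index):
    cell, sg, sol = equiv_setup
    image = [apply_symop(p, sg.ops[op_index], cell) for p in sol]
    assert spatially_equivalent(sol, image, sg, cell)
    assert spatially_equivalent(image, sol, sg, cell)   # symmetric


def test_equivalence_under_origin_shift(equiv_setup):
    cell, sg, sol = equiv_setup
    dt = cell.orth @ np.asarray(sg.origin_shifts[3])
    shifted = [p.shifted(dt) for p in sol]
    assert spatially_equivalent(sol, shifted, sg, cell)


def test_displaced_molecule_not_equivalent(equiv_setup):
    cell, sg, sol = equiv_setup
    moved = [sol[0], sol[1].shifted(np.array([10.0, 0.0, 0.0]))]
    assert not spatially_equivalent(sol, moved, sg, cell, tol_trans=2.0)


def test_polar_axis_continuous_freedom():
    rng = np.random.default_rng(8)
    cell = UnitCell(25, 30, 27)
    sg = build_space_group("P21")
    sol = [Placement("A", "m",
                     Rotation.random(random_state=rng).as_matrix(),
                     rng.uniform(0, 20, 3)) for _ in range(2)]
    slid = [p.shifted(cell.orth @ np.array([0.0, 0.314, 0.0]))
            for p in sol]
    assert spatially_equivalent(sol, slid, sg, cell)


def test_subset_matching(equiv_setup):
    cell, sg, sol = equiv_setup
    image = [apply_symop(sol[0], sg.ops[2], cell)]
    assert spatially_equivalent(sol, image, sg, cell, subset=True)
    assert not spatially_equivalent(sol, image, sg, cell, subset=False)
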
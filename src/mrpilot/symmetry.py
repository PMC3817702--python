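"""Crystallographic symmetry machinery.

This module holds everything the search engine needs to reason about
crystal symmetry without touching diffraction data:

* a small catalogue of chiral space groups (triclinic fully-polar,
  monoclinic polar, orthorhombic nonpolar and the tetragonal
  enantiomorph pair) with their operators, polar axes, allowed origin
  shifts and enantiomorph partners;
* conversion between fractional and orthogonal (Angstrom) frames using
  the standard PDB orthogonalization convention;
* rigid-body machinery: applying symmetry operators to placements,
  Kabsch superposition of paired point sets, angle/axis decomposition
  of rotations;
* the spatial-equivalence test that declares two multi-copy solutions
  "the same solution" up to one global symmetry operator plus an
  allowed origin move.

Symmetry operators live in the fractional basis; placements and
superposition work in orthogonal Angstroms.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import gemmi
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation


class SymmetryError(ValueError):
    """Base class for symmetry-related failures."""


class UnsupportedSpaceGroupError(SymmetryError):
    """Raised for a space-group symbol outside the supported catalogue."""


class DegenerateSuperpositionError(SymmetryError):
    """Raised when superposition is requested on <3 or collinear points."""


# ---------------------------------------------------------------------------
# space-group catalogue
# ---------------------------------------------------------------------------

#: short symbol -> full Hermann-Mauguin name understood by gemmi
_CATALOGUE = {
    "P1": "P 1",
    "P21": "P 1 21 1",
    "C2": "C 1 2 1",
    "P212121": "P 21 21 21",
    "P21212": "P 21 21 2",
    "P41": "P 41",
    "P43": "P 43",
}

_ENANTIOMORPH = {"P41": "P43", "P43": "P41"}

_POINT_GROUP = {
    "P1": "1",
    "P21": "2",
    "C2": "2",
    "P212121": "222",
    "P21212": "222",
    "P41": "4",
    "P43": "4",
}

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄", "01234")


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a space-group spelling to the short catalogue key.

    Accepts "P 21 21 21", "P212121" and unicode-subscript spellings.
    """
    s = symbol.translate(_SUBSCRIPT_DIGITS)
    s = s.replace(" ", "").replace("_", "").upper()
    # gemmi-style long monoclinic settings
    aliases = {"P1211": "P21", "C121": "C2"}
    return aliases.get(s, s)


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell dimensions: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.volume < 1e-6:
            raise ValueError("degenerate cell (near-zero volume)")

    @property
    def volume(self) -> float:
        return _gemmi_cell(self.a, self.b, self.c, self.alpha, self.beta,
                           self.gamma).volume

    @property
    def orth(self) -> np.ndarray:
        """3x3 orthogonalization matrix (fractional -> Angstrom)."""
        return _orth_matrix(self.a, self.b, self.c, self.alpha, self.beta,
                            self.gamma)

    @property
    def frac(self) -> np.ndarray:
        """3x3 fractionalization matrix (Angstrom -> fractional)."""
        return np.linalg.inv(self.orth)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@functools.lru_cache(maxsize=64)
def _gemmi_cell(a, b, c, alpha, beta, gamma):
    return gemmi.UnitCell(a, b, c, alpha, beta, gamma)


@functools.lru_cache(maxsize=64)
def _orth_matrix(a, b, c, alpha, beta, gamma):
    m = np.array(_gemmi_cell(a, b, c, alpha, beta, gamma).orth.mat.tolist())
    m.setflags(write=False)
    return m


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional -> orthogonal matrix, PDB CRYST1/SCALE convention."""
    return cell.orth


@dataclass(frozen=True, eq=False)
class SymOp:
    """One space-group operator: integer rotation + fractional translation."""

    rot: np.ndarray    # (3,3) int, fractional basis
    trans: np.ndarray  # (3,) float, components in [0, 1)

    def key(self) -> tuple:
        return (tuple(self.rot.ravel().tolist()),
                tuple(np.round(self.trans * 24).astype(int) % 24))

    @property
    def is_identity(self) -> bool:
        return (np.array_equal(self.rot, np.eye(3, dtype=int))
                and np.allclose(self.trans, 0.0))

    def apply_frac(self, xyz_frac: np.ndarray) -> np.ndarray:
        return xyz_frac @ self.rot.T + self.trans

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other (self o other), translation wrapped to [0,1)."""
        rot = self.rot @ other.rot
        trans = (self.rot @ other.trans + self.trans) % 1.0
        return SymOp(rot, trans)


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Everything the engine needs to know about one space group."""

    symbol: str                       # short canonical symbol, e.g. "P212121"
    hm: str                           # full Hermann-Mauguin name
    ops: tuple                        # tuple[SymOp], identity first
    polar_axes: tuple                 # (bool, bool, bool)
    origin_shifts: tuple              # tuple[np.ndarray], zero shift first
    enantiomorph: str | None
    point_group: str

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    @property
    def lattice_translations(self) -> tuple:
        """Pure translations of the group (identity + centring vectors)."""
        return tuple(op.trans for op in self.ops
                     if np.array_equal(op.rot, np.eye(3, dtype=int)))

    def ops_orth(self, cell: UnitCell) -> list:
        """Operators expressed in the orthogonal frame: (R_orth, t_orth)."""
        O, F = cell.orth, cell.frac
        return [(O @ op.rot @ F, O @ op.trans) for op in self.ops]


def _compute_polar_axes(ops: Sequence[SymOp]) -> tuple:
    flags = []
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        flags.append(all(np.allclose(op.rot @ e, e) for op in ops))
    return tuple(flags)


def _is_group_translation(v: np.ndarray, lattice: Sequence[np.ndarray]) -> bool:
    for lat in lattice:
        d = v - lat
        if np.allclose(d - np.round(d), 0.0, atol=1e-9):
            return True
    return False


def _compute_origin_shifts(ops: Sequence[SymOp], polar: tuple) -> tuple:
    """Enumerate discrete allowed origin shifts on the non-polar axes.

    A shift s is allowed when conjugating every operator by the
    translation s maps it onto another operator of the group, i.e.
    (I - R) s is a lattice translation for every rotation part R.
    Shifts differing by a lattice translation or only along polar axes
    describe the same origin choice and are deduplicated.
    """
    lattice = [op.trans for op in ops
               if np.array_equal(op.rot, np.eye(3, dtype=int))]
    eye = np.eye(3)
    candidates = []
    grid = [0.0, 0.25, 0.5, 0.75]
    for s in itertools.product(*[[0.0] if polar[i] else grid
                                 for i in range(3)]):
        s = np.array(s)
        ok = all(
            _is_group_translation((eye - op.rot) @ s, lattice)
            for op in ops)
        if ok:
            candidates.append(s)

    # dedupe modulo lattice translations and polar components
    kept: list[np.ndarray] = []
    for s in candidates:
        duplicate = False
        for t in kept:
            for lat in lattice:
                d = (s - t - lat) % 1.0
                d = d - np.round(d)
                d[list(polar)] = 0.0
                if np.allclose(d, 0.0, atol=1e-9):
                    duplicate = True
                    break
            if duplicate:
                break
        if not duplicate:
            kept.append(s)
    kept.sort(key=lambda v: tuple(v))
    for v in kept:
        v.setflags(write=False)
    return tuple(kept)


@functools.lru_cache(maxsize=16)
def build_space_group(symbol: str) -> SpaceGroupInfo:
    """Build the full symmetry description for a supported space group.

    Raises :class:`UnsupportedSpaceGroupError` for anything outside the
    seven-group catalogue.
    """
    short = normalize_symbol(symbol)
    if short not in _CATALOGUE:
        raise UnsupportedSpaceGroupError(
            f"unsupported space group {symbol!r}; supported: "
            f"{sorted(_CATALOGUE)}")
    sg = gemmi.find_spacegroup_by_name(_CATALOGUE[short])
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=int) // op.DEN
        trans = (np.array(op.tran, dtype=float) / op.DEN) % 1.0
        rot.setflags(write=False)
        trans.setflags(write=False)
        ops.append(SymOp(rot, trans))
    ops.sort(key=lambda o: (not o.is_identity,) + o.key())
    polar = _compute_polar_axes(ops)
    shifts = _compute_origin_shifts(ops, polar)
    return SpaceGroupInfo(
        symbol=short,
        hm=sg.hm,
        ops=tuple(ops),
        polar_axes=polar,
        origin_shifts=shifts,
        enantiomorph=_ENANTIOMORPH.get(short),
        point_group=_POINT_GROUP[short],
    )


def allowed_origin_moves(sg: SpaceGroupInfo) -> tuple:
    """Discrete fractional origin shifts plus continuous-axis flags."""
    return sg.origin_shifts, sg.polar_axes


# ---------------------------------------------------------------------------
# placements and rigid-body operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """A rigid-body pose of one search model in the orthogonal frame."""

    component_id: str
    model_id: str
    rot: np.ndarray    # (3,3) proper rotation
    trans: np.ndarray  # (3,) Angstrom

    def __post_init__(self):
        rot = np.asarray(self.rot, dtype=float)
        trans = np.asarray(self.trans, dtype=float)
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValueError("placement rotation must have determinant +1")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise ValueError("placement rotation must be orthonormal")
        rot.setflags(write=False)
        trans.setflags(write=False)
        object.__setattr__(self, "rot", rot)
        object.__setattr__(self, "trans", trans)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rot.T + self.trans

    def compose_left(self, rot: np.ndarray, trans: np.ndarray) -> "Placement":
        """Return the placement (rot, trans) o self."""
        return Placement(self.component_id, self.model_id,
                         rot @ self.rot, rot @ self.trans + trans)

    def shifted(self, dt: np.ndarray) -> "Placement":
        return Placement(self.component_id, self.model_id,
                         self.rot, self.trans + dt)


def apply_symop(p: Placement, op: SymOp, cell: UnitCell) -> Placement:
    """Symmetry image of a placement, expressed in the orthogonal frame."""
    O, F = cell.orth, cell.frac
    r_orth = O @ op.rot @ F
    t_orth = O @ op.trans
    return p.compose_left(r_orth, t_orth)


def kabsch_superpose(A: np.ndarray, B: np.ndarray):
    """Least-squares proper rigid transform of B onto A.

    Returns ``(rot, trans, rmsd)`` with ``rot @ B_i + trans ~ A_i`` and
    ``det(rot) = +1``. A and B are paired N x 3 point sets, N >= 3.
    Collinear (rank-deficient) inputs raise
    :class:`DegenerateSuperpositionError`: the rotation about the line
    is then undetermined.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise DegenerateSuperpositionError("paired N x 3 point sets required")
    n = A.shape[0]
    if n < 3:
        raise DegenerateSuperpositionError(
            f"need at least 3 paired points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    # degenerate when the paired points are collinear in either set
    if (np.linalg.matrix_rank(A - ca, tol=1e-8) < 2
            or np.linalg.matrix_rank(B - cb, tol=1e-8) < 2):
        raise DegenerateSuperpositionError("collinear points")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rot = Vt.T @ D @ U.T
    trans = ca - rot @ cb
    diff = (B @ rot.T + trans) - A
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return rot, trans, rmsd


@dataclass(frozen=True)
class RotationDecomposition:
    """Angle (degrees, [0, 180]) and canonical-sign unit axis."""

    theta: float
    axis: np.ndarray


def rotation_angle_axis(rot: np.ndarray) -> RotationDecomposition:
    """Decompose a proper rotation into angle (deg, [0, 180]) and axis.

    The axis keeps the true rotation sense, so the decomposition
    reconstructs the input rotation exactly; only where the sign is
    genuinely free (the identity and 180-degree rotations) is it
    canonicalized to "first nonzero component positive".
    """
    rotvec = Rotation.from_matrix(np.asarray(rot, dtype=float)).as_rotvec()
    theta = float(np.degrees(np.linalg.norm(rotvec)))
    if theta < 1e-9:
        axis = np.array([1.0, 0.0, 0.0])
    else:
        axis = rotvec / np.linalg.norm(rotvec)
    if theta < 1e-9 or abs(theta - 180.0) < 1e-9:
        for comp in axis:
            if abs(comp) > 1e-8:
                if comp < 0:
                    axis = -axis
                break
    axis = axis.copy()
    axis.setflags(write=False)
    return RotationDecomposition(theta=theta, axis=axis)


def rotation_from_angle_axis(theta_deg: float, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(theta_deg) * axis).as_matrix()


def rotation_angle_between(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Angle in degrees of the rotation taking Ra onto Rb."""
    tr = np.trace(Ra.T @ Rb)
    cos = min(1.0, max(-1.0, (tr - 1.0) / 2.0))
    return float(np.degrees(np.arccos(cos)))


# ---------------------------------------------------------------------------
# spatial equivalence of solutions
# ---------------------------------------------------------------------------

def min_image_distance(dt: np.ndarray, cell: UnitCell,
                       sg: SpaceGroupInfo | None = None) -> float:
    """Length of a translation difference modulo the group's lattice."""
    F, O = cell.frac, cell.orth
    d = F @ dt
    best = np.inf
    lattice = sg.lattice_translations if sg is not None else (np.zeros(3),)
    for lat in lattice:
        w = d - lat
        w = w - np.round(w)
        best = min(best, float(np.linalg.norm(O @ w)))
    return best


def _placements_of(sol) -> Sequence[Placement]:
    return sol.placements if hasattr(sol, "placements") else sol


def _default_entity(p: Placement) -> tuple:
    return (p.component_id, p.model_id)


def _feasible_matching(ok: np.ndarray) -> bool:
    """True when the boolean feasibility matrix admits a perfect matching."""
    n = ok.shape[0]
    if ok.shape[1] != n:
        return False
    cost = np.where(ok, 0.0, 1.0)
    rows, cols = linear_sum_assignment(cost)
    return bool(cost[rows, cols].sum() < 0.5)


def spatially_equivalent(solA, solB, sg: SpaceGroupInfo, cell: UnitCell,
                         tol_rot: float = 5.0, tol_trans: float = 2.0,
                         entity_key: Callable[[Placement], tuple] | None = None,
                         subset: bool = False) -> bool:
    """Test whether two solutions are the same up to crystal symmetry.

    True iff a single catalogue operator plus one allowed origin move
    maps every placement of ``solB`` onto a distinct placement of
    ``solA`` within the tolerances. ``entity_key`` controls which
    placements may be matched (default: same component and model; branch
    reduction relaxes this to template identity). With ``subset=True``
    the test succeeds when B maps onto a *subset* of A's placements.
    """
    A = list(_placements_of(solA))
    B = list(_placements_of(solB))
    sgA = getattr(solA, "sg_symbol", None)
    sgB = getattr(solB, "sg_symbol", None)
    if sgA is not None and sgB is not None and sgA != sgB:
        raise SymmetryError("solutions live in different space groups")
    if subset:
        if len(B) > len(A):
            return False
    elif len(A) != len(B):
        return False
    if not B:
        return True
    key = entity_key or _default_entity
    O = cell.orth
    polar = np.array(sg.polar_axes)

    for op in sg.ops:
        Bg = [apply_symop(p, op, cell) for p in B]
        deltas = []
        for s in sg.origin_shifts:
            base = O @ s
            if not polar.any():
                deltas.append(base)
                continue
            # anchor the continuous component on any compatible A partner
            for a in A:
                if key(a) != key(Bg[0]):
                    continue
                if rotation_angle_between(a.rot, Bg[0].rot) > tol_rot:
                    continue
                d_frac = cell.frac @ (a.trans - Bg[0].trans - base)
                d_frac = d_frac - np.round(d_frac)
                adj = np.where(polar, d_frac, 0.0)
                deltas.append(base + O @ adj)
            deltas.append(base)  # zero continuous component fallback
        for delta in deltas:
            ok = np.zeros((len(A), len(A)), dtype=bool)
            for j, b in enumerate(Bg):
                bt = b.trans + delta
                for i, a in enumerate(A):
                    if key(a) != key(b):
                        continue
                    if rotation_angle_between(a.rot, b.rot) > tol_rot:
                        continue
                    if min_image_distance(a.trans - bt, cell, sg) > tol_trans:
                        continue
                    ok[i, j] = True
            if subset:
                # pad with dummy columns that match anything
                pad = np.ones((len(A), len(A) - len(B)), dtype=bool)
                ok = np.concatenate([ok[:, :len(B)], pad], axis=1)
            if _feasible_matching(ok):
                return True
    return False
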
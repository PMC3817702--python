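"""Post-cycle solution analyses.

After each extension cycle the engine mines its clear solutions for
information that lets later cycles skip work: amalgamation of clear
siblings into more complete solutions, detection of noncrystallographic
point-group (Cn/Dn) assemblies among placed copies, prediction of the
missing members of a partially placed assembly, refreshing of NCS
operators after refinement, completion from user-supplied assembly
definitions, and (optionally) the use of a complete assembly as a
single rigid search model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .symmetry import (Placement, SpaceGroupInfo, UnitCell,
                       min_image_distance, rotation_angle_axis,
                       rotation_angle_between, rotation_from_angle_axis)

#: default tolerances for assembly detection (degrees, degrees, Angstrom)
TOL_AXIS = 5.0
TOL_ANGLE = 5.0
TOL_PERP = 1.0
MAX_ORDER = 12
#: tolerances for matching placements onto orbit slots
SLOT_TOL_ROT = 10.0
SLOT_TOL_TRANS = 3.0


@dataclass(frozen=True)
class AssemblyHypothesis:
    """A detected or user-supplied point-group arrangement."""

    group_label: str            # "C5", "D2", ...
    order: int                  # total group order (2n for Dn)
    axis: tuple                 # unit 3-vector
    center: tuple               # point in A
    member_indices: tuple       # indices into the solution's placements
    generators: tuple           # tuple[(R flat 9-tuple, t 3-tuple)]
    source: str = "detected"
    orbit_reps: tuple = ()      # one member index per distinct orbit

    def generator_transforms(self):
        return [(np.array(r).reshape(3, 3), np.array(t))
                for r, t in self.generators]


@dataclass
class PredictedPlacement:
    """A pending placement predicted from assembly information."""

    placement: Placement
    origin_assembly: str
    status: str = "pending"      # pending | confirmed | rejected


# ---------------------------------------------------------------------------
# NCS transform analysis
# ---------------------------------------------------------------------------

def _pair_transform(pi: Placement, pj: Placement):
    """Rigid transform taking copy i onto copy j in the crystal frame."""
    R = pj.rot @ pi.rot.T
    t = pj.trans - R @ pi.trans
    return R, t


def _iter_images(p: Placement, sg: SpaceGroupInfo | None, cell: UnitCell,
                 near: np.ndarray):
    """Crystal-symmetry images of a placement, lattice-wrapped near a point.

    Copies of one solution may sit on truth images under different
    crystal operators; NCS analysis must therefore consider every
    symmetry image of a partner placement, not just its stored frame.
    """
    if sg is None:
        yield p
        return
    from .symmetry import apply_symop
    O, F = cell.orth, cell.frac
    for op in sg.ops:
        img = apply_symop(p, op, cell)
        wrap = O @ np.round(F @ (near - img.trans))
        yield img.shifted(wrap)


def _point_group_order(theta: float, tol_angle: float,
                       max_order: int) -> int | None:
    """Smallest n with theta ~ 360*m/n (m, n coprime); None if none fits."""
    for n in range(2, max_order + 1):
        for m in range(1, n):
            if math.gcd(m, n) != 1:
                continue
            if abs(theta - 360.0 * m / n) <= tol_angle:
                return n
    return None


def _axis_center(R: np.ndarray, t: np.ndarray, anchor: np.ndarray):
    """Axis (canonical sign), axial shift and a point on the screw axis."""
    dec = rotation_angle_axis(R)
    axis = np.array(dec.axis)
    tau = float(axis @ t)
    t_perp = t - tau * axis
    # (I - R) c = t_perp ; rank-2 system, least squares
    c0, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    lam = float(axis @ (anchor - c0))
    return axis, tau, c0 + lam * axis


def _orbit_slots(member: Placement, hyp_axis, hyp_center, group_label: str):
    """The full orbit of a member placement under the exact point group."""
    axis = np.asarray(hyp_axis, dtype=float)
    center = np.asarray(hyp_center, dtype=float)
    n = int(group_label[1:])
    gens = [rotation_from_angle_axis(360.0 * k / n, axis) for k in range(n)]
    if group_label[0] == "D":
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        flip = rotation_from_angle_axis(180.0, perp)
        gens = gens + [g @ flip for g in gens]
    slots = []
    for g in gens:
        rot = g @ member.rot
        trans = g @ (member.trans - center) + center
        slots.append(Placement(member.component_id, member.model_id,
                               rot, trans))
    return slots, gens


def _partition_orbits(members, axis, center, label,
                      tol_rot=SLOT_TOL_ROT, tol_trans=SLOT_TOL_TRANS,
                      sg: SpaceGroupInfo | None = None,
                      cell: UnitCell | None = None):
    """Partition members into group orbits by greedy slot matching.

    Returns a list of ``(rep_local_index, {local_index: slot_index})``
    per orbit. Members that join no other member's orbit seed their own
    (possibly singleton) orbit. Matching is symmetry-aware: a member
    counts as occupying a slot when any of its crystal images does.
    """
    remaining = list(range(len(members)))
    orbits = []
    while remaining:
        rep = remaining[0]
        slots, _ = _orbit_slots(members[rep], axis, center, label)
        assign = {rep: 0}
        used = {0}
        rest = []
        for mi in remaining[1:]:
            best, best_d = None, None
            for si, s in enumerate(slots):
                if si in used:
                    continue
                for cand in _iter_images(members[mi], sg, cell, s.trans) \
                        if cell is not None else [members[mi]]:
                    if rotation_angle_between(cand.rot, s.rot) > tol_rot:
                        continue
                    d = float(np.linalg.norm(cand.trans - s.trans))
                    if d > tol_trans:
                        continue
                    if best is None or d < best_d:
                        best, best_d = si, d
            if best is None:
                rest.append(mi)
            else:
                assign[mi] = best
                used.add(best)
        orbits.append((rep, assign))
        remaining = rest
    return orbits


def detect_assemblies(placements: Sequence[Placement], cell: UnitCell,
                      tol_axis: float = TOL_AXIS,
                      tol_angle: float = TOL_ANGLE,
                      tol_perp: float = TOL_PERP,
                      max_order: int = MAX_ORDER,
                      sg: SpaceGroupInfo | None = None) -> list:
    """Find Cn/Dn point-group arrangements among same-component copies.

    Pairwise NCS transforms between placements of the same component
    are screened for point-group compatibility (rotation angle close to
    360*m/n, negligible translation along the rotation axis), clustered
    by axis direction, validated by mapping members onto the exact
    orbit of the snapped generator, and finally merged so that a Dn
    absorbs its Cn/C2 subgroups.
    """
    by_comp: dict = {}
    for i, p in enumerate(placements):
        by_comp.setdefault(p.component_id, []).append(i)

    candidates = []   # (i, j, order, axis, center)
    for comp, idxs in by_comp.items():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                for pj in _iter_images(placements[j], sg, cell,
                                       placements[i].trans):
                    R, t = _pair_transform(placements[i], pj)
                    theta = rotation_angle_axis(R).theta
                    if theta < tol_angle:
                        continue
                    order = _point_group_order(theta, tol_angle, max_order)
                    if order is None:
                        continue
                    anchor = 0.5 * (placements[i].trans + pj.trans)
                    axis, tau, center = _axis_center(R, t, anchor)
                    if abs(tau) > tol_perp:
                        continue
                    candidates.append((i, j, order, axis, center))
    # dedupe equivalent transforms found through different images
    seen_keys = set()
    uniq = []
    for cand in candidates:
        i, j, order, axis, center = cand
        sign = 1.0 if (axis[np.flatnonzero(np.abs(axis) > 1e-8)[0]]
                       > 0) else -1.0
        key = (i, j, order,
               tuple(np.round(sign * axis, 1).tolist()),
               tuple(np.round(center / 2.0).astype(int).tolist()))
        if key not in seen_keys:
            seen_keys.add(key)
            uniq.append(cand)
    candidates = uniq

    # cluster candidate transforms by axis direction (antipodal-aware)
    g = nx.Graph()
    g.add_nodes_from(range(len(candidates)))
    for a in range(len(candidates)):
        for b in range(a + 1, len(candidates)):
            dot = abs(float(candidates[a][3] @ candidates[b][3]))
            if np.degrees(np.arccos(min(1.0, dot))) <= tol_axis:
                g.add_edge(a, b)

    cyclic: list[AssemblyHypothesis] = []
    for cluster in sorted(nx.connected_components(g), key=min):
        cluster = sorted(cluster)
        orders = [candidates[c][2] for c in cluster]
        # a Cn orbit produces pair rotations of several periods (e.g. C6
        # gives 60/120/180 degree pairs): the group order is their lcm
        order = 1
        for o in set(orders):
            order = math.lcm(order, o)
        if order > max_order:
            order = max(set(orders), key=orders.count)
        axis = np.mean([candidates[c][3] *
                        np.sign(candidates[c][3] @ candidates[cluster[0]][3]
                                or 1.0)
                        for c in cluster], axis=0)
        axis /= np.linalg.norm(axis)
        center = np.mean([candidates[c][4] for c in cluster], axis=0)
        members = sorted({candidates[c][0] for c in cluster}
                         | {candidates[c][1] for c in cluster})
        label = f"C{order}"
        member_pls = [placements[m] for m in members]
        orbits = _partition_orbits(member_pls, axis, center, label,
                                   sg=sg, cell=cell)
        kept = [(rep, assign) for rep, assign in orbits if len(assign) >= 2]
        if not kept:
            continue
        kept_members = sorted({members[mi] for _rep, assign in kept
                               for mi in assign})
        _slots, gens = _orbit_slots(member_pls[0], axis, center, label)
        cyclic.append(AssemblyHypothesis(
            group_label=label, order=order,
            axis=tuple(axis), center=tuple(center),
            member_indices=tuple(kept_members),
            generators=tuple((tuple(gr.ravel()),
                              tuple(gr @ (-center) + center))
                             for gr in gens),
            source="detected",
            orbit_reps=tuple(members[rep] for rep, _a in kept)))

    # dihedral assembly: a Cn plus a perpendicular C2 through the same center
    dihedral: list[AssemblyHypothesis] = []
    for h in cyclic:
        for c2 in cyclic:
            if c2 is h or c2.order != 2:
                continue
            ang = np.degrees(np.arccos(min(1.0, abs(
                float(np.array(h.axis) @ np.array(c2.axis))))))
            if abs(ang - 90.0) > TOL_AXIS:
                continue
            members = sorted(set(h.member_indices) | set(c2.member_indices))
            n_main = int(h.group_label[1:])
            label = f"D{n_main}"
            member_pls = [placements[m] for m in members]
            orbits = _partition_orbits(member_pls, np.asarray(h.axis),
                                       np.asarray(h.center), label,
                                       sg=sg, cell=cell)
            kept = [(rep, a) for rep, a in orbits if len(a) >= 2]
            if not kept:
                continue
            kept_members = sorted({members[mi] for _r, a in kept for mi in a})
            center = np.asarray(h.center)
            _slots, gens = _orbit_slots(member_pls[0], np.asarray(h.axis),
                                        center, label)
            dihedral.append(AssemblyHypothesis(
                group_label=label, order=2 * n_main,
                axis=h.axis, center=h.center,
                member_indices=tuple(kept_members),
                generators=tuple((tuple(gr.ravel()),
                                  tuple(gr @ (-center) + center))
                                 for gr in gens),
                source="detected",
                orbit_reps=tuple(members[rep] for rep, _a in kept)))
            break

    # subgroup absorption: drop any hypothesis whose members are contained
    # in a dihedral hypothesis with a compatible axis
    out = list(dihedral)
    for h in cyclic:
        absorbed = False
        for d in dihedral:
            if not set(h.member_indices) <= set(d.member_indices):
                continue
            ang = np.degrees(np.arccos(min(1.0, abs(
                float(np.array(h.axis) @ np.array(d.axis))))))
            if (int(d.group_label[1:]) % int(h.group_label[1:]) == 0
                    and ang <= TOL_AXIS) or abs(ang - 90.0) <= TOL_AXIS:
                absorbed = True
                break
        if not absorbed:
            out.append(h)
    # merge duplicates (same label, same members)
    seen, uniq = set(), []
    for h in out:
        key = (h.group_label, h.member_indices)
        if key not in seen:
            seen.add(key)
            uniq.append(h)
    return uniq


def _placement_matches(p: Placement, q: Placement, sg: SpaceGroupInfo,
                       cell: UnitCell, tol_rot=SLOT_TOL_ROT,
                       tol_trans=SLOT_TOL_TRANS) -> bool:
    """Same molecule? Compare modulo crystal symmetry images (no origin)."""
    if p.component_id != q.component_id:
        return False
    from .symmetry import apply_symop
    for op in sg.ops:
        qi = apply_symop(q, op, cell)
        if rotation_angle_between(p.rot, qi.rot) > tol_rot:
            continue
        if min_image_distance(p.trans - qi.trans, cell, sg) <= tol_trans:
            return True
    return False


def predict_missing(assembly: AssemblyHypothesis,
                    placements: Sequence[Placement],
                    sg: SpaceGroupInfo, cell: UnitCell) -> list:
    """Predicted placements for the unoccupied orbit positions.

    The full orbit of the first member is generated under the group;
    positions not matching an existing placement (symmetry-aware)
    become pending predictions.
    """
    if not assembly.member_indices:
        return []
    reps = assembly.orbit_reps or (assembly.member_indices[0],)
    out = []
    for rep in reps:
        slots, _ = _orbit_slots(placements[rep], assembly.axis,
                                assembly.center, assembly.group_label)
        for s in slots:
            if any(_placement_matches(s, q, sg, cell) for q in placements):
                continue
            if any(_placement_matches(s, o.placement, sg, cell)
                   for o in out):
                continue
            out.append(PredictedPlacement(
                placement=s, origin_assembly=assembly.group_label))
    return out


def update_ncs(placements: Sequence[Placement],
               assemblies: Sequence[AssemblyHypothesis],
               cell: UnitCell, sg: SpaceGroupInfo | None = None,
               tol_axis: float = TOL_AXIS, tol_angle: float = TOL_ANGLE,
               tol_perp: float = TOL_PERP) -> list:
    """Re-fit assembly operators from the current (refined) placements.

    Each hypothesis is refitted on its own members; hypotheses whose
    members no longer map onto the refitted orbit are demoted
    (dropped). Freshly detectable groups equivalent to an existing one
    replace it.
    """
    out = []
    for h in assemblies:
        members = [placements[i] for i in h.member_indices
                   if i < len(placements)]
        if len(members) < 2:
            continue
        fresh = detect_assemblies(members, cell, tol_axis, tol_angle,
                                  tol_perp, sg=sg)
        pick = None
        for f in fresh:
            if f.group_label == h.group_label:
                pick = f
                break
        if pick is None:
            continue  # demoted: tolerance violation after refinement
        out.append(replace(pick,
                           member_indices=tuple(
                               h.member_indices[i]
                               for i in pick.member_indices),
                           source=h.source))
    return out


# ---------------------------------------------------------------------------
# amalgamation
# ---------------------------------------------------------------------------

@dataclass
class AmalgamCandidate:
    """A proposed combination of two clear siblings."""

    placements: tuple            # proposed additions beyond the parent
    model_ids: tuple
    needs_translation_search: bool = False
    orientation_only: tuple = ()  # rotations to re-use in a polar TF search


def amalgamate(parent_placements, adds_a, adds_b,
               sg: SpaceGroupInfo, cell: UnitCell) -> list:
    """Combine the additions of two clear siblings of one parent.

    Returns candidate addition sets (relative to the parent). When the
    parent is empty the two siblings fixed their origins independently:
    for nonpolar groups every discrete origin shift of B's additions is
    proposed; for polar groups only B's rotations are re-used and a
    translation search must be scheduled by the caller.
    """
    adds_a = list(adds_a)
    adds_b = list(adds_b)
    if not adds_a or not adds_b:
        return []
    out = []
    if parent_placements:
        out.append(AmalgamCandidate(
            placements=tuple(adds_a + adds_b),
            model_ids=tuple(p.model_id for p in adds_a + adds_b)))
        return out
    if any(sg.polar_axes):
        out.append(AmalgamCandidate(
            placements=tuple(adds_a),
            model_ids=tuple(p.model_id for p in adds_a),
            needs_translation_search=True,
            orientation_only=tuple(tuple(p.rot.ravel()) for p in adds_b)))
        return out
    for s in sg.origin_shifts:
        dt = cell.orth @ np.asarray(s)
        shifted = [b.shifted(dt) for b in adds_b]
        out.append(AmalgamCandidate(
            placements=tuple(adds_a + shifted),
            model_ids=tuple(p.model_id for p in adds_a + shifted)))
    return out


# ---------------------------------------------------------------------------
# known assemblies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnownAssembly:
    """User-supplied assembly: members with transforms relative to member 1.

    Not restricted to homomeric or point-group arrangements.
    """

    name: str
    members: tuple               # tuple[(component_id, R flat 9, t 3)]

    def transforms(self):
        return [(comp, np.array(r).reshape(3, 3), np.array(t))
                for comp, r, t in self.members]


def complete_known_assembly(assembly: KnownAssembly,
                            placements: Sequence[Placement],
                            models_by_placement: Sequence,
                            backend, sol_sg=None,
                            shift_range: float = 4.0, shift_step: float = 1.0,
                            rot_range: float = 10.0, rot_step: float = 5.0
                            ) -> list:
    """Predict missing members of a user assembly around a placed anchor.

    User assemblies can be imprecise, so each predicted pose is locally
    optimized with a separable grid search (translations first, then
    orientations, then translations again) before being returned as a
    pending prediction.
    """
    transforms = assembly.transforms()
    anchor_idx = None
    anchor_member = None
    for mi, (comp, _r, _t) in enumerate(transforms):
        for pi, p in enumerate(placements):
            if p.component_id == comp:
                anchor_idx, anchor_member = pi, mi
                break
        if anchor_idx is not None:
            break
    if anchor_idx is None:
        return []
    anchor = placements[anchor_idx]
    comp_a, Ra, ta = transforms[anchor_member]
    # crystal pose of the assembly frame: anchor o T_anchor^-1
    R_frame = anchor.rot @ Ra.T
    t_frame = anchor.trans - R_frame @ ta

    placed_comps = {}
    for p in placements:
        placed_comps[p.component_id] = placed_comps.get(p.component_id, 0) + 1

    out = []
    for mi, (comp, Rm, tm) in enumerate(transforms):
        if mi == anchor_member:
            continue
        pred = Placement(comp, f"assembly:{assembly.name}:{mi}",
                         R_frame @ Rm, R_frame @ tm + t_frame)
        if any(_placement_matches(pred, q, backend.sg, backend.cell)
               for q in placements):
            continue
        best = _local_search(pred, placements, models_by_placement, backend,
                             sol_sg, shift_range, shift_step, rot_range,
                             rot_step)
        out.append(PredictedPlacement(placement=best,
                                      origin_assembly=assembly.name))
    return out


def _local_search(pred, placements, models, backend, sol_sg,
                  shift_range, shift_step, rot_range, rot_step):
    """Separable grid search maximizing the backend's score gain."""
    base = backend.score(list(placements), list(models), sol_sg)

    def gain(pl):
        model = backend_model_for(backend, pl)
        return backend._delta_raw(list(placements), list(models),
                                  [pl], [model], sol_sg, base)

    steps = np.arange(-shift_range, shift_range + 1e-9, shift_step)
    rsteps = np.arange(-rot_range, rot_range + 1e-9, rot_step)
    best = pred
    best_val = gain(pred)
    for _pass in range(2):
        for axis in range(3):
            cur = best
            for s in steps:
                dt = np.zeros(3)
                dt[axis] = s
                cand = cur.shifted(dt)
                v = gain(cand)
                if v > best_val:
                    best, best_val = cand, v
        if _pass == 0:
            from scipy.spatial.transform import Rotation
            cur = best
            for rx in rsteps:
                for ry in rsteps:
                    for rz in rsteps:
                        if rx == ry == rz == 0:
                            continue
                        dR = Rotation.from_rotvec(
                            np.radians([rx, ry, rz])).as_matrix()
                        cand = Placement(cur.component_id, cur.model_id,
                                         cur.rot @ dR, cur.trans)
                        v = gain(cand)
                        if v > best_val:
                            best, best_val = cand, v
    return best


def backend_model_for(backend, placement: Placement):
    """Model-like stand-in for scoring a predicted placement.

    Predictions are scored with the true component cloud geometry of
    the backend (the prediction mechanism asks "is there something
    here", not "how good is this model").
    """
    from .toycrystal import _TruthModel
    return _TruthModel(placement.component_id,
                       backend.clouds[placement.component_id],
                       backend.weights[placement.component_id])


# ---------------------------------------------------------------------------
# assemblies as rigid search models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositeModel:
    """A complete assembly treated as one rigid search model.

    The composite searches as a single body (one rotation/translation
    function) and is disassembled into per-member placements before
    refinement.
    """

    model_id: str
    component_id: str
    composite_members: tuple     # tuple[(EnsembleModel, rel_rot, rel_trans)]
    weight: float
    source_template_id: str

    @property
    def coverage(self):
        return self.composite_members[0][0].coverage

    @property
    def coords(self):
        out = []
        for m, rr, rt in self.composite_members:
            out.append(m.coords @ rr.T + rt)
        return np.concatenate(out)

    @property
    def resids(self):
        return np.concatenate([m.resids for m, _r, _t in
                               self.composite_members])

    def __len__(self):
        return sum(len(m) for m, _r, _t in self.composite_members)

    def expand(self, placement: Placement) -> list:
        """Disassemble a composite pose into per-member placements."""
        out = []
        for m, rr, rt in self.composite_members:
            out.append(Placement(m.component_id, m.model_id,
                                 placement.rot @ rr,
                                 placement.rot @ rt + placement.trans))
        return out


def assemblies_as_models(assembly: AssemblyHypothesis,
                         placements: Sequence[Placement],
                         models_by_placement: Sequence) -> CompositeModel:
    """Build a rigid composite model from a complete assembly."""
    idxs = list(assembly.member_indices)
    p0 = placements[idxs[0]]
    inv_r = p0.rot.T
    members = []
    total_w = 0.0
    for i in idxs:
        p = placements[i]
        m = models_by_placement[i]
        rel_rot = inv_r @ p.rot
        rel_trans = inv_r @ (p.trans - p0.trans)
        members.append((m, rel_rot, rel_trans))
        total_w += float(m.weight)
    m0 = models_by_placement[idxs[0]]
    return CompositeModel(
        model_id=f"composite:{assembly.group_label}:{m0.model_id}",
        component_id=m0.component_id,
        composite_members=tuple(members),
        weight=total_w,
        source_template_id=f"composite:{m0.source_template_id}")
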
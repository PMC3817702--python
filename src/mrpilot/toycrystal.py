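"""Synthetic crystals and the mock maximum-likelihood-style scorer.

This module plays two roles. First, it is the synthetic-data
generator: it builds ground-truth "toy crystals" — a unit cell sized
from the Matthews relation, a supported space group, and a set of true
rigid-body placements of compact C-alpha clouds, optionally arranged
on Cn/Dn point-group orbits. Second, the generated
:class:`ToyCrystal` doubles as the scoring backend for the search
engine, implementing rotation search, translation search, packing,
rigid-body refinement and a log-likelihood-gain analogue that honours
the contract real maximum-likelihood scores obey: scores of different
solutions against the same crystal may be directly compared, and a
geometrically better solution never scores lower (noiseless case).

The LLG analogue of a solution is

    llg = max over allowed origin moves of
          sum_p  w_p * ov(p, matched truth)  -  0.5 * wbar * n_clash
          + per-placement score noise

where ``ov`` is an orbit overlap: the placement's images under the
*solution* space group are each compared with the best-matching image
of the matched truth under the *crystal* space group (Gaussian overlap
of shared C-alpha positions, width sigma, lattice minimum-image), and
averaged. Matching is greedy best-overlap without truth reuse. The
orbit form makes the score sensitive to a wrong enantiomorph choice
while keeping it invariant under one global symmetry operation plus an
allowed origin move. Score noise has sd ``epsilon * w_p`` and is keyed
on discretized placement bins (1 A / 5 deg) so that rescoring the same
pose is bit-for-bit reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .composition import ComponentSpec, CoverageSet
from .modelprep import CoordSet, EnsembleModel
from .symmetry import (Placement, SpaceGroupInfo, UnitCell, build_space_group,
                       rotation_angle_between, rotation_from_angle_axis)


class GenerationError(RuntimeError):
    pass


CLASH_DISTANCE = 3.0          # A; C-alpha pair closer than this is a clash
CLASH_FRACTION = 0.05         # packing passes if clashes <= 5% of smaller mol
ROT_PREFILTER_DEG = 60.0      # overlap of misoriented images is negligible
GEN_CLASH_MARGIN = 2.0        # A; truths are packed with this extra clearance
                              # so imperfect models on correct poses still pack
POS_BIN = 1.0                 # A,   noise binning
ROT_BIN = 5.0                 # deg, noise binning


# ---------------------------------------------------------------------------
# deterministic hash noise
# ---------------------------------------------------------------------------

def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


def _mix_columns(cols: Sequence[np.ndarray], seed: int) -> np.ndarray:
    """Combine integer key columns into one well-mixed uint64 stream."""
    with np.errstate(over="ignore"):
        acc = np.full(len(cols[0]), np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
        for c in cols:
            acc = _splitmix64(acc ^ c.astype(np.int64).view(np.uint64))
        return acc


def hash_normal(cols: Sequence[np.ndarray], seed: int) -> np.ndarray:
    """Standard-normal noise keyed on integer tuples (Box-Muller)."""
    h1 = _mix_columns(cols, seed)
    h2 = _splitmix64(h1)
    u1 = (h1 >> np.uint64(11)).astype(np.float64) / float(1 << 53)
    u2 = (h2 >> np.uint64(11)).astype(np.float64) / float(1 << 53)
    u1 = np.clip(u1, 1e-12, 1.0)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


def _str_key(s: str) -> int:
    return zlib.crc32(s.encode())


def _pose_bins(rot: np.ndarray, trans: np.ndarray) -> tuple:
    rv = Rotation.from_matrix(rot).as_rotvec(degrees=True)
    return (tuple(np.round(trans / POS_BIN).astype(int).tolist()),
            tuple(np.round(rv / ROT_BIN).astype(int).tolist()))


# ---------------------------------------------------------------------------
# quasi-uniform SO(3) grid (super-Fibonacci spiral)
# ---------------------------------------------------------------------------

_PHI = np.sqrt(2.0)
_PSI = 1.533751168755204288118041


def so3_grid(step_deg: float) -> np.ndarray:
    """Quaternions (N, 4) quasi-uniformly covering SO(3) at ~step_deg."""
    step = np.radians(step_deg)
    n = max(8, int(np.ceil(np.pi ** 2 / ((4.0 / 3.0) * np.pi
                                         * (step / 2.0) ** 3))))
    s = np.arange(n) + 0.5
    t = s / n
    d = 2.0 * np.pi * s
    r, R = np.sqrt(t), np.sqrt(1.0 - t)
    alpha, beta = d / _PHI, d / _PSI
    q = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                  R * np.sin(beta), R * np.cos(beta)], axis=1)
    return q


def _quat_of_matrix(R: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(R).as_quat()


# ---------------------------------------------------------------------------
# generator specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentGen:
    component_id: str
    length: int
    copies: int
    assembly: str | None = None      # e.g. "C5" or "D2"
    assembly_axis: tuple | None = None


@dataclass(frozen=True)
class GenSpec:
    """Specification for one synthetic crystal."""

    components: tuple                 # tuple[ComponentGen]
    space_group: str = "P1"
    solvent_target: float = 0.5
    sigma: float = 1.5                # A, positional overlap width
    sigma_rot: float = 10.0           # deg, orientation overlap width
    epsilon: float = 0.02             # score-noise sd as fraction of weight
    template_noise: float = 0.8       # A, coordinate noise on emitted models


@dataclass(frozen=True)
class ScoreReport:
    llg: float
    per_placement_overlap: tuple
    matched_truth_indices: tuple
    clash_count: int
    origin_shift: tuple = (0.0, 0.0, 0.0)


@dataclass
class Peak:
    """One translation-function peak."""

    placement: Placement
    raw: float
    tfz: float
    packs: bool | None = None
    clear: bool = False
    llg: float | None = None


# ---------------------------------------------------------------------------
# compact C-alpha cloud generation
# ---------------------------------------------------------------------------

def compact_chain(n: int, rng: np.random.Generator,
                  bond: float = 3.8, min_sep: float = 3.4) -> np.ndarray:
    """Seeded compact self-avoiding C-alpha walk, centred at the origin.

    The walk is confined to a sphere sized for protein-like density
    (~134 A^3 per residue), giving clouds that pack like real molecules.
    """
    r_max = (n * 134.0 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) + 1.0
    for _attempt in range(200):
        pts = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            for _try in range(300):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = pts[-1] + bond * d
                if np.linalg.norm(cand) > r_max and len(pts) > 2:
                    continue
                if len(pts) > 1:
                    arr = np.array(pts[:-1])
                    if np.min(np.linalg.norm(arr - cand, axis=1)) < min_sep:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            arr = np.array(pts)
            return arr - arr.mean(axis=0)
    raise GenerationError(f"could not build a compact {n}-residue chain")


# ---------------------------------------------------------------------------
# the toy crystal / scoring backend
# ---------------------------------------------------------------------------

@dataclass
class ToyCrystal:
    """Ground truth of a synthetic crystal; doubles as scoring backend."""

    cell: UnitCell
    sg: SpaceGroupInfo
    truths: tuple                       # tuple[(component_id, Placement)]
    clouds: Mapping[str, np.ndarray]    # component_id -> (L, 3) true coords
    weights: Mapping[str, float]        # component_id -> Da
    sigma: float = 1.5
    sigma_rot: float = 10.0
    epsilon: float = 0.02
    seed: int = 0

    def __post_init__(self):
        self._truth_cache: dict = {}

    # -- geometry helpers ---------------------------------------------------

    def _sol_sg(self, sol_sg) -> SpaceGroupInfo:
        if sol_sg is None:
            return self.sg
        if isinstance(sol_sg, str):
            return build_space_group(sol_sg)
        return sol_sg

    def _truth_images(self):
        """Per truth: list of (R_img, t_img, coords) over crystal ops."""
        if "images" not in self._truth_cache:
            ops = self.sg.ops_orth(self.cell)
            images = []
            for comp, pl in self.truths:
                X = self.clouds[comp]
                per_op = []
                for Rh, th in ops:
                    R = Rh @ pl.rot
                    t = Rh @ pl.trans + th
                    per_op.append((R, t, X @ R.T + t))
                images.append(per_op)
            self._truth_cache["images"] = images
        return self._truth_cache["images"]

    def _model_arrays(self, model) -> tuple:
        """(coords, shared-resid index into cloud, weight) for a model."""
        comp = model.component_id
        L = len(self.clouds[comp])
        resids = model.resids
        keep = resids < L
        return model.coords[keep], resids[keep], float(model.weight)

    def _ov_rigid(self, Xp: np.ndarray, Rp: np.ndarray,
                  Y: np.ndarray) -> float:
        """Gaussian overlap of placed model atoms onto one truth image."""
        diff = Xp - Y
        f = diff @ self.cell.frac.T
        shift = self.cell.orth @ np.round(f.mean(axis=0))
        d2 = ((diff - shift) ** 2).sum(axis=1)
        e = np.exp(-d2 / (2.0 * self.sigma ** 2))
        # far-field cutoff: beyond 6 sigma the Gaussian tail carries no
        # signal, and exact zeros keep unrelated placements from
        # accumulating meaningless sub-float score gains
        e[d2 > (6.0 * self.sigma) ** 2] = 0.0
        return float(e.mean())

    def _overlap_matrix(self, placements, models, sol_sg: SpaceGroupInfo,
                        delta: np.ndarray) -> np.ndarray:
        """O[p, k]: orbit-mean overlap of placement p onto truth k."""
        sol_ops = sol_sg.ops_orth(self.cell)
        images = self._truth_images()
        n_p, n_k = len(placements), len(self.truths)
        O = np.zeros((n_p, n_k))
        for ip, (pl, model) in enumerate(zip(placements, models)):
            Xm, shared, _w = self._model_arrays(model)
            for ik, (comp, _tp) in enumerate(self.truths):
                if comp != pl.component_id:
                    continue
                total = 0.0
                for Rg, tg in sol_ops:
                    Rpg = Rg @ pl.rot
                    tpg = Rg @ (pl.trans + delta) + tg
                    Xp = Xm @ Rpg.T + tpg
                    best = 0.0
                    for Rimg, timg, Yfull in images[ik]:
                        if rotation_angle_between(Rpg, Rimg) > ROT_PREFILTER_DEG:
                            continue
                        ov = self._ov_rigid(Xp, Rpg, Yfull[shared])
                        best = max(best, ov)
                    total += best
                O[ip, ik] = total / len(sol_ops)
        return O

    @staticmethod
    def _greedy_match(O: np.ndarray) -> list:
        """Greedy best-overlap matching without truth reuse."""
        n_p, n_k = O.shape
        work = O.copy()
        match = [-1] * n_p
        for _ in range(min(n_p, n_k)):
            ip, ik = np.unravel_index(np.argmax(work), work.shape)
            if work[ip, ik] <= 0.0:
                break
            match[ip] = int(ik)
            work[ip, :] = -1.0
            work[:, ik] = -1.0
        return match

    # -- clash counting -----------------------------------------------------

    def _clashes(self, placements, models, sol_sg: SpaceGroupInfo,
                 distance: float = CLASH_DISTANCE):
        """Total clash count and per-pair counts over symmetry images."""
        sol_ops = sol_sg.ops_orth(self.cell)
        coords = [m.coords @ p.rot.T + p.trans
                  for p, m in zip(placements, models)]
        F, O = self.cell.frac, self.cell.orth
        per_pair: dict = {}
        for i in range(len(placements)):
            for j in range(i, len(placements)):
                count = 0
                for gi, (Rg, tg) in enumerate(sol_ops):
                    if i == j and gi == 0:
                        continue
                    img = coords[j] @ Rg.T + tg
                    diff = coords[i][:, None, :] - img[None, :, :]
                    f = diff @ F.T
                    f -= np.round(f)
                    d2 = ((f @ O.T) ** 2).sum(axis=2)
                    count += int((d2 < distance ** 2).sum())
                if count:
                    per_pair[(i, j)] = count
        return sum(per_pair.values()), per_pair

    def packing_check(self, placements, models, sol_sg=None):
        """Packing function: clash test against all symmetry images."""
        sol_sg = self._sol_sg(sol_sg)
        total, per_pair = self._clashes(placements, models, sol_sg)
        passes = True
        for (i, j), count in per_pair.items():
            smaller = min(len(models[i]), len(models[j]))
            if count > CLASH_FRACTION * smaller:
                passes = False
                break
        return passes, total

    # -- score noise --------------------------------------------------------

    def _placement_noise(self, pl: Placement, weight: float) -> float:
        if self.epsilon == 0.0:
            return 0.0
        pos_bin, rot_bin = _pose_bins(pl.rot, pl.trans)
        key = pos_bin + rot_bin + (_str_key(pl.model_id),
                                   _str_key(pl.component_id))
        cols = [np.array([k], dtype=np.int64) for k in key]
        z = hash_normal(cols, self.seed)[0]
        return float(self.epsilon * weight * z)

    # -- the LLG analogue ---------------------------------------------------

    def _origin_candidates(self, placements, models,
                           sol_sg: SpaceGroupInfo) -> list:
        """Candidate global origin moves (orthogonal A vectors)."""
        O, F = self.cell.orth, self.cell.frac
        polar = np.array(self.sg.polar_axes)
        discrete = [O @ s for s in self.sg.origin_shifts]
        if not polar.any():
            return discrete
        # anchor continuous components on placement->truth centroid gaps
        anchors = [np.zeros(3)]
        images = self._truth_images()
        sol_ops = sol_sg.ops_orth(self.cell)
        for pl, model in zip(placements, models):
            Xm, shared, _ = self._model_arrays(model)
            if not len(Xm):
                continue
            cm = Xm.mean(axis=0)
            for ik, (comp, _t) in enumerate(self.truths):
                if comp != pl.component_id:
                    continue
                for Rg, tg in sol_ops:
                    Rpg = Rg @ pl.rot
                    for Rimg, timg, Yfull in images[ik]:
                        if rotation_angle_between(Rpg, Rimg) > ROT_PREFILTER_DEG:
                            continue
                        # Rg (t + d) + tg ~ t_img  (at matching centroids)
                        ct = Yfull[shared].mean(axis=0) if len(shared) else timg
                        need = Rg.T @ (ct - Rpg @ cm - tg) - pl.trans
                        adj = np.where(polar, F @ need, 0.0)
                        anchors.append(O @ adj)
        # dedupe anchors on a 0.5 A grid, deterministic order
        seen, uniq = set(), []
        for a in anchors:
            k = tuple(np.round(a * 2).astype(int).tolist())
            if k not in seen:
                seen.add(k)
                uniq.append(a)
        return [d + a for d in discrete for a in uniq[:40]]

    def score(self, placements, models, sol_sg=None,
              refine_polar: bool = True) -> ScoreReport:
        """The mock LLG of a set of placements (the comparable score)."""
        sol_sg = self._sol_sg(sol_sg)
        placements = list(placements)
        models = list(models)
        if not placements:
            return ScoreReport(0.0, (), (), 0)
        weights = [float(m.weight) for m in models]
        wbar = float(np.mean(weights))
        _total_clash, per_pair = self._clashes(placements, models, sol_sg)
        clash = sum(per_pair.values())
        noise = sum(self._placement_noise(p, w)
                    for p, w in zip(placements, weights))

        def matched_total(delta):
            O = self._overlap_matrix(placements, models, sol_sg, delta)
            match = self._greedy_match(O)
            ovs = [O[ip, k] if k >= 0 else 0.0 for ip, k in enumerate(match)]
            return sum(w * o for w, o in zip(weights, ovs)), ovs, match

        best = (-np.inf, None, None, None)
        for delta in self._origin_candidates(placements, models, sol_sg):
            tot, ovs, match = matched_total(delta)
            if tot > best[0]:
                best = (tot, ovs, match, delta)
        tot, ovs, match, delta = best

        polar = np.array(self.sg.polar_axes)
        if refine_polar and polar.any() and tot > 0:
            delta = self._refine_polar(delta, polar,
                                       lambda d: matched_total(d)[0])
            tot, ovs, match = matched_total(delta)

        llg = tot - 0.5 * wbar * clash + noise
        return ScoreReport(float(llg), tuple(ovs), tuple(match), clash,
                           tuple(delta))

    def _refine_polar(self, delta, polar, objective,
                      span: float = 2.0, tol: float = 0.01):
        """Golden-section refinement along each continuous origin axis."""
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        axes_orth = [self.cell.orth[:, i] / np.linalg.norm(self.cell.orth[:, i])
                     for i in range(3)]
        d = np.array(delta, dtype=float)
        for axis in range(3):
            if not polar[axis]:
                continue
            u = axes_orth[axis]
            a, b = -span, span
            fa = objective(d + a * u)
            fb = objective(d + b * u)
            x1 = b - gr * (b - a)
            x2 = a + gr * (b - a)
            f1, f2 = objective(d + x1 * u), objective(d + x2 * u)
            while b - a > tol:
                if f1 < f2:
                    a, x1, f1 = x1, x2, f2
                    x2 = a + gr * (b - a)
                    f2 = objective(d + x2 * u)
                else:
                    b, x2, f2 = x2, x1, f1
                    x1 = b - gr * (b - a)
                    f1 = objective(d + x1 * u)
            d = d + 0.5 * (a + b) * u
        return d

    # -- searches -----------------------------------------------------------

    def _unmatched_truths(self, partial_placements, partial_models,
                          sol_sg) -> list:
        if not partial_placements:
            return list(range(len(self.truths)))
        report = self.score(partial_placements, partial_models, sol_sg)
        used = {k for k in report.matched_truth_indices if k >= 0}
        return [k for k in range(len(self.truths)) if k not in used]

    def rotation_search(self, model, partial_placements=(),
                        partial_models=(), sol_sg=None, n_keep: int = 5,
                        step_deg: float = 15.0) -> list:
        """Ranked orientations with a rotation-function Z-score analogue."""
        sol_sg = self._sol_sg(sol_sg)
        grid = so3_grid(step_deg)
        if grid.size == 0:
            raise GenerationError("empty rotation grid")
        unmatched = self._unmatched_truths(partial_placements,
                                           partial_models, sol_sg)
        comp = model.component_id
        targets = []
        images = self._truth_images()
        for k in unmatched:
            if self.truths[k][0] != comp:
                continue
            for Rimg, _t, _Y in images[k]:
                targets.append(_quat_of_matrix(Rimg))
        if targets:
            T = np.array(targets)
            dots = np.abs(grid @ T.T).clip(max=1.0)
            dtheta = 2.0 * np.degrees(np.arccos(dots)).min(axis=1)
            scores = np.exp(-dtheta ** 2 / (2.0 * self.sigma_rot ** 2))
        else:
            scores = np.zeros(len(grid))
        if self.epsilon > 0.0:
            rv = Rotation.from_quat(grid).as_rotvec(degrees=True)
            bins = np.round(rv / ROT_BIN).astype(np.int64)
            cols = [bins[:, 0], bins[:, 1], bins[:, 2],
                    np.full(len(grid), _str_key(model.model_id),
                            dtype=np.int64)]
            scores = scores + self.epsilon * hash_normal(cols, self.seed)
        sd = scores.std()
        z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
        order = np.argsort(-scores, kind="stable")[:n_keep]
        return [(Rotation.from_quat(grid[i]).as_matrix(), float(z[i]))
                for i in order]

    def translation_search(self, model, orientation, partial_placements=(),
                           partial_models=(), sol_sg=None,
                           grid_step: float = 2.0, n_peaks: int = 10) -> list:
        """Translation-function landscape on a fractional grid.

        The raw value at each grid point is the overlap gain of adding
        the oriented model there (fixed truth matching; clashes are
        judged by the separate packing step, and the exact score of
        surviving peaks is recomputed by ``score``). The TFZ analogue
        standardizes raw over the whole grid.
        """
        sol_sg = self._sol_sg(sol_sg)
        O, F = self.cell.orth, self.cell.frac
        lengths = self.cell.lengths
        ns = [max(2, int(np.ceil(l / grid_step))) for l in lengths]
        fr = [np.arange(n) / n for n in ns]
        gx, gy, gz = np.meshgrid(*fr, indexing="ij")
        tf = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        G = len(tf)

        unmatched = self._unmatched_truths(partial_placements,
                                           partial_models, sol_sg)
        raw = np.zeros(G)
        members = getattr(model, "composite_members", None) or \
            ((model, np.eye(3), np.zeros(3)),)
        sol_ops = sol_sg.ops_orth(self.cell)
        images = self._truth_images()
        two_sig2 = 2.0 * self.sigma ** 2
        for mem, rel_rot, rel_trans in members:
            Xm, shared, w = self._model_arrays(mem)
            Rmem = orientation @ rel_rot
            Xbase = Xm @ Rmem.T + orientation @ rel_trans
            acc_g = np.zeros(G)
            for Rg, tg in sol_ops:
                Rpg = Rg @ Rmem
                base = Xbase @ Rg.T + tg
                best = np.zeros(G)
                for k in unmatched:
                    if self.truths[k][0] != mem.component_id:
                        continue
                    for Rimg, _timg, Yfull in images[k]:
                        if rotation_angle_between(Rpg, Rimg) > ROT_PREFILTER_DEG:
                            continue
                        W = (base - Yfull[shared]) @ F.T        # (N, 3)
                        Mg = F @ Rg @ O                          # frac rot
                        E = tf @ Mg.T                            # (G, 3)
                        for lo in range(0, G, 4096):
                            hi = min(G, lo + 4096)
                            S = W[None, :, :] + E[lo:hi, None, :]
                            S -= np.round(S)
                            d2 = ((S @ O.T) ** 2).sum(axis=2)
                            np.maximum(best[lo:hi],
                                       np.exp(-d2 / two_sig2).mean(axis=1),
                                       out=best[lo:hi])
                acc_g += best
            raw += w * acc_g / len(sol_ops)

        # clash handling is the packing function's job (a separate step):
        # folding the clash penalty into the landscape would let the
        # occupied half of the cell dominate the grid statistics and
        # destroy the TFZ contrast of genuine peaks
        if self.epsilon > 0.0:
            total_w = sum(self._model_arrays(m)[2] for m, _r, _t in members)
            pos = tf @ O.T
            bins = np.round(pos / POS_BIN).astype(np.int64)
            rv = Rotation.from_matrix(orientation).as_rotvec(degrees=True)
            rb = np.round(rv / ROT_BIN).astype(np.int64)
            cols = [bins[:, 0], bins[:, 1], bins[:, 2],
                    np.full(G, rb[0]), np.full(G, rb[1]), np.full(G, rb[2]),
                    np.full(G, _str_key(model.model_id), dtype=np.int64)]
            raw = raw + self.epsilon * total_w * hash_normal(cols, self.seed)

        sd = raw.std()
        tfz = (raw - raw.mean()) / sd if sd > 1e-12 else np.zeros_like(raw)

        vol = raw.reshape(ns)
        local_max = vol >= ndimage.maximum_filter(vol, size=3, mode="wrap")
        idx = np.flatnonzero(local_max.ravel())
        idx = idx[np.argsort(-raw[idx], kind="stable")][:n_peaks]
        peaks = []
        for i in idx:
            t_orth = O @ tf[i]
            pose = self._snap_peak(members, orientation, t_orth, unmatched,
                                   grid_step)
            peaks.append(Peak(
                placement=Placement(model.component_id, model.model_id,
                                    pose[0], pose[1]),
                raw=float(raw[i]), tfz=float(tfz[i])))
        return peaks

    def _snap_peak(self, members, orientation, t_orth, unmatched,
                   grid_step):
        """Interpolate a grid peak to the sub-grid rigid optimum.

        The search grids are coarse (translation step ~2 A, rotation
        step ~15 deg); reported peaks are polished to the local overlap
        maximum within one grid cell so that peak categorization and
        packing judge the actual solution, not its lattice rounding.
        """
        images = self._truth_images()
        sol_ops = self.sg.ops_orth(self.cell)
        # image prefiltering is done once: the pose moves by at most
        # ~12 deg during interpolation, well inside the 60 deg cutoff
        tasks = []
        for mem, rel_rot, rel_trans in members:
            Xm, shared, w = self._model_arrays(mem)
            for Rg, tg in sol_ops:
                Rpg0 = Rg @ orientation @ rel_rot
                ys = []
                for k in unmatched:
                    if self.truths[k][0] != mem.component_id:
                        continue
                    for Rimg, _ti, Yfull in images[k]:
                        if rotation_angle_between(Rpg0, Rimg) \
                                <= ROT_PREFILTER_DEG:
                            ys.append(Yfull[shared])
                if ys:
                    tasks.append((Xm, rel_rot, rel_trans, w, Rg, tg, ys))
        if not tasks:
            return orientation, t_orth
        n_ops = len(sol_ops)

        def objective(x):
            R = orientation @ Rotation.from_rotvec(
                np.radians(x[:3])).as_matrix()
            t = t_orth + x[3:]
            total = 0.0
            for Xm, rel_rot, rel_trans, w, Rg, tg, ys in tasks:
                Rmem = R @ rel_rot
                Xp = (Xm @ Rmem.T + R @ rel_trans + t) @ Rg.T + tg
                best = 0.0
                for Y in ys:
                    best = max(best, self._ov_rigid(Xp, None, Y))
                total += w * best / n_ops
            return -total

        span = 1.5 * grid_step
        res = minimize(objective, np.zeros(6), method="Powell",
                       bounds=[(-12.0, 12.0)] * 3 + [(-span, span)] * 3,
                       options={"xtol": 5e-2, "ftol": 1e-4, "maxiter": 3})
        R = orientation @ Rotation.from_rotvec(
            np.radians(res.x[:3])).as_matrix()
        return R, t_orth + res.x[3:]

    def snap_placement(self, model, placement: Placement,
                       partial_placements=(), partial_models=(),
                       sol_sg=None, span: float = 2.0) -> Placement:
        """Polish a proposed placement to its local overlap optimum.

        Predicted placements (assembly completion, amalgamation) enter
        the workflow like translation peaks, so they receive the same
        sub-grid rigid interpolation before packing and scoring.
        """
        sol_sg = self._sol_sg(sol_sg)
        unmatched = self._unmatched_truths(partial_placements,
                                           partial_models, sol_sg)
        members = getattr(model, "composite_members", None) or \
            ((model, np.eye(3), np.zeros(3)),)
        R, t = self._snap_peak(members, placement.rot, placement.trans,
                               unmatched, span / 1.5)
        return Placement(placement.component_id, placement.model_id, R, t)

    # -- fast score deltas (predictions, background) ------------------------

    def _delta_raw(self, partial_placements, partial_models,
                   additions, addition_models, sol_sg,
                   base_report: ScoreReport | None = None,
                   include_clash: bool = True) -> float:
        """Score gain of adding placements, at the parent's origin move."""
        sol_sg = self._sol_sg(sol_sg)
        if base_report is None:
            base_report = self.score(partial_placements, partial_models,
                                     sol_sg)
        delta = np.array(base_report.origin_shift)
        used = {k for k in base_report.matched_truth_indices if k >= 0}
        O = self._overlap_matrix(additions, addition_models, sol_sg, delta)
        O[:, sorted(used)] = 0.0
        match = self._greedy_match(O)
        gain = sum(float(m.weight) * (O[i, k] if k >= 0 else 0.0)
                   for i, (m, k) in enumerate(zip(addition_models, match)))
        if include_clash:
            all_m = list(partial_models) + list(addition_models)
            wbar = float(np.mean([m.weight for m in all_m]))
            new_clash = 0
            for i, (pl, m) in enumerate(zip(additions, addition_models)):
                others = list(partial_placements) + list(additions[:i])
                omods = list(partial_models) + list(addition_models[:i])
                new_clash += self._clash_of_one(pl, m, others, omods, sol_sg)
            gain -= 0.5 * wbar * new_clash
        gain += sum(self._placement_noise(p, m.weight)
                    for p, m in zip(additions, addition_models))
        return float(gain)

    def background_zscore(self, partial_placements, partial_models,
                          additions, addition_models, sol_sg=None,
                          n_samples: int = 200, seed: int = 0) -> float:
        """Z of a candidate's score gain against random placements.

        The background distribution re-places the same models at
        seeded random poses. Used to identify clear non-search
        solutions (predictions, amalgamations) that never went through
        a translation search.
        """
        if n_samples < 50:
            raise ValueError("background_zscore needs n_samples >= 50")
        sol_sg = self._sol_sg(sol_sg)
        base = self.score(partial_placements, partial_models, sol_sg)
        # the Z measures overlap significance; clashes are the packing
        # function's business and would otherwise dominate the spread of
        # the random background in a tightly packed cell
        cand = self._delta_raw(partial_placements, partial_models,
                               additions, addition_models, sol_sg, base,
                               include_clash=False)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF,
                                    seed & 0x7FFFFFFF, 0x6261636b]))
        samples = np.empty(n_samples)
        for s in range(n_samples):
            rand = []
            for pl in additions:
                R = Rotation.random(random_state=rng).as_matrix()
                t = self.cell.orth @ rng.random(3)
                rand.append(Placement(pl.component_id, pl.model_id, R, t))
            samples[s] = self._delta_raw(partial_placements, partial_models,
                                         rand, addition_models, sol_sg, base,
                                         include_clash=False)
        sd = samples.std()
        if sd < 1e-12:
            return 0.0
        return float((cand - samples.mean()) / sd)

    # -- rigid-body refinement ----------------------------------------------

    def rigid_refine(self, placements, models, sol_sg=None, scope: str = "all",
                     max_rot: float = 15.0, max_shift: float = 5.0,
                     tol: float = 1e-4, max_sweeps: int = 10):
        """Derivative-free local maximization of the score.

        Each in-scope placement is optimized over 6 rigid-body
        parameters (small-angle rotation vector about the current
        orientation, bounded to +-15 deg / +-5 A) with Powell's method;
        sweeps repeat until the total score improves by less than
        ``tol``. The smooth part of the score (overlap + clash) drives
        the optimization; binned score noise re-enters in the final
        report.
        """
        sol_sg = self._sol_sg(sol_sg)
        placements = list(placements)
        idx_scope = (range(len(placements)) if scope == "all"
                     else [len(placements) - 1])
        report = self.score(placements, models, sol_sg)
        delta = np.array(report.origin_shift)
        sol_ops = sol_sg.ops_orth(self.cell)
        images = self._truth_images()
        weights = [float(m.weight) for m in models]
        wbar = float(np.mean(weights))
        warn = False

        def smooth_single(ip, pl):
            """w*OV of one placement against its matched truth - clashes."""
            k = report.matched_truth_indices[ip] \
                if ip < len(report.matched_truth_indices) else -1
            model = models[ip]
            Xm, shared, w = self._model_arrays(model)
            total = 0.0
            if k >= 0:
                for Rg, tg in sol_ops:
                    Rpg = Rg @ pl.rot
                    tpg = Rg @ (pl.trans + delta) + tg
                    Xp = Xm @ Rpg.T + tpg
                    best = 0.0
                    for Rimg, _timg, Yfull in images[k]:
                        if rotation_angle_between(Rpg, Rimg) > ROT_PREFILTER_DEG:
                            continue
                        best = max(best, self._ov_rigid(Xp, Rpg,
                                                        Yfull[shared]))
                    total += best
                total = w * total / len(sol_ops)
            others = [q for jq, q in enumerate(placements) if jq != ip]
            omods = [models[jq] for jq in range(len(placements)) if jq != ip]
            clash = self._clash_of_one(pl, model, others, omods, sol_sg)
            return total - 0.5 * wbar * clash

        prev_total = None
        for _sweep in range(max_sweeps):
            for ip in idx_scope:
                pl0 = placements[ip]

                def objective(x, ip=ip, pl0=pl0):
                    R = pl0.rot @ Rotation.from_rotvec(
                        np.radians(x[:3])).as_matrix()
                    pl = Placement(pl0.component_id, pl0.model_id,
                                   R, pl0.trans + x[3:])
                    return -smooth_single(ip, pl)

                res = minimize(
                    objective, np.zeros(6), method="Powell",
                    bounds=[(-max_rot, max_rot)] * 3
                    + [(-max_shift, max_shift)] * 3,
                    options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 40})
                x = res.x
                R = pl0.rot @ Rotation.from_rotvec(np.radians(x[:3])).as_matrix()
                placements[ip] = Placement(pl0.component_id, pl0.model_id,
                                           R, pl0.trans + x[3:])
            new = self.score(placements, models, sol_sg)
            if prev_total is not None and new.llg - prev_total < tol:
                report = new
                break
            prev_total = new.llg
            report = new
        else:
            warn = True
        return placements, report, warn

    def _clash_of_one(self, pl, model, others, other_models, sol_sg):
        sol_ops = sol_sg.ops_orth(self.cell)
        F, O = self.cell.frac, self.cell.orth
        X = model.coords @ pl.rot.T + pl.trans
        count = 0
        r_self = X - X.mean(axis=0)
        reach = float(np.linalg.norm(r_self, axis=1).max()) + CLASH_DISTANCE
        for gi, (Rg, tg) in enumerate(sol_ops):
            if gi > 0:
                img = X @ Rg.T + tg
                count += self._pair_clash(X, img, F, O)
        for q, qm in zip(others, other_models):
            Y = qm.coords @ q.rot.T + q.trans
            reach_q = reach + float(np.linalg.norm(
                Y - Y.mean(axis=0), axis=1).max())
            for Rg, tg in sol_ops:
                img = Y @ Rg.T + tg
                dc = X.mean(axis=0) - img.mean(axis=0)
                f = F @ dc
                f -= np.round(f)
                if np.linalg.norm(O @ f) > reach_q:
                    continue
                count += self._pair_clash(X, img, F, O)
        return count

    @staticmethod
    def _pair_clash(X, Y, F, O):
        diff = X[:, None, :] - Y[None, :, :]
        f = diff @ F.T
        f -= np.round(f)
        d2 = ((f @ O.T) ** 2).sum(axis=2)
        return int((d2 < CLASH_DISTANCE ** 2).sum())


# ---------------------------------------------------------------------------
# crystal generation
# ---------------------------------------------------------------------------

def _cell_for(space_group: str, volume: float) -> UnitCell:
    sg = build_space_group(space_group)
    if sg.point_group == "4":            # tetragonal: a = b
        c = 1.1 * volume ** (1.0 / 3.0)
        a = np.sqrt(volume / c)
        return UnitCell(a, a, c)
    s = volume ** (1.0 / 3.0)
    a, b = 0.93 * s, 1.0 * s
    return UnitCell(a, b, volume / (a * b))


def _orbit_placements(comp_id: str, group: str, axis: np.ndarray,
                      center: np.ndarray, radius: float,
                      base_rot: np.ndarray) -> list:
    """Exact point-group orbit of one member around (axis, center)."""
    order = int(group[1:])
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    first = Placement(comp_id, f"truth:{comp_id}", base_rot,
                      center + radius * perp)
    out = []
    gens = []
    for k in range(order):
        gens.append(rotation_from_angle_axis(360.0 * k / order, axis))
    if group.startswith("D"):
        flip = rotation_from_angle_axis(180.0, perp)
        gens = gens + [g @ flip for g in gens]
    for g in gens:
        rot = g @ first.rot
        trans = g @ (first.trans - center) + center
        out.append(Placement(comp_id, first.model_id, rot, trans))
    return out


def _ring_radius(cloud: np.ndarray, group: str, comp_id: str) -> float:
    """Smallest orbit radius whose members keep the packing clearance.

    The assembly is rigid during crystal relaxation, so its internal
    geometry must be clash-free (at the generator's margin) from the
    start; the smallest such radius keeps the assembly footprint
    compact enough to pack at the target solvent fraction.
    """
    d_need = CLASH_DISTANCE + GEN_CLASH_MARGIN
    r_mol = float(np.linalg.norm(cloud, axis=1).max())
    axis = np.array([0.0, 0.0, 1.0])
    center = np.zeros(3)
    r = 0.3 * r_mol
    while r < 20.0 * r_mol:
        pls = _orbit_placements(comp_id, group, axis, center, r, np.eye(3))
        coords = [cloud @ p.rot.T + p.trans for p in pls]
        ok = True
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                diff = coords[i][:, None, :] - coords[j][None, :, :]
                if (np.linalg.norm(diff, axis=2) < d_need).any():
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return r
        r += 0.5
    raise GenerationError(f"cannot build a clash-free {group} ring")


@dataclass
class GeneratedCase:
    """A generated crystal plus the inputs a search would start from."""

    crystal: ToyCrystal
    components: dict          # component_id -> ComponentSpec
    templates: dict           # component_id -> EnsembleModel (perturbed)
    genspec: GenSpec
    seed: int


_AA = "ACDEFGHIKLMNPQRSTVWY"


def generate_crystal(genspec: GenSpec, seed: int,
                     max_attempts: int = 1000) -> GeneratedCase:
    """Build a toy crystal honouring the generation spec.

    Components are compact self-avoiding C-alpha clouds; the cell is
    sized from total weight and the target solvent fraction via the
    Matthews relation; truths are placed by seeded rejection-plus-
    relaxation until the packing function passes; assembly copies sit
    exactly on their point-group orbit. Emits per-component sequences
    and perturbed template models alongside the ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0x746F79]))
    sg = build_space_group(genspec.space_group)
    comps, clouds, weights = {}, {}, {}
    for cg in genspec.components:
        seq = "".join(rng.choice(list(_AA)) for _ in range(cg.length))
        spec = ComponentSpec(cg.component_id, seq)
        comps[cg.component_id] = spec
        clouds[cg.component_id] = compact_chain(cg.length, rng)
        weights[cg.component_id] = spec.mw

    from .composition import MATTHEWS_PROTEIN_CONST
    asu_mass = sum(weights[cg.component_id] * cg.copies
                   for cg in genspec.components)
    vm = MATTHEWS_PROTEIN_CONST / (1.0 - genspec.solvent_target)
    volume = vm * sg.n_ops * asu_mass
    cell = _cell_for(genspec.space_group, volume)

    crystal = ToyCrystal(cell=cell, sg=sg, truths=(), clouds=clouds,
                         weights=weights, sigma=genspec.sigma,
                         sigma_rot=genspec.sigma_rot,
                         epsilon=genspec.epsilon, seed=seed)

    # units: assemblies move rigidly, monomers individually
    units = []
    for cg in genspec.components:
        if cg.assembly:
            order = int(cg.assembly[1:]) * (2 if cg.assembly[0] == "D" else 1)
            if cg.copies % order:
                raise GenerationError(
                    f"{cg.copies} copies cannot form {cg.assembly} "
                    f"assemblies (orbit size {order})")
            radius = _ring_radius(clouds[cg.component_id], cg.assembly,
                                  cg.component_id)
            for _ in range(cg.copies // order):
                units.append(("assembly", cg, radius))
        else:
            for _ in range(cg.copies):
                units.append(("single", cg, 0.0))

    for restart in range(5):
        placed = _try_place_units(units, crystal, comps, rng, max_attempts)
        if placed is not None:
            crystal.truths = tuple((p.component_id, p) for p in placed)
            break
    else:
        raise GenerationError(
            "cannot place the requested contents without clashes")

    templates = {}
    for cg in genspec.components:
        cid = cg.component_id
        L = cg.length
        noise = genspec.template_noise * rng.normal(size=(L, 3))
        cs = CoordSet(np.arange(L), clouds[cid] + noise, np.full(L, 20.0))
        templates[cid] = EnsembleModel(
            model_id=f"{cid}:template", component_id=cid, members=(cs,),
            coverage=CoverageSet.full(L), weight=weights[cid],
            source_template_id=f"tmpl_{cid}", protocol_id="generated")
    return GeneratedCase(crystal=crystal, components=comps,
                         templates=templates, genspec=genspec, seed=seed)


class _TruthModel:
    """Minimal model-like view of a true component cloud."""

    def __init__(self, comp_id, cloud, weight):
        self.component_id = comp_id
        self.model_id = f"truth:{comp_id}"
        self.coords = cloud
        self.resids = np.arange(len(cloud))
        self.weight = weight

    def __len__(self):
        return len(self.coords)


def truth_models(crystal: ToyCrystal) -> list:
    """Model-like objects for the ground-truth placements, in order."""
    return [_TruthModel(c, crystal.clouds[c], crystal.weights[c])
            for c, _p in crystal.truths]


def _try_place_units(units, crystal: ToyCrystal, comps, rng,
                     max_attempts: int):
    """Random placement followed by rigid-body clash relaxation.

    Units (single molecules, or whole assemblies moving rigidly) are
    dropped at random poses; their translations and orientations are
    then relaxed by minimizing a soft-sphere overlap energy over all
    symmetry images (analytic forces and torques, periodic KD-tree
    neighbour search) until the packing function passes at the
    generator's clearance. Returns None when relaxation fails.
    """
    from scipy.optimize import minimize as _minimize
    from scipy.spatial import cKDTree

    cell, sg = crystal.cell, crystal.sg
    O, F = cell.orth, cell.frac
    if not np.allclose(O, np.diag(np.diag(O))):
        raise GenerationError("generator cells must be orthogonal")
    L = np.diag(O).copy()
    sol_ops = sg.ops_orth(cell)
    d_cut = CLASH_DISTANCE + GEN_CLASH_MARGIN + 0.3

    placements: list[Placement] = []
    unit_of: list[int] = []

    def unit_atoms(kind, cg, radius, base_rot, center, axis):
        if kind == "assembly":
            group = _orbit_placements(cg.component_id, cg.assembly, axis,
                                      center, radius, base_rot)
        else:
            group = [Placement(cg.component_id, f"truth:{cg.component_id}",
                               base_rot, center)]
        cloud = crystal.clouds[cg.component_id]
        xyz = np.concatenate([cloud @ p.rot.T + p.trans for p in group])
        return group, xyz

    def overlap_count(xyz, existing):
        """Neighbour count of candidate atoms vs placed content + images."""
        from scipy.spatial import cKDTree as _T
        count = 0
        pool = [existing] if existing is not None and len(existing) else []
        pool.append(xyz)
        allpts = np.concatenate(pool)
        for gi, (Rg, tg) in enumerate(sol_ops):
            img = allpts @ Rg.T + tg
            imgw = (img @ F.T % 1.0) * L
            tree = _T(imgw, boxsize=L)
            posw = (xyz @ F.T % 1.0) * L
            n = int(tree.query_ball_point(posw, d_cut,
                                          return_length=True).sum())
            if gi == 0:
                n -= len(xyz)        # self matches
            count += n
        return count

    # greedy insertion: each unit tries several seeded poses and keeps
    # the least-overlapping one as the relaxation start
    existing = None
    for ui, (kind, cg, radius) in enumerate(units):
        best = None
        for _try in range(30):
            base_rot = Rotation.random(random_state=rng).as_matrix()
            center = O @ rng.random(3)
            axis = (np.array(cg.assembly_axis, dtype=float)
                    if cg.assembly_axis is not None
                    else rng.normal(size=3))
            group, xyz = unit_atoms(kind, cg, radius, base_rot, center, axis)
            n_ov = overlap_count(xyz, existing)
            if best is None or n_ov < best[0]:
                best = (n_ov, group, xyz)
            if n_ov == 0:
                break
        _n, group, xyz = best
        placements.extend(group)
        unit_of.extend([ui] * len(group))
        existing = xyz if existing is None else np.concatenate([existing,
                                                                xyz])

    models = [_TruthModel(p.component_id, crystal.clouds[p.component_id],
                          crystal.weights[p.component_id])
              for p in placements]
    probe = ToyCrystal(cell=cell, sg=sg, truths=(), clouds=crystal.clouds,
                       weights=crystal.weights, epsilon=0.0)
    n_units = len(units)
    unit_of = np.array(unit_of)

    # flat atom arrays
    atom_xyz = []
    atom_pl = []
    for ip, (p, m) in enumerate(zip(placements, models)):
        atom_xyz.append(m.coords @ p.rot.T + p.trans)
        atom_pl.extend([ip] * len(m))
    atoms = np.concatenate(atom_xyz)
    atom_pl = np.array(atom_pl)
    atom_unit = unit_of[atom_pl]
    rots = [p.rot.copy() for p in placements]
    trans = [p.trans.copy() for p in placements]

    def unit_centers():
        return np.array([atoms[atom_unit == u].mean(axis=0)
                         for u in range(n_units)])

    def energy_grad(x, centers, cut=d_cut):
        dx = x.reshape(n_units, 6)
        dt, dw = dx[:, :3], dx[:, 3:]
        Rs = Rotation.from_rotvec(dw).as_matrix()       # (U, 3, 3)
        rel = atoms - centers[atom_unit]
        pos = np.einsum("aij,aj->ai", Rs[atom_unit], rel) \
            + centers[atom_unit] + dt[atom_unit]
        E = 0.0
        gt = np.zeros((n_units, 3))
        gw = np.zeros((n_units, 3))
        posw = (pos @ F.T % 1.0) * L
        for gi, (Rg, tg) in enumerate(sol_ops):
            img = pos @ Rg.T + tg
            imgw = (img @ F.T % 1.0) * L
            tree = cKDTree(imgw, boxsize=L)
            pairs = tree.query_ball_point(posw, cut)
            ia, ib = [], []
            for a, lst in enumerate(pairs):
                for b in lst:
                    if gi == 0 and atom_pl[a] == atom_pl[b]:
                        continue
                    ia.append(a)
                    ib.append(b)
            if not ia:
                continue
            ia = np.array(ia)
            ib = np.array(ib)
            v = posw[ia] - imgw[ib]
            v -= L * np.round(v / L)
            d = np.linalg.norm(v, axis=1)
            d[d < 1e-6] = 1e-6
            pen = cut - d
            keep = pen > 0
            ia, ib, v, d, pen = ia[keep], ib[keep], v[keep], d[keep], pen[keep]
            if not len(ia):
                continue
            E += float((pen ** 2).sum())
            vhat = v / d[:, None]
            f = 2.0 * pen[:, None] * vhat        # force pushing a from b
            np.add.at(gt, atom_unit[ia], -f)
            np.add.at(gt, atom_unit[ib], f @ Rg)
            arm_a = pos[ia] - centers[atom_unit[ia]]
            np.add.at(gw, atom_unit[ia], np.cross(arm_a, -f))
            arm_b = pos[ib] - centers[atom_unit[ib]]
            np.add.at(gw, atom_unit[ib], np.cross(arm_b, f @ Rg))
        return E, np.concatenate([gt, gw], axis=1).ravel()

    def apply(x, centers):
        nonlocal atoms
        dx = x.reshape(n_units, 6)
        dt, dw = dx[:, :3], dx[:, 3:]
        Rs = Rotation.from_rotvec(dw).as_matrix()
        rel = atoms - centers[atom_unit]
        atoms = np.einsum("aij,aj->ai", Rs[atom_unit], rel) \
            + centers[atom_unit] + dt[atom_unit]
        for ip in range(len(placements)):
            u = unit_of[ip]
            rots[ip] = Rs[u] @ rots[ip]
            trans[ip] = Rs[u] @ (trans[ip] - centers[u]) + centers[u] + dt[u]

    # annealed clearance: relax at growing cutoffs so jams untangle
    for frac in (0.6, 0.8):
        centers = unit_centers()
        res = _minimize(energy_grad, np.zeros(n_units * 6), jac=True,
                        args=(centers, frac * d_cut), method="L-BFGS-B",
                        options={"maxiter": 60, "ftol": 1e-12,
                                 "gtol": 1e-10})
        apply(res.x, centers)

    prev_e = np.inf
    for _round in range(max(8, max_attempts // 40)):
        centers = unit_centers()
        res = _minimize(energy_grad, np.zeros(n_units * 6), jac=True,
                        args=(centers, d_cut), method="L-BFGS-B",
                        options={"maxiter": 80, "ftol": 1e-12,
                                 "gtol": 1e-10})
        apply(res.x, centers)
        final = [Placement(p.component_id, p.model_id, rots[ip], trans[ip])
                 for ip, p in enumerate(placements)]
        passes, _pp = _packing_state(probe, final, models)
        if passes:
            return final
        if res.fun > 0.95 * prev_e:
            # stuck in a local minimum: seeded translational kick
            kick = np.zeros((n_units, 6))
            kick[:, :3] = rng.normal(scale=2.0, size=(n_units, 3))
            apply(kick.ravel(), unit_centers())
            prev_e = np.inf
        else:
            prev_e = res.fun
    return None


def _packing_state(probe: ToyCrystal, placements, models):
    # the generator's own tolerance: a clearance margin beyond the clash
    # distance, so that models with realistic coordinate error placed on
    # true poses still pass the packing function
    total, per_pair = probe._clashes(placements, models, probe.sg,
                                     distance=CLASH_DISTANCE
                                     + GEN_CLASH_MARGIN)
    passes = all(c <= CLASH_FRACTION * min(len(models[i]), len(models[j]))
                 for (i, j), c in per_pair.items())
    return passes, per_pair


def make_model_variants(template: EnsembleModel, n: int, noise: float,
                        seed: int) -> list:
    """n independently perturbed copies of a template model.

    All variants share the template's coverage, weight and source
    identity; protocol ids run variant_1..variant_n.
    """
    if n < 1:
        raise ValueError("need n >= 1 variants")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                        0x766172]))
    out = []
    for i in range(1, n + 1):
        members = []
        for cs in template.members:
            pert = noise * rng.normal(size=cs.xyz.shape) if noise > 0 else 0.0
            members.append(CoordSet(cs.resids, cs.xyz + pert, cs.b))
        out.append(replace(template,
                           model_id=f"{template.source_template_id}:variant_{i}",
                           protocol_id=f"variant_{i}",
                           members=tuple(members)))
    return out
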
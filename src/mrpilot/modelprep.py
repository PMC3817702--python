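"""Search-model preparation.

Converts every stage of the model-input hierarchy (ready ensemble,
model collection, template + alignment, homology hit, bare sequence)
into ready-to-search ensembles: template editing protocols (atom
pruning and B-factor schemes), collection superposition with optional
trimming, and priority ordering of the resulting models.

Models are C-alpha only: the engine's decisions need rigid-body
geometry and scattering weights, nothing finer. The PDB reader accepts
full-atom files and extracts C-alpha positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import gemmi
import numpy as np

from .composition import (AlignmentPair, ComponentSpec, CoverageSet,
                          coverage_from_alignment, RESIDUE_MASS,
                          WATER_MASS)
from .symmetry import DegenerateSuperpositionError, kabsch_superpose


class ModelPrepError(ValueError):
    pass


@dataclass(frozen=True)
class CoordSet:
    """C-alpha coordinates of one model member, keyed by residue index."""

    resids: np.ndarray  # (N,) int, 0-based sequence positions
    xyz: np.ndarray     # (N, 3) Angstrom
    b: np.ndarray       # (N,) B values

    def __post_init__(self):
        resids = np.asarray(self.resids, dtype=int)
        xyz = np.asarray(self.xyz, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if not (len(resids) == len(xyz) == len(b)):
            raise ModelPrepError("resids, xyz and b must have equal length")
        for arr in (resids, xyz, b):
            arr.setflags(write=False)
        object.__setattr__(self, "resids", resids)
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "b", b)

    def __len__(self) -> int:
        return len(self.resids)

    def subset(self, mask: np.ndarray) -> "CoordSet":
        return CoordSet(self.resids[mask], self.xyz[mask], self.b[mask])


STAGES = ("ensemble", "collection", "template", "homology_hit",
          "sequence_only")
#: search priority: more specialized inputs first
_STAGE_PRIORITY = {s: i for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class ModelInput:
    """One model description at some stage of the input hierarchy."""

    component_id: str
    stage: str
    members: tuple = ()                 # tuple[CoordSet]
    alignment: AlignmentPair | None = None
    source_template_id: str | None = None
    identity: float | None = None       # homology hits: sequence identity

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ModelPrepError(f"unknown stage {self.stage!r}")
        if self.stage in ("template", "homology_hit") and self.alignment is None:
            raise ModelPrepError(f"{self.stage} input requires an alignment")


@dataclass(frozen=True)
class EnsembleModel:
    """A ready search model: superposed members, coverage, weight."""

    model_id: str
    component_id: str
    members: tuple                      # tuple[CoordSet], identical resids
    coverage: CoverageSet
    weight: float                       # Da of covered target sequence
    source_template_id: str
    protocol_id: str = "asis"

    def __post_init__(self):
        if not self.members:
            raise ModelPrepError("ensemble needs at least one member")
        ref = self.members[0].resids
        for m in self.members[1:]:
            if not np.array_equal(m.resids, ref):
                raise ModelPrepError("members must share residue indexing")
        if self.weight <= 0:
            raise ModelPrepError("ensemble weight must be positive")

    @property
    def coords(self) -> np.ndarray:
        """Representative coordinates (first member)."""
        return self.members[0].xyz

    @property
    def resids(self) -> np.ndarray:
        return self.members[0].resids

    def __len__(self) -> int:
        return len(self.members[0])


@dataclass(frozen=True)
class Protocol:
    """One template-editing protocol: pruning mode + B-factor scheme."""

    protocol_id: str
    prune_mode: str = "none"        # none | unaligned | unaligned_plus_lowid
    b_scheme: str = "asis"          # asis | constant | similarity

    def __post_init__(self):
        if self.prune_mode not in ("none", "unaligned", "unaligned_plus_lowid"):
            raise ModelPrepError(f"unknown prune mode {self.prune_mode!r}")
        if self.b_scheme not in ("asis", "constant", "similarity"):
            raise ModelPrepError(f"unknown B scheme {self.b_scheme!r}")


#: default protocol grid (redundant prune=none B-variant combinations folded)
DEFAULT_PROTOCOLS = (
    Protocol("keep_asis", "none", "asis"),
    Protocol("prune_asis", "unaligned", "asis"),
    Protocol("prune_bconst", "unaligned", "constant"),
    Protocol("prune_bsim", "unaligned", "similarity"),
    Protocol("prune_lowid_bconst", "unaligned_plus_lowid", "constant"),
    Protocol("prune_lowid_bsim", "unaligned_plus_lowid", "similarity"),
)

B_CONSTANT = 20.0
B_SIMILARITY_SLOPE = 60.0
LOWID_WINDOW = 9
LOWID_THRESHOLD = 0.2


def sequence_weight(target_seq: str, coverage: CoverageSet) -> float:
    """Da of the covered part of the target sequence (plus one water)."""
    mass = sum(RESIDUE_MASS[target_seq[i].upper()]
               for s, e in coverage.intervals for i in range(s, e))
    return mass + WATER_MASS if mass > 0 else 0.0


def _window_identity(al: AlignmentPair) -> np.ndarray:
    """Per-column identity over a sliding window of alignment columns."""
    n = len(al.columns)
    if al.matches is None:
        return np.full(n, al.identity)
    m = np.array(al.matches, dtype=float)
    half = LOWID_WINDOW // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = m[lo:hi].mean()
    return out


def edit_template(tmpl: ModelInput, al: AlignmentPair, proto: Protocol,
                  target_seq: str, model_id: str | None = None,
                  bridge_gap: int = 2) -> EnsembleModel:
    """Turn a raw template into a search ensemble under one protocol.

    Residues unpaired in the alignment are deleted (unless prune mode
    is ``none``); the low-identity mode additionally removes residues
    in sliding windows of identity below the threshold. B factors are
    kept, set constant, or mapped from window identity. Surviving
    residues are renumbered to target indexing and coverage recomputed.
    """
    if tmpl.stage not in ("template", "homology_hit", "ensemble"):
        raise ModelPrepError("edit_template expects a template-like input")
    member = tmpl.members[0]
    res_to_idx = {int(r): i for i, r in enumerate(member.resids)}

    wid = _window_identity(al)
    kept_cols = []
    for ci, (t, m) in enumerate(al.columns):
        if m not in res_to_idx:
            continue
        if proto.prune_mode == "unaligned_plus_lowid" and wid[ci] < LOWID_THRESHOLD:
            continue
        kept_cols.append((ci, t, m))

    if proto.prune_mode == "none":
        # keep every model residue; aligned ones renumber to the target,
        # unaligned ones keep an off-target index (no coverage credit)
        aligned = {m: (ci, t) for ci, t, m in kept_cols}
        resids, xyz, b = [], [], []
        offset = len(target_seq) + 1  # park unaligned residues off-target
        for i, mres in enumerate(member.resids):
            if int(mres) in aligned:
                ci, t = aligned[int(mres)]
                resids.append(t)
                bval = _b_value(member.b[i], wid[ci], proto)
            else:
                resids.append(offset + int(mres))
                bval = _b_value(member.b[i], al.identity, proto)
            xyz.append(member.xyz[i])
            b.append(bval)
        order = np.argsort(resids, kind="stable")
        new = CoordSet(np.array(resids)[order], np.array(xyz)[order],
                       np.array(b)[order])
    else:
        resids, xyz, b = [], [], []
        for ci, t, m in kept_cols:
            i = res_to_idx[m]
            resids.append(t)
            xyz.append(member.xyz[i])
            b.append(_b_value(member.b[i], wid[ci], proto))
        if not resids:
            raise ModelPrepError(
                "model vanished: no residues survive the pruning protocol")
        new = CoordSet(np.array(resids), np.array(xyz), np.array(b))

    cov_cols = tuple((t, m) for _, t, m in kept_cols)
    cov = coverage_from_alignment(
        AlignmentPair(al.target_id, al.model_id, cov_cols, al.identity),
        len(target_seq), bridge_gap=bridge_gap)
    if cov.empty:
        raise ModelPrepError("model vanished: empty coverage after editing")
    weight = sequence_weight(target_seq, cov)
    src = tmpl.source_template_id or al.model_id
    return EnsembleModel(
        model_id=model_id or f"{src}:{proto.protocol_id}",
        component_id=tmpl.component_id,
        members=(new,),
        coverage=cov,
        weight=weight,
        source_template_id=src,
        protocol_id=proto.protocol_id,
    )


def _b_value(b_orig: float, wid: float, proto: Protocol) -> float:
    if proto.b_scheme == "asis":
        return float(b_orig)
    if proto.b_scheme == "constant":
        return B_CONSTANT
    return B_CONSTANT + B_SIMILARITY_SLOPE * (1.0 - float(wid))


def build_ensemble(collection: Sequence[CoordSet],
                   trim_threshold: float = 2.5,
                   component_id: str = "", model_id: str = "ensemble",
                   target_seq: str | None = None,
                   source_template_id: str | None = None,
                   max_rounds: int = 10) -> EnsembleModel:
    """Superpose a model collection and trim divergent residues.

    Members 2..n are Kabsch-superposed onto member 1 over their common
    residues; residues whose inter-member spread (maximum pairwise
    distance) exceeds ``trim_threshold`` are removed and the
    superposition repeated until stable (at most ``max_rounds`` rounds).
    """
    if not collection:
        raise ModelPrepError("empty model collection")
    members = list(collection)
    common = set(members[0].resids.tolist())
    for m in members[1:]:
        common &= set(m.resids.tolist())
    common = np.array(sorted(common), dtype=int)

    for _ in range(max_rounds):
        if len(common) < 3:
            raise ModelPrepError(
                "fewer than 3 common residues: cannot superpose collection")
        idx = [np.searchsorted(m.resids, common) for m in members]
        ref = members[0].xyz[idx[0]]
        aligned = [members[0]]
        stacks = [ref]
        for m, ix in zip(members[1:], idx[1:]):
            try:
                rot, trans, _ = kabsch_superpose(ref, m.xyz[ix])
            except DegenerateSuperpositionError as exc:
                raise ModelPrepError(f"superposition failed: {exc}") from exc
            aligned.append(CoordSet(m.resids, m.xyz @ rot.T + trans, m.b))
            stacks.append(aligned[-1].xyz[ix])
        members = aligned
        if len(members) == 1:
            break
        pile = np.stack(stacks)                      # (M, C, 3)
        spread = np.zeros(len(common))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                d = np.linalg.norm(pile[i] - pile[j], axis=1)
                spread = np.maximum(spread, d)
        keep = common[spread <= trim_threshold]
        if len(keep) == len(common):
            break
        common = keep
        members = [m.subset(np.isin(m.resids, common)) for m in members]

    members = [m.subset(np.isin(m.resids, common)) for m in members]
    cov = CoverageSet.from_pairs((int(r), int(r) + 1) for r in common)
    weight = (sequence_weight(target_seq, cov) if target_seq
              else 110.0 * cov.length + WATER_MASS)
    return EnsembleModel(
        model_id=model_id, component_id=component_id,
        members=tuple(members), coverage=cov, weight=weight,
        source_template_id=source_template_id or model_id,
        protocol_id="ensembled",
    )


def expand_to_ensembles(spec: ComponentSpec, inputs: Sequence[ModelInput],
                        protocols: Sequence[Protocol] = DEFAULT_PROTOCOLS,
                        seed: int = 0) -> list[EnsembleModel]:
    """Expand every input into ready ensembles, in search priority order.

    Ready ensembles come first, then collections, then templates and
    homology hits (hits ordered by descending identity); each
    template-like input yields one ensemble per protocol, with the
    protocol order shuffled by the seeded generator (there is no a
    priori ranking among protocols). Sequence-only inputs contribute
    nothing.
    """
    rng = np.random.default_rng(seed)
    ordered = sorted(
        enumerate(inputs),
        key=lambda t: (_STAGE_PRIORITY[t[1].stage],
                       -(t[1].identity or 0.0), t[0]))
    out: list[EnsembleModel] = []
    for pos, mi in ordered:
        if mi.stage == "sequence_only":
            continue
        if mi.stage == "ensemble":
            src = mi.source_template_id or f"input{pos}"
            cov = (mi.alignment and coverage_from_alignment(
                mi.alignment, spec.length)) or CoverageSet.full(spec.length)
            out.append(EnsembleModel(
                model_id=f"{spec.component_id}:{src}",
                component_id=spec.component_id, members=mi.members,
                coverage=cov, weight=sequence_weight(spec.sequence, cov),
                source_template_id=src, protocol_id="ready"))
        elif mi.stage == "collection":
            src = mi.source_template_id or f"collection{pos}"
            out.append(build_ensemble(
                mi.members, component_id=spec.component_id,
                model_id=f"{spec.component_id}:{src}",
                target_seq=spec.sequence, source_template_id=src))
        else:  # template / homology_hit
            shuffled = list(protocols)
            rng.shuffle(shuffled)
            for proto in shuffled:
                try:
                    out.append(edit_template(mi, mi.alignment, proto,
                                             spec.sequence))
                except ModelPrepError:
                    continue  # protocol removed everything; skip variant
    return out


# ---------------------------------------------------------------------------
# PDB coordinate IO
# ---------------------------------------------------------------------------

def read_ca_pdb(path, resid_offset: int = -1) -> CoordSet:
    """Read C-alpha coordinates from a PDB file.

    Residue numbers are shifted by ``resid_offset`` (default -1: PDB
    files are 1-based, internal indexing is 0-based).
    """
    st = gemmi.read_structure(str(path))
    resids, xyz, b = [], [], []
    for model in st:
        for chain in model:
            for res in chain:
                ca = res.find_atom("CA", "*")
                if ca is None:
                    continue
                resids.append(res.seqid.num + resid_offset)
                xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
                b.append(ca.b_iso)
        break  # first model only
    if not resids:
        raise ModelPrepError(f"no C-alpha atoms found in {path}")
    order = np.argsort(resids, kind="stable")
    return CoordSet(np.array(resids)[order], np.array(xyz)[order],
                    np.array(b)[order])


def write_ca_pdb(path, chains: Sequence[tuple[str, CoordSet]],
                 cell=None, sg_symbol: str | None = None,
                 resid_offset: int = 1) -> None:
    """Write C-alpha chains as a PDB file (CRYST1 included when known)."""
    st = gemmi.Structure()
    st.name = "mrpilot"
    if cell is not None:
        st.cell = gemmi.UnitCell(cell.a, cell.b, cell.c,
                                 cell.alpha, cell.beta, cell.gamma)
    if sg_symbol:
        from .symmetry import build_space_group
        st.spacegroup_hm = build_space_group(sg_symbol).hm
    model = gemmi.Model("1")
    for chain_name, cs in chains:
        chain = gemmi.Chain(chain_name)
        for r, pos, bval in zip(cs.resids, cs.xyz, cs.b):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(r) + resid_offset, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*pos)
            atom.b_iso = float(bval)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())
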
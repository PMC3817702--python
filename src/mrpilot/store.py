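"""Solution archive, PDB export and the solutions utility helpers.

The archive is a line-delimited JSON format with a mandatory version
tag and an end marker: one record per line, human-diffable, and
round-trip stable (write/read/write is byte-identical). Unknown fields
in records survive a read unchanged, so newer writers remain readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .composition import CoverageSet
from .modelprep import CoordSet, EnsembleModel
from .symmetry import Placement, UnitCell, build_space_group

FORMAT_NAME = "mrpilot-archive"
FORMAT_VERSION = 1


class ArchiveError(ValueError):
    pass


def _jsonify(obj):
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


# -- serialization helpers ---------------------------------------------------

def placement_to_dict(p: Placement) -> dict:
    return {"component_id": p.component_id, "model_id": p.model_id,
            "rot": [round(float(v), 9) for v in np.asarray(p.rot).ravel()],
            "trans": [round(float(v), 6) for v in np.asarray(p.trans)]}


def placement_from_dict(d: dict) -> Placement:
    rot = np.array(d["rot"], dtype=float).reshape(3, 3)
    # re-orthonormalize: rounding to archive precision may leave the
    # matrix a hair outside the strict placement invariant
    u, _s, vt = np.linalg.svd(rot)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] *= -1
        rot = u @ vt
    return Placement(d["component_id"], d["model_id"], rot,
                     np.array(d["trans"], dtype=float))


def model_to_dict(m) -> dict:
    if hasattr(m, "composite_members"):      # composite search model
        return {"model_id": m.model_id, "component_id": m.component_id,
                "kind": "composite",
                "source_template_id": m.source_template_id,
                "weight": round(float(m.weight), 4)}
    return {
        "model_id": m.model_id,
        "component_id": m.component_id,
        "kind": "ensemble",
        "source_template_id": m.source_template_id,
        "protocol_id": m.protocol_id,
        "weight": round(float(m.weight), 4),
        "coverage": [list(iv) for iv in m.coverage.intervals],
        "members": [{
            "resids": cs.resids.tolist(),
            "xyz": [[round(float(v), 4) for v in row] for row in cs.xyz],
            "b": [round(float(v), 3) for v in cs.b],
        } for cs in m.members],
    }


def model_from_dict(d: dict):
    if d.get("kind") == "composite":
        return None                         # composites are not re-loadable
    members = tuple(CoordSet(np.array(cs["resids"], dtype=int),
                             np.array(cs["xyz"], dtype=float),
                             np.array(cs["b"], dtype=float))
                    for cs in d["members"])
    return EnsembleModel(
        model_id=d["model_id"], component_id=d["component_id"],
        members=members,
        coverage=CoverageSet(tuple(tuple(iv) for iv in d["coverage"])),
        weight=float(d["weight"]),
        source_template_id=d["source_template_id"],
        protocol_id=d.get("protocol_id", "asis"))


def solution_to_dict(sol) -> dict:
    return {
        "solution_id": sol.solution_id,
        "parent_id": sol.parent_id,
        "sg_symbol": sol.sg_symbol,
        "placements": [placement_to_dict(p) for p in sol.placements],
        "llg": round(float(sol.llg), 6),
        "tfz_history": [round(float(t), 4) for t in sol.tfz_history],
        "status": sol.status,
        "origin": sol.origin,
        "clear": bool(sol.clear),
    }


# -- the archive -------------------------------------------------------------

@dataclass
class SolutionArchive:
    """Every solution a run ever scored, plus run metadata."""

    header: dict
    solutions: list = field(default_factory=list)   # list of record dicts
    ledger: dict = field(default_factory=dict)
    ranking: list = field(default_factory=list)

    @classmethod
    def from_run(cls, result) -> "SolutionArchive":
        header = {
            "seed": result.seed,
            "space_groups": list(result.space_groups),
            "cell": [result.cell.a, result.cell.b, result.cell.c,
                     result.cell.alpha, result.cell.beta,
                     result.cell.gamma],
            "config": {k: v for k, v in vars(result.config).items()
                       if isinstance(v, (int, float, str, bool))},
            "components": {cid: {"sequence": c.sequence,
                                 "stoichiometry": c.stoichiometry}
                           for cid, c in result.components.items()},
            "models": [model_to_dict(m) for m in result.models.values()],
        }
        solutions = [solution_to_dict(s)
                     for _sid, s in sorted(result.solutions.items())]
        return cls(header=header, solutions=solutions,
                   ledger=dict(result.ledger.counts),
                   ranking=list(result.ranking))

    # -- IO ------------------------------------------------------------------

    def write(self, path) -> None:
        lines = [_jsonify({"format": FORMAT_NAME,
                           "version": FORMAT_VERSION})]
        lines.append(_jsonify({"record_type": "header", **self.header}))
        lines.append(_jsonify({"record_type": "ledger", **self.ledger}))
        lines.append(_jsonify({"record_type": "ranking",
                               "ids": self.ranking}))
        for sol in self.solutions:
            lines.append(_jsonify({"record_type": "solution", **sol}))
        lines.append(_jsonify({"record_type": "end",
                               "n_records": len(self.solutions)}))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "SolutionArchive":
        header, ledger, ranking, solutions = None, {}, [], []
        n_expected = None
        offset = 0
        with open(path) as fh:
            first = fh.readline()
            try:
                tag = json.loads(first)
            except json.JSONDecodeError as exc:
                raise ArchiveError(
                    f"not an archive: bad tag line at byte 0") from exc
            if tag.get("format") != FORMAT_NAME:
                raise ArchiveError(f"not a {FORMAT_NAME} file")
            if tag.get("version") != FORMAT_VERSION:
                raise ArchiveError(
                    f"archive version mismatch: file has "
                    f"{tag.get('version')}, this reader supports "
                    f"{FORMAT_VERSION}")
            offset = len(first)
            for line in fh:
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ArchiveError(
                        f"truncated or corrupt archive at byte "
                        f"{offset}") from exc
                offset += len(line)
                rt = rec.pop("record_type", None)
                if rt == "header":
                    header = rec
                elif rt == "ledger":
                    ledger = rec
                elif rt == "ranking":
                    ranking = rec["ids"]
                elif rt == "solution":
                    solutions.append(rec)
                elif rt == "end":
                    n_expected = rec.get("n_records")
        if header is None or n_expected is None:
            raise ArchiveError(
                f"truncated archive: end marker missing (read "
                f"{offset} bytes)")
        if n_expected != len(solutions):
            raise ArchiveError(
                f"truncated archive: expected {n_expected} solution "
                f"records, found {len(solutions)}")
        return cls(header=header, solutions=solutions, ledger=ledger,
                   ranking=ranking)

    # -- accessors -----------------------------------------------------------

    @property
    def cell(self) -> UnitCell:
        return UnitCell(*self.header["cell"])

    def models_by_id(self) -> dict:
        out = {}
        for d in self.header.get("models", ()):
            m = model_from_dict(d)
            if m is not None:
                out[m.model_id] = m
        return out

    def solution(self, solution_id: str) -> dict:
        for rec in self.solutions:
            if rec["solution_id"] == solution_id:
                return rec
        raise ArchiveError(f"no solution {solution_id!r} in archive")

    def ranked(self) -> list:
        by_id = {rec["solution_id"]: rec for rec in self.solutions}
        return [by_id[i] for i in self.ranking if i in by_id]

    def summary(self) -> dict:
        """Machine-readable run summary (for downstream integration)."""
        return {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "seed": self.header.get("seed"),
            "space_groups": self.header.get("space_groups"),
            "ledger": self.ledger,
            "n_solutions": len(self.solutions),
            "ranking": [
                {"solution_id": rec["solution_id"],
                 "sg": rec["sg_symbol"],
                 "n_placed": len(rec["placements"]),
                 "llg": rec["llg"],
                 "tfz_history": rec["tfz_history"]}
                for rec in self.ranked()],
        }


# -- PDB export --------------------------------------------------------------

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def export_solution(archive: SolutionArchive, solution_id: str,
                    mode: str = "altloc", backend=None) -> str:
    """Render one solution as PDB text.

    ``altloc`` emits every ensemble member under successive
    alternate-location indicators within one chain per placement;
    ``best_member`` scores each member against the backend and emits
    the winner. Chains are lettered by placement order.
    """
    import gemmi

    if mode not in ("altloc", "best_member"):
        raise ArchiveError(f"unknown export mode {mode!r}")
    rec = archive.solution(solution_id)
    models = archive.models_by_id()
    placements = [placement_from_dict(d) for d in rec["placements"]]
    if len(placements) > len(_CHAIN_IDS):
        raise ArchiveError(
            f"cannot export {len(placements)} placements in altloc mode: "
            f"chain identifiers A-Z are exhausted; export subsets instead")
    if mode == "best_member" and backend is None:
        raise ArchiveError("best_member export needs a scoring backend")

    cell = archive.cell
    st = gemmi.Structure()
    st.name = solution_id
    st.cell = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha,
                             cell.beta, cell.gamma)
    st.spacegroup_hm = build_space_group(rec["sg_symbol"]).hm
    gm = gemmi.Model("1")
    for ip, pl in enumerate(placements):
        model = models.get(pl.model_id)
        if model is None:
            raise ArchiveError(f"model {pl.model_id!r} not in archive")
        members = list(model.members)
        if mode == "best_member" and len(members) > 1:
            best = None
            for mi, cs in enumerate(members):
                single = EnsembleModel(
                    model_id=f"{model.model_id}#m{mi}",
                    component_id=model.component_id, members=(cs,),
                    coverage=model.coverage, weight=model.weight,
                    source_template_id=model.source_template_id,
                    protocol_id=model.protocol_id)
                rep = backend.score([pl], [single], rec["sg_symbol"])
                if best is None or rep.llg > best[0]:
                    best = (rep.llg, mi)
            members = [members[best[1]]]
        chain = gemmi.Chain(_CHAIN_IDS[ip])
        n_res = len(members[0])
        for ri in range(n_res):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(members[0].resids[ri]) + 1, " ")
            for mi, cs in enumerate(members):
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                if len(members) > 1:
                    atom.altloc = _CHAIN_IDS[mi]
                pos = pl.apply(cs.xyz[ri])
                atom.pos = gemmi.Position(*pos)
                atom.b_iso = float(cs.b[ri])
                atom.occ = round(1.0 / len(members), 2)
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string()
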
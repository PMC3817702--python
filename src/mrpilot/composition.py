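"""Sequence bookkeeping and asymmetric-unit content estimation.

Covers FASTA parsing, molecular weight, alignment-derived sequence
coverage, Matthews-coefficient composition selection, and the
"what is still missing from this partial solution" analysis that
decides which models are admissible for the next extension cycle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .symmetry import SpaceGroupInfo, UnitCell


class CompositionError(ValueError):
    pass


# average residue masses (Da), Expasy convention; peptide-bond water excluded
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,
}
WATER_MASS = 18.02

#: standard protein relation between Matthews coefficient and solvent fraction
MATTHEWS_PROTEIN_CONST = 1.23


def parse_fasta(stream) -> list[tuple[str, str]]:
    """Read FASTA records in file order as ``(id, SEQUENCE)`` pairs."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = [(r.id, str(r.seq).strip().upper())
               for r in SeqIO.parse(stream, "fasta")]
    if not records:
        raise CompositionError("empty FASTA input")
    for rid, seq in records:
        if not seq:
            raise CompositionError(f"FASTA record {rid!r} has empty sequence")
    return records


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da; 'X' counts as 110.0 Da."""
    if not sequence:
        raise CompositionError("empty sequence")
    try:
        mass = sum(RESIDUE_MASS[ch] for ch in sequence.upper())
    except KeyError as exc:
        raise CompositionError(f"invalid residue {exc.args[0]!r}") from exc
    return mass + WATER_MASS


@dataclass(frozen=True)
class ComponentSpec:
    """One search component: sequence, stoichiometry, derived weight."""

    component_id: str
    sequence: str
    stoichiometry: int = 1

    def __post_init__(self):
        if self.stoichiometry < 1:
            raise CompositionError("stoichiometry must be a positive integer")
        molecular_weight(self.sequence)  # validates alphabet / emptiness

    @property
    def mw(self) -> float:
        return molecular_weight(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# coverage intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageSet:
    """Sorted, non-overlapping half-open [start, end) intervals, 0-based."""

    intervals: tuple = ()

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[int, int]]) -> "CoverageSet":
        ivs = sorted((int(s), int(e)) for s, e in pairs if e > s)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return CoverageSet(tuple(tuple(iv) for iv in merged))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def empty(self) -> bool:
        return not self.intervals

    def union(self, other: "CoverageSet") -> "CoverageSet":
        return CoverageSet.from_pairs(self.intervals + other.intervals)

    def intersect(self, other: "CoverageSet") -> "CoverageSet":
        out = []
        for s1, e1 in self.intervals:
            for s2, e2 in other.intervals:
                s, e = max(s1, s2), min(e1, e2)
                if e > s:
                    out.append((s, e))
        return CoverageSet.from_pairs(out)

    def subtract(self, other: "CoverageSet") -> "CoverageSet":
        out = []
        for s, e in self.intervals:
            cur = [(s, e)]
            for s2, e2 in other.intervals:
                nxt = []
                for cs, ce in cur:
                    if e2 <= cs or s2 >= ce:
                        nxt.append((cs, ce))
                    else:
                        if cs < s2:
                            nxt.append((cs, s2))
                        if e2 < ce:
                            nxt.append((e2, ce))
                cur = nxt
            out.extend(cur)
        return CoverageSet.from_pairs(out)

    @staticmethod
    def full(length: int) -> "CoverageSet":
        return CoverageSet.from_pairs([(0, length)])


@dataclass(frozen=True)
class AlignmentPair:
    """A pairwise target/model alignment as explicit column pairs.

    ``columns`` are 0-based ``(target_index, model_index)`` pairs,
    strictly increasing in both coordinates. ``matches`` optionally
    records per-column residue identity (used for window-identity
    pruning and similarity B factors); ``identity`` is the fraction of
    identical aligned columns.
    """

    target_id: str
    model_id: str
    columns: tuple
    identity: float
    matches: tuple | None = None

    def __post_init__(self):
        prev_t, prev_m = -1, -1
        for t, m in self.columns:
            if t <= prev_t or m <= prev_m:
                raise CompositionError(
                    "alignment columns must be strictly increasing")
            prev_t, prev_m = t, m
        if not 0.0 <= self.identity <= 1.0:
            raise CompositionError("identity must lie in [0, 1]")
        if self.matches is not None and len(self.matches) != len(self.columns):
            raise CompositionError("matches must parallel columns")


def alignment_from_aligned_fasta(stream, target_id: str | None = None
                                 ) -> AlignmentPair:
    """Build an :class:`AlignmentPair` from a 2-record aligned FASTA.

    The first record is the target, the second the model; both must
    have equal aligned length. Identity is computed over aligned
    (gap-free) columns.
    """
    records = parse_fasta(stream)
    if len(records) != 2:
        raise CompositionError("pairwise alignment needs exactly 2 records")
    (tid, tseq), (mid, mseq) = records
    if len(tseq) != len(mseq):
        raise CompositionError("aligned sequences differ in length")
    cols, matches = [], []
    ti = mi = 0
    for a, b in zip(tseq, mseq):
        if a not in "-." and b not in "-.":
            cols.append((ti, mi))
            matches.append(a == b)
        if a not in "-.":
            ti += 1
        if b not in "-.":
            mi += 1
    identity = float(np.mean(matches)) if matches else 0.0
    return AlignmentPair(target_id=target_id or tid, model_id=mid,
                         columns=tuple(cols), identity=identity,
                         matches=tuple(matches))


def coverage_from_alignment(al: AlignmentPair, target_length: int,
                            bridge_gap: int = 2) -> CoverageSet:
    """Covered target intervals; short internal gaps are bridged.

    Runs of aligned target indices become half-open intervals; gaps of
    at most ``bridge_gap`` target residues inside a run are absorbed.
    """
    tidx = [t for t, _ in al.columns]
    if tidx and (tidx[0] < 0 or tidx[-1] >= target_length):
        raise CompositionError("alignment index out of target bounds")
    if not tidx:
        return CoverageSet()
    pairs = []
    start = prev = tidx[0]
    for t in tidx[1:]:
        if t - prev - 1 <= bridge_gap:
            prev = t
        else:
            pairs.append((start, prev + 1))
            start = prev = t
    pairs.append((start, prev + 1))
    return CoverageSet.from_pairs(pairs)


# ---------------------------------------------------------------------------
# Matthews-based ASU content selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsuContents:
    """Chosen asymmetric-unit content and its Matthews statistics."""

    n_complexes: int
    copies: Mapping[str, int]
    solvent_fraction: float
    vm: float
    plausibilities: tuple = ()   # (Z, solvent, plausibility) per examined Z


def solvent_from_vm(vm: float) -> float:
    return 1.0 - MATTHEWS_PROTEIN_CONST / vm


def matthews_select(cell: UnitCell, sg: SpaceGroupInfo,
                    components: Sequence[ComponentSpec],
                    center: float = 0.50, sd: float = 0.12,
                    min_solvent: float = 0.20) -> AsuContents:
    """Choose how many complexes fit the asymmetric unit.

    V_M(Z) = V_cell / (n_ops * Z * sum(MW * stoichiometry)); the Z >= 1
    maximizing a Gaussian plausibility on the implied solvent fraction
    (centre 0.50, sd 0.12 by default) is selected. Fails when even a
    single complex leaves less than ``min_solvent`` solvent.
    """
    if not components:
        raise CompositionError("at least one component required")
    mw_complex = sum(c.mw * c.stoichiometry for c in components)
    scanned = []
    z = 1
    while True:
        vm = cell.volume / (sg.n_ops * z * mw_complex)
        solv = solvent_from_vm(vm)
        if solv < min_solvent:
            break
        plaus = float(np.exp(-((solv - center) ** 2) / (2.0 * sd ** 2)))
        scanned.append((z, solv, plaus))
        z += 1
        if z > 10000:  # unphysical; guards pathological cells
            break
    if not scanned:
        raise CompositionError(
            "cell too small: no complex count leaves plausible solvent")
    best_z, best_solv, _ = max(scanned, key=lambda t: t[2])
    vm = cell.volume / (sg.n_ops * best_z * mw_complex)
    return AsuContents(
        n_complexes=best_z,
        copies={c.component_id: c.stoichiometry * best_z for c in components},
        solvent_fraction=best_solv,
        vm=vm,
        plausibilities=tuple(scanned),
    )


# ---------------------------------------------------------------------------
# missing composition and model admissibility
# ---------------------------------------------------------------------------

def missing_composition(placements, asu: AsuContents,
                        components: Mapping[str, ComponentSpec],
                        model_coverage: Mapping[str, CoverageSet],
                        overlap_tol: float = 0.10) -> dict[str, list[CoverageSet]]:
    """Per-component uncovered sequence, one CoverageSet per open copy.

    Placed models are packed into copies greedily: a placement joins the
    first copy where its coverage overlaps what is already covered by at
    most ``overlap_tol`` of its own length, otherwise it opens a new
    copy. Copies with no placements are fully uncovered. The result
    maps component ids to the uncovered intervals of each copy that is
    still (partly) open; a complete solution yields an empty dict.
    """
    placed: dict[str, list[CoverageSet]] = {}
    for p in placements:
        comp = components.get(p.component_id)
        if comp is None:
            raise CompositionError(
                f"placement references unknown component {p.component_id!r}")
        cov = model_coverage.get(p.model_id)
        if cov is None:
            raise CompositionError(
                f"no recorded coverage for model {p.model_id!r}")
        copies = placed.setdefault(p.component_id, [])
        for i, existing in enumerate(copies):
            overlap = existing.intersect(cov).length
            if cov.length == 0 or overlap <= overlap_tol * cov.length:
                copies[i] = existing.union(cov)
                break
        else:
            copies.append(cov)

    out: dict[str, list[CoverageSet]] = {}
    for comp_id, comp in components.items():
        total = asu.copies.get(comp_id, 0)
        used = placed.get(comp_id, [])
        if len(used) > total:
            raise CompositionError(
                f"component {comp_id!r}: more copies placed than the "
                f"asymmetric unit holds")
        full = CoverageSet.full(comp.length)
        open_copies = []
        for cov in used:
            rem = full.subtract(cov)
            # a copy covered up to the tolerance counts as closed
            if rem.length > overlap_tol * comp.length:
                open_copies.append(rem)
        open_copies.extend([full] * (total - len(used)))
        if open_copies:
            out[comp_id] = open_copies
    return out


def model_admissible(model, missing: Mapping[str, list[CoverageSet]],
                     overlap_tol: float = 0.10) -> bool:
    """Does some open copy still need (most of) what this model covers?

    True iff a remaining copy's uncovered intervals contain the model's
    coverage up to an overlap of ``overlap_tol`` of the model's covered
    length.
    """
    copies = missing.get(model.component_id, [])
    need = model.coverage.length
    if need == 0:
        return False
    for uncovered in copies:
        inside = model.coverage.intersect(uncovered).length
        if need - inside <= overlap_tol * need:
            return True
    return False
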
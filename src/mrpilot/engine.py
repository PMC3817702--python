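"""The blackboard search controller.

Runs extension cycles against a scoring backend: composition analysis,
pending-prediction scoring with search bypass, rotation/translation/
packing searches in depth-first priority order, translation-peak
categorization, thresholded selection, rigid-body refinement, second
thresholding with propagation, alternative-model rescoring by
superposition (quick mode), solution analyses (amalgamation, assembly
detection and completion), branch reduction by template equivalence,
space-group arbitration, output selection and dry-run enumeration.

Determinism is a design commitment: all results are collected and
processed in a canonical (priority, then solution id) order, so a run
reproduces bit-for-bit for a fixed seed regardless of worker count.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .analysis import (AssemblyHypothesis, CompositeModel, amalgamate,
                       assemblies_as_models, complete_known_assembly,
                       detect_assemblies, predict_missing, update_ncs)
from .composition import (AsuContents, ComponentSpec, matthews_select,
                          missing_composition, model_admissible)
from .symmetry import (Placement, SpaceGroupInfo, UnitCell, build_space_group,
                       kabsch_superpose, spatially_equivalent,
                       DegenerateSuperpositionError)


class EngineError(RuntimeError):
    pass


JOB_KINDS = ("rotation_search", "translation_search", "packing",
             "rescore_by_superposition", "prediction_score", "refine")


@dataclass
class JobLedger:
    """Counts of backend jobs executed, per kind (never decreasing)."""

    counts: dict = field(default_factory=lambda: {k: 0 for k in JOB_KINDS})

    def add(self, kind: str, n: int = 1) -> None:
        self.counts[kind] += n

    def total_model_evaluations(self) -> int:
        return (self.counts["translation_search"]
                + self.counts["rescore_by_superposition"])


@dataclass
class EngineConfig:
    """Tunable knobs of the search controller."""

    mode: str = "full"                   # "full" | "quick"
    tfz_clear: float = 7.0               # clear-solution TFZ threshold
    select_fraction: float = 0.25        # pre-refinement percentage threshold
    purge_fraction: float = 0.25         # post-refinement percentage threshold
    sg_fraction: float = 0.25            # space-group arbitration threshold
    max_active_branches: int = 25
    template_equivalence: bool = True
    assembly_search_models: bool = False
    detect_assemblies: bool = True
    seed: int = 0
    workers: int = 1
    pool_threshold: int = 20
    grid_step: float = 2.0               # A, translation-search grid
    rot_step: float = 15.0               # deg, rotation-search grid
    n_keep_rot: int = 5
    background_samples: int = 200
    tol_rot: float = 5.0                 # deg, spatial equivalence
    tol_trans: float = 2.0               # A, spatial equivalence
    overlap_tol: float = 0.10            # coverage-overlap tolerance
    max_cycles: int = 60
    do_refine: bool = True
    known_assemblies: tuple = ()

    def __post_init__(self):
        for f in (self.select_fraction, self.purge_fraction,
                  self.sg_fraction):
            if not 0.0 < f < 1.0:
                raise EngineError("percentage fractions must lie in (0, 1)")
        if self.tfz_clear <= 0:
            raise EngineError("tfz_clear must be positive")
        if self.mode not in ("full", "quick"):
            raise EngineError(f"unknown mode {self.mode!r}")


@dataclass(eq=False)
class PartialSolution:
    """One node of the search tree."""

    solution_id: str
    parent_id: str | None
    sg_symbol: str
    placements: tuple = ()
    llg: float = 0.0
    tfz_history: tuple = ()
    status: str = "active"     # active|complete|rejected|merged|root
    origin: str = "search"     # search|prediction|amalgam|rescore|root
    clear: bool = False
    assemblies: tuple = ()     # AssemblyHypothesis records
    pending: tuple = ()        # associations awaiting evaluation

    @property
    def n_placed(self) -> int:
        return len(self.placements)


@dataclass(eq=False)
class _Candidate:
    """A proposed extension of a parent solution, before propagation."""

    parent: PartialSolution
    additions: tuple
    kind: str                  # search|prediction|amalgam|rescore
    tfz: float = 0.0
    llg: float | None = None
    packs: bool = True
    clear: bool = False
    refine: bool = True
    refine_scope: str = "all"

    @property
    def placements(self) -> tuple:
        return tuple(self.parent.placements) + tuple(self.additions)


# ---------------------------------------------------------------------------
# spec-level operations (used standalone and by the engine loop)
# ---------------------------------------------------------------------------

def categorize(peak, cfg: EngineConfig) -> str:
    """Clear iff the peak packs and its TFZ reaches the threshold.

    Solutions generated by alternative-model rescoring are clear
    irrespective of the score; that flag is set by the rescoring path.
    """
    if getattr(peak, "rescored", False):
        return "clear"
    packs = peak.packs if peak.packs is not None else False
    return "clear" if (packs and peak.tfz >= cfg.tfz_clear) else "ordinary"


def select_for_refinement(cands: Sequence[_Candidate], parent_llg: float,
                          cfg: EngineConfig) -> list:
    """Percentage-threshold selection; packing failures excluded first.

    threshold = best - f * |best - parent|; clear candidates below the
    threshold are retained; the result is capped at
    ``max_active_branches`` by descending score.
    """
    pool = [c for c in cands if c.packs]
    if not pool:
        return []
    best = max(c.llg for c in pool)
    thr = best - cfg.select_fraction * abs(best - parent_llg)
    kept = [c for c in pool if c.llg >= thr or c.clear]
    kept.sort(key=lambda c: -c.llg)
    return kept[:cfg.max_active_branches]


def propagate(cands: Sequence[_Candidate], parent_llg: float,
              cfg: EngineConfig) -> list:
    """Second (post-refinement) thresholding; clears retained."""
    if not cands:
        return []
    best = max(c.llg for c in cands)
    thr = best - cfg.purge_fraction * abs(best - parent_llg)
    return [c for c in cands if c.llg >= thr or c.clear]


def _template_multiset(sol: PartialSolution, models: Mapping) -> tuple:
    out = []
    for p in sol.placements:
        m = models.get(p.model_id)
        out.append((p.component_id,
                    m.source_template_id if m else p.model_id))
    return tuple(sorted(out))


def reduce_branches(partials: Sequence[PartialSolution],
                    sg: SpaceGroupInfo, cell: UnitCell, cfg: EngineConfig,
                    models: Mapping) -> list:
    """Merge spatially equivalent solutions built from the same templates.

    Solutions are partitioned by the multiset of source templates per
    component and by spatial equivalence (with model identity relaxed
    to template identity); only the highest-scoring representative of
    each class stays active, the rest are marked merged.
    """
    def entity_key(p: Placement) -> tuple:
        m = models.get(p.model_id)
        return (p.component_id, m.source_template_id if m else p.model_id)

    survivors: list[PartialSolution] = []
    ordered = sorted(partials, key=lambda s: (-s.llg, s.solution_id))
    for sol in ordered:
        merged = False
        for rep in survivors:
            if _template_multiset(sol, models) != _template_multiset(rep,
                                                                     models):
                continue
            if spatially_equivalent(rep, sol, sg, cell, cfg.tol_rot,
                                    cfg.tol_trans, entity_key=entity_key):
                sol.status = "merged"
                rep.clear = rep.clear or sol.clear
                merged = True
                break
        if not merged:
            survivors.append(sol)
    return survivors


def arbitrate_space_groups(per_sg_best: Mapping[str, float],
                           improvement: float, cfg: EngineConfig) -> list:
    """Keep space groups whose best score is within the threshold.

    threshold = best overall - sg_fraction * |improvement over the
    cycle|; with no improvement there is nothing to discriminate on and
    every group stays active.
    """
    if not per_sg_best:
        return []
    best = max(per_sg_best.values())
    thr = best - cfg.sg_fraction * abs(improvement)
    if improvement == 0:
        return sorted(per_sg_best)
    return sorted(s for s, v in per_sg_best.items() if v >= thr)


def expand_sg_choice(symbol: str, level: str = "exact") -> list:
    """Space groups compatible with the stated uncertainty level."""
    sg = build_space_group(symbol)
    if level == "exact":
        return [sg.symbol]
    if level == "enantiomorph":
        out = [sg.symbol]
        if sg.enantiomorph:
            out.append(sg.enantiomorph)
        return out
    if level == "point_group":
        from .symmetry import _CATALOGUE, _POINT_GROUP
        return sorted(s for s in _CATALOGUE
                      if _POINT_GROUP[s] == sg.point_group)
    raise EngineError(f"unknown space-group knowledge level {level!r}")


@dataclass(frozen=True)
class EnumerationResult:
    assignments: int      # quasi-equivalent complete assignments (leaves)
    evaluations: int      # model evaluations performed by the reduced search


def dry_run_enumerate(components: Mapping[str, ComponentSpec],
                      model_lists: Mapping[str, Sequence],
                      asu: AsuContents, cfg: EngineConfig
                      ) -> EnumerationResult:
    """Count the unscored extension tree without any backend calls.

    With branch reduction off the number of complete assignments is the
    product over extension steps of the admissible-model counts. With
    template equivalence on, branches whose models share a template
    collapse into one lineage per template class, and ``evaluations``
    counts the model evaluations the live reduced search performs
    (every admissible model is still scored at every step).
    """
    comp_ids = sorted(asu.copies)
    n_models = {c: len(model_lists.get(c, ())) for c in comp_ids}
    n_classes = {c: len({m.source_template_id for m in model_lists.get(c, ())})
                 for c in comp_ids}
    reduction = cfg.template_equivalence

    @functools.lru_cache(maxsize=None)
    def leaves(state: tuple) -> int:
        if not any(state):
            return 1
        total = 0
        for i, c in enumerate(comp_ids):
            if state[i] > 0 and n_models[c] > 0:
                nxt = state[:i] + (state[i] - 1,) + state[i + 1:]
                branch = n_classes[c] if reduction else n_models[c]
                total += branch * leaves(nxt)
        return total

    @functools.lru_cache(maxsize=None)
    def evals(state: tuple) -> int:
        if not any(state):
            return 0
        here = sum(n_models[c] for i, c in enumerate(comp_ids)
                   if state[i] > 0 and n_models[c] > 0)
        deeper = 0
        for i, c in enumerate(comp_ids):
            if state[i] > 0 and n_models[c] > 0:
                nxt = state[:i] + (state[i] - 1,) + state[i + 1:]
                branch = n_classes[c] if reduction else n_models[c]
                deeper += branch * evals(nxt)
        return here + deeper

    state0 = tuple(asu.copies[c] for c in comp_ids)
    return EnumerationResult(assignments=leaves(state0),
                             evaluations=evals(state0))


# ---------------------------------------------------------------------------
# the search engine
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Everything a run produced: every solution ever scored, plus state."""

    solutions: dict                 # solution_id -> PartialSolution
    ranking: list                   # ranked output solution ids
    ledger: JobLedger
    config: EngineConfig
    seed: int
    space_groups: list
    components: dict
    models: dict
    cell: UnitCell
    log: list = field(default_factory=list)
    cycle_stats: list = field(default_factory=list)  # per-cycle job deltas

    def best(self) -> PartialSolution | None:
        return self.solutions[self.ranking[0]] if self.ranking else None


class SearchEngine:
    """Stateful driver of one molecular-replacement run."""

    def __init__(self, components: Mapping[str, ComponentSpec],
                 model_lists: Mapping[str, Sequence], backend,
                 sg_list: Sequence[str], cfg: EngineConfig,
                 asu: AsuContents | None = None):
        self.components = dict(components)
        self.backend = backend
        self.cfg = cfg
        self.cell: UnitCell = backend.cell
        self.models: dict = {}
        for comp, lst in model_lists.items():
            for m in lst:
                self.models[m.model_id] = m
        self.model_lists = {c: list(lst) for c, lst in model_lists.items()}
        if not any(self.model_lists.values()):
            raise EngineError("nothing to search with: no models given")
        self.sg_list = list(sg_list)
        sg0 = build_space_group(self.sg_list[0])
        self.asu = asu or matthews_select(self.cell, sg0,
                                          list(self.components.values()))
        self.ledger = JobLedger()
        self.solutions: dict[str, PartialSolution] = {}
        self.active: dict[str, list] = {}
        self.log: list = []
        self._counter = 0
        self._rejected_predictions: set = set()
        for sym in self.sg_list:
            root = PartialSolution(solution_id=f"{sym}:root", parent_id=None,
                                   sg_symbol=sym, status="active",
                                   origin="root")
            self.solutions[root.solution_id] = root
            self.active[sym] = [root]

    # -- bookkeeping --------------------------------------------------------

    def _new_id(self, sym: str) -> str:
        self._counter += 1
        return f"{sym}:{self._counter:05d}"

    def _models_for(self, placements) -> list:
        return [self.models[p.model_id] for p in placements]

    def _coverage_map(self) -> dict:
        return {mid: m.coverage for mid, m in self.models.items()}

    def _missing(self, sol: PartialSolution) -> dict:
        return missing_composition(sol.placements, self.asu, self.components,
                                   self._coverage_map(),
                                   overlap_tol=self.cfg.overlap_tol)

    def _score(self, placements, sym):
        return self.backend.score(list(placements),
                                  self._models_for(placements), sym)

    # -- main loop ----------------------------------------------------------

    def run(self) -> RunResult:
        prev_best = 0.0
        cycle_stats: list = []
        for cycle in range(1, self.cfg.max_cycles + 1):
            before = dict(self.ledger.counts)
            any_new = False
            per_sg_best: dict[str, float] = {}
            for sym in list(self.active):
                n_new, n_pending = self.extension_cycle(sym, cycle)
                any_new = any_new or n_new > 0 or n_pending > 0
                pool = [s for s in self.active[sym]
                        if s.status in ("active", "complete")]
                per_sg_best[sym] = max((s.llg for s in pool), default=0.0)
            best_now = max(per_sg_best.values(), default=0.0)
            keep = arbitrate_space_groups(per_sg_best, best_now - prev_best,
                                          self.cfg)
            for sym in list(self.active):
                if sym not in keep:
                    self.log.append(f"cycle {cycle}: space group {sym} "
                                    f"dropped by arbitration")
                    del self.active[sym]
            prev_best = best_now
            cycle_stats.append({k: self.ledger.counts[k] - before[k]
                                for k in self.ledger.counts})
            if not any_new:
                break
            if self.cfg.mode == "quick" and any(
                    s.status == "complete" and s.clear
                    for sols in self.active.values() for s in sols):
                # quick strategy: the traversal ends once a clear,
                # complete solution exists
                self.log.append(f"cycle {cycle}: quick mode stop on a "
                                f"complete clear solution")
                break
        ranking = [s.solution_id for s in self.finalize_output()]
        return RunResult(solutions=self.solutions, ranking=ranking,
                         ledger=self.ledger, config=self.cfg,
                         seed=self.cfg.seed, space_groups=list(self.active),
                         components=self.components, models=self.models,
                         cell=self.cell, log=self.log,
                         cycle_stats=cycle_stats)

    # -- one extension cycle ------------------------------------------------

    def extension_cycle(self, sym: str, cycle: int):
        cfg = self.cfg
        sg = build_space_group(sym)
        actives = sorted(
            [s for s in self.active[sym] if s.status == "active"],
            key=lambda s: (-s.llg, s.solution_id))
        candidates: list[_Candidate] = []
        bypassed: set[str] = set()
        n_pending_next = 0

        # (1) composition analysis; (2) pending predictions and amalgams
        missing_of: dict[str, dict] = {}
        for sol in actives:
            missing = self._missing(sol)
            missing_of[sol.solution_id] = missing
            if not missing and sol.placements:
                sol.status = "complete"
                continue
            cands, bypass = self._evaluate_pending(sol, sym, cycle)
            candidates.extend(cands)
            if bypass:
                bypassed.add(sol.solution_id)
            sol.pending = ()

        actives = [s for s in actives if s.status == "active"]

        # (3) searches: rotation -> translation -> packing, depth first
        clear_exists = any(c.clear for c in candidates)
        pairs = []
        for sol in actives:
            if sol.solution_id in bypassed:
                continue
            missing = missing_of[sol.solution_id]
            for prio, model in enumerate(self._admissible_models(missing)):
                pairs.append((sol, prio, model))
        pairs.sort(key=lambda t: (-t[0].llg, t[0].solution_id, t[1]))

        if cfg.mode == "full" and pairs:
            # full mode: every (partial, model) search is an independent
            # job; results are absorbed in canonical priority order so
            # the run is identical for any worker count
            from .execution import JobSpec, parallel_map
            jobs = [JobSpec(
                job_id=f"{i:05d}|{sol.solution_id}|{model.model_id}",
                kind="search", fn=_run_search_job,
                args=(self.backend, tuple(sol.placements),
                      tuple(self._models_for(sol.placements)), model, sym,
                      cfg.n_keep_rot, cfg.rot_step, cfg.grid_step,
                      cfg.tfz_clear),
                cost_hint="slow", priority=(i,))
                for i, (sol, _prio, model) in enumerate(pairs)]
            report = parallel_map(jobs, workers=cfg.workers,
                                  pool_threshold=cfg.pool_threshold)
            for (sol, _prio, model), job in zip(pairs, jobs):
                res = report.results[job.job_id]
                if not res.ok:
                    self.log.append(
                        f"search failed for {sol.solution_id}/"
                        f"{model.model_id}: branch rejected")
                    continue
                found = self._absorb_search_result(sol, res.value,
                                                   candidates)
                clear_exists = clear_exists or found is not None
        else:
            for sol, _prio, model in pairs:
                if cfg.mode == "quick" and clear_exists:
                    break
                try:
                    found = self._search_one(sol, model, sym, candidates)
                except Exception as exc:        # noqa: BLE001
                    self.log.append(
                        f"search failed for {sol.solution_id}/"
                        f"{model.model_id}: branch rejected ({exc})")
                    continue
                if found:
                    clear_exists = True
                    if cfg.mode == "quick":
                        missing = missing_of[sol.solution_id]
                        alts = [m for m in self._admissible_models(missing)
                                if m.model_id != model.model_id
                                and not isinstance(m, CompositeModel)
                                and m.component_id == model.component_id]
                        candidates.extend(self.rescore_alternatives(
                            found, model, alts, sym))

        # (4) categorization happened inline; (5) selection per parent
        by_parent: dict[str, list] = {}
        for c in candidates:
            by_parent.setdefault(c.parent.solution_id, []).append(c)
        refined: list[_Candidate] = []
        for pid, cands in sorted(by_parent.items()):
            parent = self.solutions[pid]
            selected = select_for_refinement(cands, parent.llg, cfg)
            for c in cands:
                if c not in selected and c.packs:
                    self._record_candidate(c, "rejected")
                elif not c.packs:
                    self._record_candidate(c, "rejected")
            # (6) refinement
            for c in selected:
                if cfg.do_refine and c.refine:
                    placements, report, _warn = self.backend.rigid_refine(
                        list(c.placements), self._models_for(c.placements),
                        sym, scope=c.refine_scope)
                    self.ledger.add("refine")
                    n_par = len(c.parent.placements)
                    c.additions = tuple(placements[n_par:])
                    if c.refine_scope == "all" and n_par:
                        c.parent = replace(
                            c.parent, placements=tuple(placements[:n_par]))
                    c.llg = report.llg
                refined.append(c)

        # (7) second thresholding and propagation
        new_solutions: list[PartialSolution] = []
        for pid, cands in sorted(
                ((p, [c for c in refined
                      if c.parent.solution_id == p]) for p in by_parent),
                key=lambda t: t[0]):
            if not cands:
                continue
            parent = self.solutions[pid]
            for c in propagate(cands, parent.llg, cfg):
                sol = PartialSolution(
                    solution_id=self._new_id(sym), parent_id=pid,
                    sg_symbol=sym, placements=c.placements,
                    llg=float(c.llg),
                    tfz_history=parent.tfz_history + (float(c.tfz),),
                    status="active", origin=c.kind, clear=c.clear)
                if not self._missing(sol):
                    sol.status = "complete"
                self.solutions[sol.solution_id] = sol
                new_solutions.append(sol)

        # branch reduction first: equivalent same-template lineages are
        # collapsed before the (potentially quadratic) solution analyses
        still_active = [s for s in self.active[sym]
                        if s.status in ("active", "complete")]
        pool = [s for s in still_active if s.status == "active"
                and s.placements] + new_solutions
        pool = list({s.solution_id: s for s in pool}.values())
        if cfg.template_equivalence:
            pool = reduce_branches(pool, sg, self.cell, cfg, self.models)
        pool.sort(key=lambda s: (-s.llg, s.solution_id))

        # (8) solution analyses on the surviving propagated set
        survivors = {s.solution_id for s in pool}
        self._analyses([s for s in new_solutions
                        if s.solution_id in survivors], sym)
        roots = [s for s in still_active if not s.placements
                 and s.status == "active" and not s.parent_id]
        completes = [s for s in still_active if s.status == "complete"]
        # parents that produced propagated children retire from the
        # active set (their lineage continues through the children)
        extended = {c.parent_id for c in new_solutions}
        pool = [s for s in pool if s.solution_id not in extended]
        keep_roots = [] if any(s.placements for s in pool) else roots
        self.active[sym] = completes + keep_roots \
            + pool[:cfg.max_active_branches]
        n_pending_next = sum(len(s.pending) for s in self.active[sym])
        return len(new_solutions), n_pending_next

    # -- helpers for the cycle ----------------------------------------------

    def _admissible_models(self, missing: dict) -> list:
        out = []
        for comp in sorted(self.model_lists):
            for m in self.model_lists[comp]:
                if isinstance(m, CompositeModel):
                    need = {}
                    for mem, _r, _t in m.composite_members:
                        need[mem.component_id] = \
                            need.get(mem.component_id, 0) + 1
                    if all(len(missing.get(c, ())) >= n
                           for c, n in need.items()):
                        out.append(m)
                elif model_admissible(m, missing, self.cfg.overlap_tol):
                    out.append(m)
        # composites first: biggest scattering gain per search
        out.sort(key=lambda m: not isinstance(m, CompositeModel))
        return out

    def _expand_additions(self, model, placement: Placement) -> tuple:
        if isinstance(model, CompositeModel):
            return tuple(model.expand(placement))
        return (placement,)

    def _search_one(self, sol: PartialSolution, model, sym: str,
                    candidates: list):
        """Rotation search, then translation searches depth-first.

        Returns the first clear candidate found for this (solution,
        model) pair, or None. All evaluated peaks are appended to
        ``candidates``.
        """
        cfg = self.cfg
        out = _run_search_job(self.backend, tuple(sol.placements),
                              tuple(self._models_for(sol.placements)),
                              model, sym, cfg.n_keep_rot, cfg.rot_step,
                              cfg.grid_step, cfg.tfz_clear)
        return self._absorb_search_result(sol, out, candidates)

    def _absorb_search_result(self, sol: PartialSolution, out: dict,
                              candidates: list):
        self.ledger.add("rotation_search", out["n_rf"])
        self.ledger.add("translation_search", out["n_tf"])
        self.ledger.add("packing", out["n_pack"])
        first_clear = None
        for additions, tfz, llg, packs, clear in out["results"]:
            cand = _Candidate(parent=sol, additions=additions,
                              kind="search", tfz=tfz, llg=llg,
                              packs=packs, clear=clear)
            candidates.append(cand)
            if clear and first_clear is None:
                first_clear = cand
        return first_clear

    def rescore_alternatives(self, clear_cand: _Candidate, placed_model,
                             alternatives: Sequence, sym: str) -> list:
        """Equivalent solutions for alternative models, by superposition.

        Each alternative is superposed onto the placed model through
        common target-numbered residues. Same-template alternatives
        are scored without refinement; different-template ones are
        rigid-refined (last placement only) first. All results are
        marked clear irrespective of the score.
        """
        out = []
        placed = clear_cand.additions[-1]
        parent = clear_cand.parent
        for alt in alternatives:
            common, idx_p, idx_a = np.intersect1d(
                placed_model.resids, alt.resids, return_indices=True)
            if len(common) < 3:
                self.log.append(f"rescore skip {alt.model_id}: "
                                f"no usable sequence overlap")
                continue
            Y = placed_model.coords[idx_p] @ placed.rot.T + placed.trans
            X = alt.coords[idx_a]
            try:
                rot, trans, _rmsd = kabsch_superpose(Y, X)
            except DegenerateSuperpositionError:
                self.log.append(f"rescore skip {alt.model_id}: "
                                f"superposition failed")
                continue
            alt_pl = Placement(alt.component_id, alt.model_id, rot, trans)
            placements = tuple(parent.placements) + (alt_pl,)
            models = self._models_for(parent.placements) + [alt]
            same_template = (alt.source_template_id
                             == placed_model.source_template_id)
            if not same_template and self.cfg.do_refine:
                refined, report, _w = self.backend.rigid_refine(
                    list(placements), models, sym, scope="last")
                self.ledger.add("refine")
                placements = tuple(refined)
                alt_pl = placements[-1]
                llg = report.llg
            else:
                llg = self.backend.score(list(placements), models, sym).llg
            self.ledger.add("rescore_by_superposition")
            out.append(_Candidate(parent=parent, additions=(alt_pl,),
                                  kind="rescore", tfz=clear_cand.tfz,
                                  llg=llg, packs=True, clear=True,
                                  refine=False))
        return out

    def _evaluate_pending(self, sol: PartialSolution, sym: str, cycle: int):
        """Score pending predictions/amalgamations; bypass search if clear."""
        cfg = self.cfg
        out: list[_Candidate] = []
        bypass = False
        parent_pl = list(sol.placements)
        parent_md = self._models_for(parent_pl)
        for assoc in sol.pending:
            kind = assoc["kind"]
            if kind == "amalgam_polar":
                # polar empty-parent amalgamation: re-use B's rotations,
                # schedule a translation search (rotation search skipped)
                for rot_flat, model_id in zip(assoc["rotations"],
                                              assoc["model_ids"]):
                    model = self.models[model_id]
                    R = np.array(rot_flat).reshape(3, 3)
                    peaks = self.backend.translation_search(
                        model, R, parent_pl, parent_md, sym,
                        grid_step=cfg.grid_step)
                    self.ledger.add("translation_search")
                    for pk in peaks[:3]:
                        additions = (pk.placement,)
                        placements = tuple(parent_pl) + additions
                        models = parent_md + [model]
                        packs, _ = self.backend.packing_check(
                            list(placements), models, sym)
                        self.ledger.add("packing")
                        pk.packs = packs
                        rep = self.backend.score(list(placements), models,
                                                 sym)
                        c = _Candidate(parent=sol, additions=additions,
                                       kind="amalgam", tfz=pk.tfz,
                                       llg=rep.llg, packs=packs)
                        c.clear = categorize(pk, cfg) == "clear"
                        out.append(c)
                continue

            if kind == "prediction":
                confirmed = []
                zs = []
                for pl in assoc["placements"]:
                    key = self._prediction_key(sym, pl)
                    if key in self._rejected_predictions:
                        continue
                    model = self.models[pl.model_id]
                    if hasattr(self.backend, "snap_placement"):
                        pl = self.backend.snap_placement(
                            model, pl, parent_pl, parent_md, sym)
                    pls = tuple(parent_pl) + tuple(confirmed) + (pl,)
                    mds = [self.models[q.model_id] for q in pls]
                    packs, _ = self.backend.packing_check(list(pls), mds,
                                                          sym)
                    self.ledger.add("packing")
                    z = self.backend.background_zscore(
                        list(pls[:-1]), mds[:-1], [pl], [model], sym,
                        n_samples=cfg.background_samples,
                        seed=cfg.seed + cycle)
                    self.ledger.add("prediction_score")
                    if packs and z >= cfg.tfz_clear:
                        confirmed.append(pl)
                        zs.append(float(z))
                    else:
                        self._rejected_predictions.add(key)
                        self.log.append(
                            f"{sol.solution_id}: prediction "
                            f"{assoc.get('label', '?')} rejected "
                            f"(packs={packs}, z={z:.1f})")
                if confirmed:
                    pls = tuple(parent_pl) + tuple(confirmed)
                    mds = [self.models[q.model_id] for q in pls]
                    rep = self.backend.score(list(pls), mds, sym)
                    out.append(_Candidate(parent=sol,
                                          additions=tuple(confirmed),
                                          kind="prediction",
                                          tfz=float(min(zs)),
                                          llg=float(rep.llg), packs=True,
                                          clear=True))
                    bypass = True
                continue

            variants = assoc.get("variants") or [assoc["placements"]]
            best = None
            for var in variants:
                additions = tuple(var)
                placements = tuple(parent_pl) + additions
                models = parent_md + [self.models[p.model_id]
                                      for p in additions]
                packs, _ = self.backend.packing_check(list(placements),
                                                      models, sym)
                self.ledger.add("packing")
                if not packs:
                    continue
                z = self.backend.background_zscore(
                    parent_pl, parent_md, list(additions),
                    [self.models[p.model_id] for p in additions], sym,
                    n_samples=cfg.background_samples,
                    seed=cfg.seed + cycle)
                rep = self.backend.score(list(placements), models, sym)
                if best is None or rep.llg > best[0]:
                    best = (rep.llg, z, additions)
            self.ledger.add("prediction_score")
            if best is None:
                self.log.append(f"{sol.solution_id}: pending {kind} "
                                f"rejected (packing)")
                continue
            llg, z, additions = best
            clear = z >= cfg.tfz_clear
            c = _Candidate(parent=sol, additions=additions, kind=kind,
                           tfz=float(z), llg=float(llg), packs=True,
                           clear=clear)
            if clear:
                bypass = True
                out.append(c)
            else:
                self.log.append(f"{sol.solution_id}: pending {kind} not "
                                f"clear (z={z:.1f})")
        return out, bypass

    @staticmethod
    def _prediction_key(sym: str, pl: Placement) -> tuple:
        """Coarse pose key memoizing rejected predictions.

        A prediction rejected once (no signal at that pose) stays
        rejected: re-proposals of the same orbit slot by descendant
        solutions would only repeat the same scoring job.
        """
        from scipy.spatial.transform import Rotation
        rv = Rotation.from_matrix(pl.rot).as_rotvec(degrees=True)
        return (sym, pl.component_id,
                tuple(np.round(pl.trans / 2.0).astype(int).tolist()),
                tuple(np.round(rv / 10.0).astype(int).tolist()))

    def _record_candidate(self, c: _Candidate, status: str) -> None:
        sol = PartialSolution(
            solution_id=self._new_id(c.parent.sg_symbol),
            parent_id=c.parent.solution_id, sg_symbol=c.parent.sg_symbol,
            placements=c.placements, llg=float(c.llg or 0.0),
            tfz_history=c.parent.tfz_history + (float(c.tfz),),
            status=status, origin=c.kind, clear=c.clear)
        self.solutions[sol.solution_id] = sol

    # -- solution analyses ---------------------------------------------------

    def _analyses(self, new_solutions: Sequence[PartialSolution],
                  sym: str) -> None:
        cfg = self.cfg
        sg = build_space_group(sym)
        clears = [s for s in new_solutions if s.clear]

        # amalgamation of clear siblings
        by_parent: dict[str, list] = {}
        for s in clears:
            by_parent.setdefault(s.parent_id, []).append(s)
        for pid, sibs in sorted(by_parent.items()):
            if len(sibs) < 2:
                continue
            parent = self.solutions[pid]
            n_par = len(parent.placements)
            sibs.sort(key=lambda s: (-s.llg, s.solution_id))
            a = sibs[0]
            for b in sibs[1:]:
                adds_a = a.placements[n_par:]
                adds_b = b.placements[n_par:]
                if not self._composition_allows(parent, adds_a + adds_b):
                    continue
                cands = amalgamate(parent.placements, adds_a, adds_b,
                                   sg, self.cell)
                for am in cands:
                    if am.needs_translation_search:
                        a.pending += ({"kind": "amalgam_polar",
                                       "rotations": [
                                           tuple(np.array(p.rot).ravel())
                                           for p in adds_b],
                                       "model_ids": [p.model_id
                                                     for p in adds_b]},)
                        break
                else:
                    variants = [list(am.placements[len(adds_a):])
                                for am in cands]
                    a.pending += ({"kind": "amalgam",
                                   "variants": variants},)

        # assembly detection, NCS refresh and missing-member prediction
        if cfg.detect_assemblies:
            for s in new_solutions:
                if sum(1 for _ in s.placements) < 2:
                    continue
                fresh = detect_assemblies(list(s.placements), self.cell,
                                          sg=sg)
                parent = self.solutions.get(s.parent_id)
                inherited = update_ncs(list(s.placements),
                                       parent.assemblies if parent else (),
                                       self.cell, sg=sg) if parent else []
                merged = {(h.group_label, h.member_indices): h
                          for h in inherited}
                for h in fresh:
                    merged[(h.group_label, h.member_indices)] = h
                s.assemblies = tuple(merged.values())
                missing = self._missing(s)
                for h in s.assemblies:
                    preds = predict_missing(h, list(s.placements), sg,
                                            self.cell)
                    if not preds:
                        continue
                    preds = self._cap_to_missing(preds, s, missing)
                    if preds:
                        s.pending += ({"kind": "prediction",
                                       "placements": [p.placement
                                                      for p in preds],
                                       "label": h.group_label},)
                # complete assemblies as optional composite search models
                if cfg.assembly_search_models:
                    for h in s.assemblies:
                        if len(h.member_indices) == h.order:
                            comp_model = assemblies_as_models(
                                h, list(s.placements),
                                self._models_for(s.placements))
                            if comp_model.model_id not in self.models:
                                self.models[comp_model.model_id] = comp_model
                                self.model_lists.setdefault(
                                    comp_model.component_id, []).append(
                                        comp_model)

        # user-supplied (known) assemblies
        for ka in cfg.known_assemblies:
            for s in clears:
                preds = complete_known_assembly(
                    ka, list(s.placements), self._models_for(s.placements),
                    self.backend, sym)
                missing = self._missing(s)
                preds = self._cap_to_missing(preds, s, missing)
                if preds:
                    s.pending += ({"kind": "prediction",
                                   "placements": [p.placement for p in preds],
                                   "label": ka.name},)

    def _composition_allows(self, parent: PartialSolution,
                            additions: Sequence[Placement]) -> bool:
        counts: dict[str, int] = {}
        for p in tuple(parent.placements) + tuple(additions):
            counts[p.component_id] = counts.get(p.component_id, 0) + 1
        return all(n <= self.asu.copies.get(c, 0)
                   for c, n in counts.items())

    def _cap_to_missing(self, preds, sol: PartialSolution,
                        missing: dict) -> list:
        out = []
        budget = {c: len(v) for c, v in missing.items()}
        for pr in preds:
            comp = pr.placement.component_id
            if budget.get(comp, 0) > 0:
                budget[comp] -= 1
                # predictions borrow the model of a placed sibling copy
                model_id = next((p.model_id for p in sol.placements
                                 if p.component_id == comp), None)
                if model_id is None:
                    continue
                pl = Placement(comp, model_id, pr.placement.rot,
                               pr.placement.trans)
                out.append(PredictedPlacement_like(pl))
        return out

    # -- output selection ----------------------------------------------------

    #: score differences below this are numerical noise, not evidence;
    #: real score contrasts between solutions are orders larger
    SCORE_RESOLUTION = 0.01

    def finalize_output(self) -> list:
        """Rank, threshold, and drop symmetry-subset solutions.

        A solution whose placements all match a subset of a *better*
        solution (one global operator + origin move) is discarded;
        "better" requires a margin above the score resolution, so that
        an over-placed variant gaining only numerical dust never
        displaces the correct-count solution. Incomplete ancestors are
        absorbed the same way: their completion genuinely scores
        higher. Equal scores rank the smaller solution first.
        """
        cfg = self.cfg
        res = self.SCORE_RESOLUTION
        pool = [s for s in self.solutions.values()
                if s.placements and s.status in ("active", "complete",
                                                 "merged")
                and s.sg_symbol in self.active]
        if not pool:
            return []
        pool.sort(key=lambda s: (-round(s.llg / res), s.n_placed,
                                 s.solution_id))
        best = pool[0].llg
        thr = best - cfg.select_fraction * abs(best)
        pool = [s for s in pool if s.llg >= thr]

        def entity_key(p: Placement) -> tuple:
            m = self.models.get(p.model_id)
            return (p.component_id,
                    m.source_template_id if m else p.model_id)

        kept: list[PartialSolution] = []
        for s in pool:
            subset = False
            for better in kept:
                if better.llg <= s.llg + res:
                    continue
                if spatially_equivalent(
                        better, s, build_space_group(s.sg_symbol), self.cell,
                        cfg.tol_rot, cfg.tol_trans, entity_key=entity_key,
                        subset=True):
                    subset = True
                    break
            if not subset:
                kept.append(s)
        return kept


def _run_search_job(backend, parent_placements, parent_models, model, sym,
                    n_keep_rot, rot_step, grid_step, tfz_clear) -> dict:
    """One (partial, model) search: RF, then depth-first TFs + packing.

    A pure function of its inputs (runs identically in a worker
    process). Composite models are disassembled into member placements
    before packing and scoring.
    """
    local_models = {model.model_id: model}
    members = getattr(model, "composite_members", None)
    if members:
        for mem, _r, _t in members:
            local_models[mem.model_id] = mem
    orients = backend.rotation_search(
        model, list(parent_placements), list(parent_models), sym,
        n_keep=n_keep_rot, step_deg=rot_step)
    n_tf = n_pack = 0
    results = []
    first_clear = None
    for R, _rfz in orients:
        peaks = backend.translation_search(
            model, R, list(parent_placements), list(parent_models), sym,
            grid_step=grid_step)
        n_tf += 1
        for pk in peaks:
            if members:
                additions = tuple(model.expand(pk.placement))
            else:
                additions = (pk.placement,)
            placements = tuple(parent_placements) + additions
            mods = list(parent_models) + [local_models[p.model_id]
                                          for p in additions]
            packs, _n = backend.packing_check(list(placements), mods, sym)
            n_pack += 1
            clear = bool(packs and pk.tfz >= tfz_clear)
            rep = backend.score(list(placements), mods, sym)
            results.append((additions, float(pk.tfz), float(rep.llg),
                            bool(packs), clear))
            if clear and first_clear is None:
                first_clear = len(results) - 1
        if first_clear is not None:
            break          # depth-first: stop at the first clear orientation
    return {"n_rf": 1, "n_tf": n_tf, "n_pack": n_pack, "results": results,
            "first_clear": first_clear}


def PredictedPlacement_like(pl: Placement):
    from .analysis import PredictedPlacement
    return PredictedPlacement(placement=pl, origin_assembly="engine")


def run_search(components: Mapping[str, ComponentSpec],
               model_lists: Mapping[str, Sequence], backend,
               sg_choice, cfg: EngineConfig | None = None,
               asu: AsuContents | None = None) -> RunResult:
    """Run the full extension-cycle search and return the archive state.

    ``sg_choice`` may be a single symbol, an explicit list of symbols,
    or a ``(symbol, level)`` pair with level in {"exact",
    "enantiomorph", "point_group"}.
    """
    cfg = cfg or EngineConfig()
    if isinstance(sg_choice, str):
        sg_list = [build_space_group(sg_choice).symbol]
    elif (isinstance(sg_choice, tuple) and len(sg_choice) == 2
          and sg_choice[1] in ("exact", "enantiomorph", "point_group")):
        sg_list = expand_sg_choice(*sg_choice)
    else:
        sg_list = [build_space_group(s).symbol for s in sg_choice]
    engine = SearchEngine(components, model_lists, backend, sg_list, cfg,
                          asu=asu)
    return engine.run()
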
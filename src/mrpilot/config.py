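"""Run-configuration handling.

A run is described by a YAML document naming the components (sequences
and stoichiometry), the model inputs for each component at any stage of
the input hierarchy, the space-group knowledge level, the engine mode
and, for self-contained synthetic runs, a ``genspec`` block describing
the toy crystal to generate (which then also serves as the scoring
backend).

Schema sketch::

    space_group: P212121
    sg_uncertainty: exact        # exact | enantiomorph | point_group
    mode: quick                  # quick | full
    seed: 1
    engine: {grid_step: 3.0}     # optional EngineConfig overrides
    genspec:
      solvent: 0.5
      components:
        - {id: A, length: 20, copies: 4, assembly: C5}
    components:                  # optional; defaults to generated models
      - id: A
        stoichiometry: 1
        models:
          - {stage: generated}               # the generator's template
          - {stage: variants, n: 13, noise: 0.5}
          - {stage: ensemble, path: m.pdb}
          - {stage: template, path: t.pdb, alignment: aln.fasta}
          - {stage: collection, paths: [a.pdb, b.pdb]}
          - {stage: hit_list, path: hits.tsv}
    known_assemblies:
      - name: dimer
        members:                 # transforms are relative to member 1
          - {component: A, rot: [1,0,0, 0,1,0, 0,0,1], trans: [0,0,0]}
          - {component: B, rot: [...], trans: [...]}
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .analysis import KnownAssembly
from .composition import (ComponentSpec, alignment_from_aligned_fasta,
                          parse_fasta)
from .engine import EngineConfig
from .modelprep import (DEFAULT_PROTOCOLS, ModelInput, expand_to_ensembles,
                        read_ca_pdb)
from .toycrystal import (ComponentGen, GenSpec, generate_crystal,
                         make_model_variants)


class ConfigError(ValueError):
    pass


@dataclass
class RunSetup:
    """Everything needed to start a search (or a dry run)."""

    components: dict              # component_id -> ComponentSpec
    model_lists: dict             # component_id -> list of models
    backend: object | None        # scoring backend (None: dry run only)
    sg_choice: tuple              # (symbol, level)
    cfg: EngineConfig
    generated: object | None = None   # GeneratedCase when genspec present


def _load_genspec(block: Mapping, default_sg: str) -> GenSpec:
    comps = []
    for c in block.get("components", ()):
        comps.append(ComponentGen(
            component_id=str(c["id"]), length=int(c["length"]),
            copies=int(c["copies"]), assembly=c.get("assembly"),
            assembly_axis=tuple(c["axis"]) if "axis" in c else None))
    if not comps:
        raise ConfigError("genspec needs at least one component")
    return GenSpec(
        components=tuple(comps),
        space_group=block.get("space_group", default_sg),
        solvent_target=float(block.get("solvent", 0.5)),
        sigma=float(block.get("sigma", 1.5)),
        sigma_rot=float(block.get("sigma_rot", 10.0)),
        epsilon=float(block.get("epsilon", 0.02)),
        template_noise=float(block.get("template_noise", 0.8)))


def _hit_list_inputs(path: Path, component_id: str) -> list:
    """Parse a homology-hit table: hit_id, pdb path, alignment, identity."""
    out = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise ConfigError(
                    f"hit table row needs 4 tab-separated columns, "
                    f"got {row!r}")
            hit_id, pdb_path, aln_path, identity = row[:4]
            base = path.parent
            with open(base / aln_path) as afh:
                al = alignment_from_aligned_fasta(afh.read())
            out.append(ModelInput(
                component_id=component_id, stage="homology_hit",
                members=(read_ca_pdb(base / pdb_path),),
                alignment=al, source_template_id=hit_id,
                identity=float(identity)))
    return out


def load_config(path) -> RunSetup:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("run config must be a YAML mapping")

    sg_symbol = doc.get("space_group")
    if not sg_symbol:
        raise ConfigError("space_group is required")
    level = doc.get("sg_uncertainty", "exact")
    seed = int(doc.get("seed", 0))

    known = []
    for ka in doc.get("known_assemblies", ()):
        members = tuple((str(m["component"]), tuple(m["rot"]),
                         tuple(m["trans"])) for m in ka["members"])
        known.append(KnownAssembly(name=str(ka["name"]), members=members))

    engine_overrides = dict(doc.get("engine", {}))
    cfg = EngineConfig(mode=doc.get("mode", "full"), seed=seed,
                       workers=int(doc.get("workers", 1)),
                       known_assemblies=tuple(known), **engine_overrides)

    generated = None
    backend = None
    components: dict = {}
    if "genspec" in doc:
        genspec = _load_genspec(doc["genspec"], sg_symbol)
        generated = generate_crystal(genspec, seed)
        backend = generated.crystal
        components.update(generated.components)

    model_lists: dict = {c: [] for c in components}
    comp_blocks = doc.get("components")
    if comp_blocks:
        for cb in comp_blocks:
            cid = str(cb["id"])
            if cid not in components:
                seq = cb.get("sequence")
                if not seq and "sequence_file" in cb:
                    with open(path.parent / cb["sequence_file"]) as fh:
                        seq = parse_fasta(fh.read())[0][1]
                if not seq:
                    raise ConfigError(f"component {cid}: no sequence")
                components[cid] = ComponentSpec(
                    cid, seq, int(cb.get("stoichiometry", 1)))
            spec = components[cid]
            inputs = []
            model_lists.setdefault(cid, [])
            for mb in cb.get("models", ()):
                stage = mb["stage"]
                if stage == "generated":
                    if generated is None:
                        raise ConfigError(
                            "stage 'generated' requires a genspec block")
                    model_lists[cid].append(generated.templates[cid])
                elif stage == "variants":
                    if generated is None:
                        raise ConfigError(
                            "stage 'variants' requires a genspec block")
                    model_lists[cid].extend(make_model_variants(
                        generated.templates[cid], int(mb["n"]),
                        float(mb.get("noise", 0.5)), seed))
                elif stage == "hit_list":
                    inputs.extend(_hit_list_inputs(
                        path.parent / mb["path"], cid))
                elif stage in ("ensemble", "template"):
                    al = None
                    if "alignment" in mb:
                        with open(path.parent / mb["alignment"]) as fh:
                            al = alignment_from_aligned_fasta(fh.read())
                    inputs.append(ModelInput(
                        component_id=cid, stage=stage,
                        members=(read_ca_pdb(path.parent / mb["path"]),),
                        alignment=al,
                        source_template_id=mb.get("template_id")))
                elif stage == "collection":
                    members = tuple(read_ca_pdb(path.parent / p)
                                    for p in mb["paths"])
                    inputs.append(ModelInput(
                        component_id=cid, stage="collection",
                        members=members,
                        source_template_id=mb.get("template_id")))
                elif stage == "sequence_only":
                    inputs.append(ModelInput(component_id=cid,
                                             stage="sequence_only"))
                else:
                    raise ConfigError(f"unknown model stage {stage!r}")
            if inputs:
                model_lists[cid].extend(expand_to_ensembles(
                    spec, inputs, DEFAULT_PROTOCOLS, seed))
    elif generated is not None:
        # no explicit model inputs: search with the generated templates
        for cid, tmpl in generated.templates.items():
            model_lists[cid].append(tmpl)

    if not components:
        raise ConfigError("no components defined (genspec or components)")
    return RunSetup(components=components, model_lists=model_lists,
                    backend=backend, sg_choice=(sg_symbol, level), cfg=cfg,
                    generated=generated)
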
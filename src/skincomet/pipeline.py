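"""End-to-end orchestration: panel -> orthogroups -> alignments ->
calibrated profile HMMs -> scans, as one reusable library layer.

The stage graph is linear; each helper is also exposed on its own so the
CLI subcommands and tests can run stages in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .msa import Msa, progressive_align
from .ortho import (OrthoGroup, build_similarity_graph, cluster_orthogroups,
                    concat_core_distances, nj_tree, single_copy_core)
from .phmm import (DEFAULT_BACKGROUND, ProfileHmm, build_profile, calibrate_ga,
                   score_forward_many, select_match_columns)
from .seqio import AA20, ProteinRecord, ValidationError

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


def panel_background(proteins: Sequence[ProteinRecord],
                     min_residues: int = 1000) -> np.ndarray:
    """Amino-acid background frequencies of the reference panel.

    Falls back to the generic background when the panel holds fewer than
    ``min_residues`` residues; a +1 pseudocount per residue type keeps
    every frequency positive.
    """
    counts = np.ones(20)
    total = 0
    for p in proteins:
        for c in p.sequence:
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
                total += 1
    if total < min_residues:
        return DEFAULT_BACKGROUND.copy()
    return counts / counts.sum()


@dataclass
class ModelBuildResult:
    models: list[ProfileHmm]
    groups: list[OrthoGroup]
    alignments: dict[str, Msa]
    group_of_model: dict[str, str]


def build_models_from_panel(proteomes: Mapping[str, Sequence[ProteinRecord]],
                            min_group_size: int = 2,
                            min_norm_score: float = 0.3,
                            max_gap_frac: float = 0.5,
                            pseudocount: float = 1.0,
                            seed_groups_only: bool = False,
                            model_names: Mapping[str, str] | None = None,
                            calibrate: bool = True) -> ModelBuildResult:
    """Infer orthogroups across the panel, align each group of at least
    ``min_group_size`` members, build a profile HMM per group, and
    calibrate each model's gathering threshold against the full panel
    (group members as true positives, all other panel proteins as true
    negatives).

    ``model_names`` optionally maps group ids to model names (e.g. seed
    gene symbols); unnamed models keep their group id.
    """
    proteins = [p for prots in proteomes.values() for p in prots]
    if len(proteins) < 2:
        raise ValidationError("panel too small to build models")
    edges = build_similarity_graph(proteins, min_norm_score=min_norm_score)
    groups = cluster_orthogroups(edges, proteins)
    bg = panel_background(proteins)
    by_id = {p.protein_id: p for p in proteins}

    models: list[ProfileHmm] = []
    alignments: dict[str, Msa] = {}
    group_of_model: dict[str, str] = {}
    for grp in groups:
        if len(grp.members) < min_group_size:
            continue
        if seed_groups_only and not grp.is_seed_group:
            continue
        records = [by_id[p] for p in grp.protein_ids]
        msa = progressive_align(records)
        alignments[grp.group_id] = msa
        name = (model_names or {}).get(grp.group_id, grp.group_id)
        flags = select_match_columns(msa, max_gap_frac=max_gap_frac)
        hmm = build_profile(msa, flags, pseudocount=pseudocount,
                            background=bg, name=name)
        group_of_model[name] = grp.group_id
        models.append(hmm)

    if calibrate:
        all_ids = [p.protein_id for p in proteins]
        seqs = [p.sequence for p in proteins]
        for hmm in models:
            member_set = set(hmm.members)
            bits = score_forward_many(hmm, seqs)
            pos_mask = np.array([pid in member_set for pid in all_ids])
            calibrate_ga(
                hmm,
                positives=[p for p in proteins if p.protein_id in member_set],
                negatives=[p for p in proteins if p.protein_id not in member_set],
                pos_scores=bits[pos_mask],
                neg_scores=bits[~pos_mask],
            )
            if hmm.ga_overlap:
                logger.warning("model %s: positive/negative scores overlap", hmm.name)
    return ModelBuildResult(models, groups, alignments, group_of_model)


def panel_tree(proteomes: Mapping[str, Sequence[ProteinRecord]],
               groups: Sequence[OrthoGroup],
               alignments: Mapping[str, Msa]) -> str:
    """Neighbor-joining panel phylogeny from the concatenated single-copy
    core alignment (rows relabelled genome-wise), as newick."""
    genome_ids = list(proteomes)
    core = single_copy_core(groups, genome_ids)
    if not core:
        raise ValidationError("no single-copy core groups in panel")
    genome_of = {p.protein_id: p.genome_id
                 for prots in proteomes.values() for p in prots}
    relabelled = []
    for grp in core:
        aln = alignments.get(grp.group_id)
        if aln is None:
            raise ValidationError(f"missing alignment for core group {grp.group_id}")
        relabelled.append(Msa([genome_of[r] for r in aln.row_ids], list(aln.rows)))
    dm = concat_core_distances(core, relabelled)
    return nj_tree(dm)


def config_hash(config: Mapping[str, object]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: Mapping[str, object], seed: int | None,
               stage: str) -> dict[str, object]:
    return {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": seed,
        "version": __version__,
    }


def write_manifest(out_dir: str | Path, stage: str,
                   config: Mapping[str, object], seed: int | None,
                   outputs: Sequence[str | Path],
                   started: float) -> Path:
    """Write a per-stage manifest: parameters, seed, output hashes and
    wall time."""
    out_dir = Path(out_dir)
    entries = {}
    for p in outputs:
        p = Path(p)
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": seed,
        "version": __version__,
        "outputs": entries,
        "wall_seconds": round(time.time() - started, 3),
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
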
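"""Apply calibrated model collections to proteomes and gene catalogs, and
aggregate/normalize the resulting hit tables.

Counting is per-model: each model is an independent search with its own
gathering threshold, so one protein may count toward several models
(mirroring independent per-model searches).  Module-level values are sums
over member models; two normalizations follow: per-sample relative
abundance (rows sum to one) and per-module maximum scaling across the
full combined sample set (each module column has max one).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phmm import ProfileHmm, score_forward_many
from .seqio import LabeledMatrix, ModuleDef, NormState, ProteinRecord, ValidationError

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"


def _require_ga(models: Sequence[ProfileHmm]) -> None:
    missing = [m.name for m in models if m.ga_bits is None]
    if missing:
        raise ValidationError(
            f"models without gathering threshold: {', '.join(missing)}")


def _hit_matrix(models: Sequence[ProfileHmm],
                proteins: Sequence[ProteinRecord]) -> np.ndarray:
    """Boolean (proteins x models) pass-GA matrix."""
    seqs = [p.sequence for p in proteins]
    hits = np.zeros((len(proteins), len(models)), dtype=bool)
    for j, m in enumerate(models):
        if seqs:
            bits = score_forward_many(m, seqs)
            hits[:, j] = bits >= m.ga_bits
    return hits


def scan_proteome(models: Sequence[ProfileHmm],
                  proteins: Sequence[ProteinRecord]) -> pd.Series:
    """Count, per model, the proteins scoring at or above the model's GA."""
    _require_ga(models)
    hits = _hit_matrix(models, proteins)
    return pd.Series(hits.sum(axis=0), index=[m.name for m in models], dtype=float)


def scan_genomes(models: Sequence[ProfileHmm],
                 proteomes: Mapping[str, Sequence[ProteinRecord]]) -> LabeledMatrix:
    """Genome x model raw count matrix (the genomic distribution table)."""
    rows = {gid: scan_proteome(models, prots) for gid, prots in proteomes.items()}
    df = pd.DataFrame(rows).T
    df.index.name = "genome_id"
    return LabeledMatrix(df, NormState.raw_counts)


def quantify_metagenome(models: Sequence[ProfileHmm],
                        gene_catalog: Sequence[ProteinRecord],
                        gene_counts: LabeledMatrix) -> LabeledMatrix:
    """Abundance-weighted model quantification of a metagenome.

    For each sample and model, the value is the summed read count of
    catalog genes passing that model's GA.  Genes hit by no model are
    accounted for in an ``UNMAPPED`` column.
    """
    _require_ga(models)
    by_id = {p.protein_id: p for p in gene_catalog}
    missing = [g for g in gene_counts.col_ids if g not in by_id]
    if missing:
        raise ValidationError(
            f"gene ids missing from catalog: {', '.join(missing[:10])}")
    genes = [by_id[g] for g in gene_counts.col_ids]
    hits = _hit_matrix(models, genes)           # (genes, models)
    counts = gene_counts.df.to_numpy(dtype=float)  # (samples, genes)
    values = counts @ hits
    unmapped = counts @ (~hits.any(axis=1)).astype(float)
    df = pd.DataFrame(values, index=gene_counts.row_ids,
                      columns=[m.name for m in models])
    df[UNMAPPED] = unmapped
    return LabeledMatrix(df, NormState.raw_counts)


def aggregate_modules(hits: LabeledMatrix,
                      catalog: Sequence[ModuleDef]) -> LabeledMatrix:
    """Sum member-model columns into module columns.

    Models listed in the catalog but absent from the table are zero-filled
    with a warning; an ``UNMAPPED`` column passes through untouched.  When
    the catalog covers every model column, row totals are conserved.
    """
    df = hits.df
    out = {}
    for mod in catalog:
        missing = [m for m in mod.member_models if m not in df.columns]
        if missing:
            logger.warning("module %s: models absent from table, zero-filled: %s",
                           mod.module_id, ", ".join(missing))
        present = [m for m in mod.member_models if m in df.columns]
        out[mod.module_id] = (df[present].sum(axis=1) if present
                              else pd.Series(0.0, index=df.index))
    res = pd.DataFrame(out, index=df.index)
    if UNMAPPED in df.columns:
        res[UNMAPPED] = df[UNMAPPED]
    return LabeledMatrix(res, hits.norm_state)


def renorm_sample_relative(hits: LabeledMatrix,
                           include_unmapped: bool = False) -> LabeledMatrix:
    """Divide each row by its total, removing library-size differences.

    The ``UNMAPPED`` accounting column is dropped and excluded from the
    denominator unless ``include_unmapped``.  Zero rows stay zero with a
    warning.
    """
    if hits.norm_state != NormState.raw_counts:
        raise ValidationError(
            f"sample-relative renormalization expects raw counts, got {hits.norm_state}")
    df = hits.df.copy()
    if UNMAPPED in df.columns and not include_unmapped:
        df = df.drop(columns=[UNMAPPED])
    totals = df.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("zero-total rows left as zeros: %s",
                       ", ".join(map(str, df.index[zero])))
    out = df.div(totals.replace(0.0, 1.0), axis=0)
    return LabeledMatrix(out, NormState.sample_relative)


def normalize_module_max(hits: LabeledMatrix) -> LabeledMatrix:
    """Scale every module column by its maximum over the full combined
    sample set, so all samples within one module lie in [0, 1] and the
    top sample is exactly 1.  Idempotent; zero columns stay zero."""
    if hits.norm_state not in (NormState.sample_relative, NormState.module_max):
        raise ValidationError(
            f"module-max normalization expects sample-relative input, got {hits.norm_state}")
    df = hits.df
    maxima = df.max(axis=0)
    out = df.div(maxima.replace(0.0, 1.0), axis=1)
    return LabeledMatrix(out, NormState.module_max)
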
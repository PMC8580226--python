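"""Functional-potential inference from 16S compositions.

Predicts per-sample abundance of skin-aging gene models by projecting an
OTU table through reference-genome gene content: each OTU is mapped to
the panel genome(s) with the deepest shared taxonomic prefix, and the
predicted value for (sample, model) is the OTU-abundance-weighted sum of
the mapped genomes' model counts.  The projection is exactly linear in
the OTU abundances.

No 16S copy-number correction is applied unless a per-genome copy-number
table is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import LabeledMatrix, NormState, ValidationError

logger = logging.getLogger(__name__)

#: Rank through which a taxonomy match is required for mapping (0-based
#: index into domain;phylum;class;order;family;genus;species): genus.
GENUS_DEPTH = 6


@dataclass
class OtuTable:
    """Samples x OTUs counts plus an OTU -> taxonomy-string map."""

    counts: LabeledMatrix
    taxonomy: dict[str, str]

    def __post_init__(self) -> None:
        missing = [o for o in self.counts.col_ids if o not in self.taxonomy]
        if missing:
            raise ValidationError(
                f"OTUs without taxonomy: {', '.join(missing[:10])}")


@dataclass
class GenomeMap:
    """Per-OTU weights over panel genomes; unmapped OTUs map to ()."""

    weights: dict[str, tuple[tuple[str, float], ...]]
    method: dict[str, str] = field(default_factory=dict)

    def unmapped(self) -> list[str]:
        return [o for o, w in self.weights.items() if not w]


def _split_taxonomy(tax: str, label: str) -> list[str]:
    if tax.strip().lower() == "unassigned":
        return []
    ranks = [r.strip() for r in tax.split(";")]
    if not ranks or all(not r for r in ranks):
        raise ValidationError(f"malformed taxonomy string for {label!r}: {tax!r}")
    return ranks


def _prefix_depth(a: list[str], b: list[str]) -> int:
    depth = 0
    for x, y in zip(a, b):
        # empty rank annotations (e.g. 's__') end the informative prefix
        if not x or not y or x != y:
            break
        depth += 1
    return depth


def map_otus_to_genomes(otus: OtuTable,
                        panel_taxa: Mapping[str, str]) -> GenomeMap:
    """Map each OTU to the panel genome with the deepest matching
    taxonomic prefix; ties are averaged over the tied genomes.  OTUs that
    match no panel genome through the genus rank are left unmapped (with
    the unmapped fraction logged by the caller)."""
    panel = {g: _split_taxonomy(t, g) for g, t in panel_taxa.items()}
    weights: dict[str, tuple[tuple[str, float], ...]] = {}
    method: dict[str, str] = {}
    for otu in otus.counts.col_ids:
        ranks = _split_taxonomy(otus.taxonomy[otu], otu)
        if not ranks:
            weights[otu] = ()
            method[otu] = "unmapped"
            continue
        depths = {g: _prefix_depth(ranks, p) for g, p in panel.items()}
        best = max(depths.values(), default=0)
        if best < GENUS_DEPTH:
            weights[otu] = ()
            method[otu] = "unmapped"
            continue
        tied = sorted(g for g, d in depths.items() if d == best)
        w = 1.0 / len(tied)
        weights[otu] = tuple((g, w) for g in tied)
        full = len(tied) == 1 and best >= len(panel[tied[0]])
        method[otu] = "exact_taxon" if full else "nearest_rank"
    return GenomeMap(weights, method)


def predict_gene_content(otus: OtuTable,
                         gene_counts: LabeledMatrix,
                         mapping: GenomeMap,
                         copy_number: Mapping[str, float] | None = None) -> LabeledMatrix:
    """Project OTU abundances through reference gene content.

    predicted(sample, model) = sum over OTUs of abundance(sample, OTU)
    x weighted sum over mapped genomes of count(genome, model).  Exactly
    linear in the OTU abundances.  When ``copy_number`` is given, each
    OTU's abundance is divided by its mapped genomes' 16S copy number.
    """
    genomes = gene_counts.row_ids
    g_index = {g: i for i, g in enumerate(genomes)}
    otu_ids = otus.counts.col_ids
    W = np.zeros((len(otu_ids), len(genomes)))
    for i, otu in enumerate(otu_ids):
        for g, w in mapping.weights.get(otu, ()):
            if g not in g_index:
                raise ValidationError(f"mapped genome {g!r} absent from gene counts")
            cn = float(copy_number.get(g, 1.0)) if copy_number else 1.0
            W[i, g_index[g]] = w / cn
    A = otus.counts.df.to_numpy(dtype=float)
    C = gene_counts.df.to_numpy(dtype=float)
    pred = A @ W @ C

    mapped_mass = A @ W.sum(axis=1)
    totals = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, 1.0 - mapped_mass / np.maximum(totals, 1e-300), 0.0)
    for sample, f in zip(otus.counts.row_ids, frac):
        if f > 0:
            logger.warning("sample %s: unmapped OTU fraction %.3f", sample, f)
        if f >= 1.0:
            logger.warning("sample %s contains only unmapped OTUs", sample)
    df = pd.DataFrame(pred, index=otus.counts.row_ids, columns=gene_counts.col_ids)
    return LabeledMatrix(df, NormState.raw_counts)


def unmapped_fraction(otus: OtuTable, mapping: GenomeMap) -> pd.Series:
    """Per-sample fraction of OTU abundance not mapped to any genome."""
    A = otus.counts.df
    mapped = [o for o in A.columns if mapping.weights.get(str(o))]
    totals = A.sum(axis=1)
    frac = 1.0 - A[mapped].sum(axis=1) / totals.replace(0.0, 1.0)
    return frac.where(totals > 0, 0.0)
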
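"""Orthologous-group inference across a reference proteome panel.

Pipeline: exact Smith-Waterman all-vs-all similarity (BLOSUM62, affine
gaps), reciprocal-best-hit (RBH) edge selection with an in-paralog merge,
connected components as orthogroups, the single-copy core, and a
neighbor-joining panel phylogeny from concatenated core alignments.

A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention);
the default 11/1 therefore charges 12 for the first gapped residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord, SeedGene, ValidationError


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity edge; ``protein_a`` < ``protein_b``
    lexicographically.  ``norm_score`` is the raw local-alignment score
    divided by the self-score of the shorter sequence, clamped to [0, 1]."""

    protein_a: str
    protein_b: str
    score: float
    norm_score: float


@dataclass(frozen=True)
class OrthoGroup:
    """A set of proteins with a common evolutionary origin in the panel."""

    group_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, protein_id)
    is_seed_group: bool = False

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(p for _, p in self.members)


@dataclass
class DistanceMatrix:
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxon_ids), len(self.taxon_ids)):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.diag(v).any():
            raise ValidationError("distance matrix diagonal not zero")
        if (v < 0).any():
            raise ValidationError("negative distances")
        self.values = v


def _make_aligner(matrix: str, gap_open: float, gap_extend: float,
                  mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_score(a: str, b: str, matrix: str = "BLOSUM62",
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman local alignment score of two amino-acid strings.

    Returns 0 when no positive-scoring local alignment exists.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return max(0.0, float(aligner.score(a, b)))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def build_similarity_graph(proteins: Sequence[ProteinRecord],
                           min_norm_score: float = 0.3,
                           matrix: str = "BLOSUM62",
                           gap_open: float = 11.0, gap_extend: float = 1.0,
                           prefilter_kmer: int | None = 4) -> list[SimilarityEdge]:
    """Score all protein pairs (inter- and intra-genome) and keep edges
    with normalized score >= ``min_norm_score``.

    Pairs sharing no ``prefilter_kmer``-mer are skipped (their normalized
    score cannot approach homologous levels); pass ``None`` to disable.
    Output order is deterministic: sorted by (protein_a, protein_b).
    """
    if len(proteins) < 2:
        raise ValidationError("need at least two proteins")
    prots = sorted(proteins, key=lambda r: r.protein_id)
    ids = [p.protein_id for p in prots]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate protein ids in panel")

    aligner = _make_aligner(matrix, gap_open, gap_extend)
    self_score = {p.protein_id: max(1e-300, float(aligner.score(p.sequence, p.sequence)))
                  for p in prots}
    kmers = ({p.protein_id: _kmer_set(p.sequence, prefilter_kmer) for p in prots}
             if prefilter_kmer else None)

    edges: list[SimilarityEdge] = []
    for pa, pb in itertools.combinations(prots, 2):
        if kmers is not None and kmers[pa.protein_id].isdisjoint(kmers[pb.protein_id]):
            continue
        score = max(0.0, float(aligner.score(pa.sequence, pb.sequence)))
        shorter = pa if (len(pa.sequence), pa.protein_id) <= (len(pb.sequence), pb.protein_id) else pb
        norm = min(1.0, score / self_score[shorter.protein_id])
        if norm >= min_norm_score:
            edges.append(SimilarityEdge(pa.protein_id, pb.protein_id, score, norm))
    return edges


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_orthogroups(edges: Sequence[SimilarityEdge],
                        proteins: Sequence[ProteinRecord]) -> list[OrthoGroup]:
    """Reciprocal-best-hit clustering with in-paralog merging.

    For every ordered genome pair the best-scoring hit per query is found
    (ties broken by lexicographic protein id); inter-genome edges are kept
    iff reciprocal-best.  An intra-genome pair whose normalized score
    exceeds both proteins' best inter-genome normalized scores is merged
    as a pair of in-paralogs.  Connected components of the kept graph are
    the orthogroups; proteins without kept edges become singletons.
    Group ids are assigned deterministically from sorted member lists.
    """
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    # best inter-genome hit per (query protein, target genome)
    best: dict[tuple[str, str], tuple[float, str]] = {}
    # best inter-genome norm score per protein (any genome)
    best_any: dict[str, float] = {}
    inter, intra = [], []
    for e in edges:
        ga, gb = genome_of[e.protein_a], genome_of[e.protein_b]
        if ga == gb:
            intra.append(e)
            continue
        inter.append(e)
        for q, t, tg in ((e.protein_a, e.protein_b, gb), (e.protein_b, e.protein_a, ga)):
            key = (q, tg)
            cur = best.get(key)
            cand = (e.norm_score, t)
            # higher score wins; ties broken toward the lexicographically
            # smaller partner id
            if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                best[key] = cand
            if e.norm_score > best_any.get(q, 0.0):
                best_any[q] = e.norm_score

    uf = _UnionFind(genome_of)
    for e in inter:
        ga, gb = genome_of[e.protein_a], genome_of[e.protein_b]
        if (best[(e.protein_a, gb)][1] == e.protein_b
                and best[(e.protein_b, ga)][1] == e.protein_a):
            uf.union(e.protein_a, e.protein_b)
    for e in intra:
        if (e.norm_score > best_any.get(e.protein_a, 0.0)
                and e.norm_score > best_any.get(e.protein_b, 0.0)):
            uf.union(e.protein_a, e.protein_b)

    comps: dict[str, list[str]] = {}
    for pid in genome_of:
        comps.setdefault(uf.find(pid), []).append(pid)
    member_lists = sorted(tuple(sorted(m)) for m in comps.values())
    width = max(5, len(str(len(member_lists))))
    groups = []
    for i, members in enumerate(member_lists, start=1):
        groups.append(OrthoGroup(
            group_id=f"OG{i:0{width}d}",
            members=tuple((genome_of[p], p) for p in members),
        ))
    return groups


def mark_seed_groups(groups: Sequence[OrthoGroup],
                     seed_genes: Sequence[SeedGene],
                     gene_symbol_of: Mapping[str, str]) -> list[OrthoGroup]:
    """Flag groups containing a protein whose gene symbol or id matches a
    seed-gene entry.  ``gene_symbol_of`` maps protein ids to annotated
    gene symbols (for example parsed from FASTA descriptions)."""
    symbols = {s.gene_symbol for s in seed_genes}
    tags = {s.locus_tag for s in seed_genes if s.locus_tag}
    out = []
    for g in groups:
        hit = any(gene_symbol_of.get(p, "") in symbols or p in tags
                  for p in g.protein_ids)
        out.append(replace(g, is_seed_group=hit))
    return out


def single_copy_core(groups: Sequence[OrthoGroup],
                     genome_ids: Sequence[str]) -> list[OrthoGroup]:
    """Groups with exactly one member in every genome of the panel."""
    wanted = set(genome_ids)
    core = []
    for g in groups:
        counts: dict[str, int] = {}
        for gid, _ in g.members:
            counts[gid] = counts.get(gid, 0) + 1
        if set(counts) == wanted and all(c == 1 for c in counts.values()):
            core.append(g)
    return core


def concat_core_distances(core_groups: Sequence[OrthoGroup],
                          alignments: Sequence["object"]) -> DistanceMatrix:
    """Pairwise p-distances over the concatenation of per-group alignments.

    Each alignment's rows must be labelled by genome id.  The distance
    between two genomes is 1 - (identical columns / compared columns),
    where only columns with residues in both rows are compared.
    """
    if len(core_groups) != len(alignments):
        raise ValidationError("one alignment required per core group")
    genomes = sorted({gid for g in core_groups for gid, _ in g.members})
    concat = {g: [] for g in genomes}
    for grp, aln in zip(core_groups, alignments):
        rows = dict(zip(aln.row_ids, aln.rows))
        for g in genomes:
            if g not in rows:
                raise ValidationError(
                    f"alignment for group {grp.group_id} missing genome {g!r}")
            concat[g].append(rows[g])
    cat = {g: "".join(parts) for g, parts in concat.items()}
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cat[genomes[i]], cat[genomes[j]]
            compared = ident = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    compared += 1
                    if x == y:
                        ident += 1
            d[i, j] = d[j, i] = 1.0 - ident / compared if compared else 0.0
    return DistanceMatrix(genomes, d)


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero.  NJ recovers the generating tree exactly when the input
    distances are additive.
    """
    if len(d.taxon_ids) < 3:
        raise ValidationError("neighbor joining needs at least three taxa")
    import skbio
    from skbio.tree import nj as _nj

    dm = skbio.DistanceMatrix(d.values, ids=d.taxon_ids)
    tree = _nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(tree).strip()
    if not newick.endswith(";"):
        newick += ";"
    return newick
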
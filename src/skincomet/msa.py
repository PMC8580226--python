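"""Progressive multiple sequence alignment of orthogroup families.

A UPGMA guide tree on k-mer distances orders pairwise and
profile-profile merges.  Merges use global (Needleman-Wunsch) alignment
with affine gaps (a gap of length k costs ``gap_open + k*gap_extend``)
and BLOSUM62 column scores averaged over residue-bearing row pairs;
terminal gaps are penalized.  Once a gap is introduced it is never
removed ("once a gap, always a gap").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import AA20, ProteinRecord, ValidationError

_AA_INDEX = {a: i for i, a in enumerate(AA20)}

_NEG = -1e30  # effectively -inf but safe in arithmetic


def _blosum_matrix(name: str = "BLOSUM62") -> np.ndarray:
    mat = substitution_matrices.load(name)
    out = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            out[i, j] = mat[a][b]
    return out


@dataclass
class Msa:
    """An alignment: equal-length rows over amino acids plus '-'.

    Ungapping row i must reproduce the input sequence for ``row_ids[i]``.
    """

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValidationError("row_ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, row_id: str) -> str:
        return self.rows[self.row_ids.index(row_id)].replace("-", "")


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - |shared k-mers| / min(|kmers(a)|, |kmers(b)|), in [0, 1]."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(a) < k or len(b) < k:
        raise ValidationError(f"sequence shorter than k={k}")
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def guide_tree(seqs: Sequence[ProteinRecord], k: int = 3):
    """UPGMA guide tree on k-mer distances.

    Returns a nested-tuple topology over protein ids, deterministic under
    input reordering (sequences are sorted by id before clustering, and
    scipy's linkage resolves equal heights by cluster index).
    """
    if len(seqs) < 2:
        raise ValidationError("guide tree needs at least two sequences")
    ordered = sorted(seqs, key=lambda r: r.protein_id)
    ids = [r.protein_id for r in ordered]
    n = len(ordered)
    if n == 2:
        return (ids[0], ids[1])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_distance(ordered[i].sequence,
                                              ordered[j].sequence, k)
    z = linkage(squareform(d, checks=False), method="average")
    nodes: list[object] = list(ids)
    for a, b, _, _ in z:
        nodes.append((nodes[int(a)], nodes[int(b)]))
    return nodes[-1]


def _profile_counts(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue counts (cols x 20) and residue-bearing counts.

    'X' and '-' carry no substitution information and are excluded."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, 20))
    for row in rows:
        for j, c in enumerate(row):
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[j, idx] += 1
    return counts, counts.sum(axis=1)


def _align_profiles(rows_a: list[str], rows_b: list[str], blosum: np.ndarray,
                    gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles.

    Column score = mean BLOSUM score over residue-bearing row pairs (zero
    when a column pair has none).  Row-vectorized DP; the horizontal gap
    state is computed with a running-maximum scan.
    """
    ca, na = _profile_counts(rows_a)
    cb, nb = _profile_counts(rows_b)
    n, m = len(ca), len(cb)
    denom = np.outer(na, nb)
    S = np.where(denom > 0, (ca @ blosum @ cb.T) / np.maximum(denom, 1), 0.0)

    go, ge = gap_open + gap_extend, gap_extend  # first/subsequent gap char
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap columns in B (consumes A)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap columns in A (consumes B)
    M[0, 0] = 0.0
    Ix[1:, 0] = -(gap_open + ge * np.arange(1, n + 1))
    Iy[0, 1:] = -(gap_open + ge * np.arange(1, m + 1))
    j_idx = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        Ix[i] = np.maximum(M[i - 1] - go, Ix[i - 1] - ge)
        Ix[i, 0] = -(gap_open + ge * i)
        # Iy[i, j] = max_{k<j} (max(M,Ix)[i,k] - gap_open - (j-k)*ge)
        base = np.maximum(M[i], Ix[i]) + ge * j_idx
        run = np.maximum.accumulate(base[:-1])
        Iy[i, 1:] = run - gap_open - ge * j_idx[1:]
        Iy[i, 0] = _NEG

    # traceback (deterministic preference M > Ix > Iy)
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = n, m
    finals = {"M": M[n, m], "Ix": Ix[n, m], "Iy": Iy[n, m]}
    state = "M" if finals["M"] >= max(finals["Ix"], finals["Iy"]) else (
        "Ix" if finals["Ix"] >= finals["Iy"] else "Iy")
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            for rows, out, col in ((rows_a, out_a, i - 1), (rows_b, out_b, j - 1)):
                for r, o in zip(rows, out):
                    o.append(r[col])
            val = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if abs(val - M[i, j]) < tol:
                state = "M"
            elif abs(val - Ix[i, j]) < tol:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            for r, o in zip(rows_a, out_a):
                o.append(r[i - 1])
            for o in out_b:
                o.append("-")
            if i - 1 >= 0 and abs((M[i - 1, j] - go) - Ix[i, j]) < tol:
                state = "M"
            i -= 1
        else:
            for o in out_a:
                o.append("-")
            for r, o in zip(rows_b, out_b):
                o.append(r[j - 1])
            prev = np.maximum(M[i], Ix[i])
            # find the k where the horizontal gap opened
            if abs((prev[j - 1] - go) - Iy[i, j]) < tol:
                state = "M" if M[i, j - 1] >= Ix[i, j - 1] else "Ix"
            j -= 1
    return (["".join(reversed(o)) for o in out_a],
            ["".join(reversed(o)) for o in out_b])


def progressive_align(seqs: Sequence[ProteinRecord],
                      matrix: str = "BLOSUM62",
                      gap_open: float = 11.0, gap_extend: float = 1.0,
                      k: int = 3) -> Msa:
    """Align a family along its UPGMA guide tree.

    Single sequences return a trivial one-row alignment; two or more are
    merged bottom-up with :func:`_align_profiles`.
    """
    if not seqs:
        raise ValidationError("no sequences to align")
    by_id = {r.protein_id: r for r in seqs}
    if len(by_id) != len(seqs):
        raise ValidationError("duplicate protein ids in family")
    if len(seqs) == 1:
        rec = seqs[0]
        return Msa([rec.protein_id], [rec.sequence])
    blosum = _blosum_matrix(matrix)
    tree = guide_tree(seqs, k=k)

    def _build(node) -> tuple[list[str], list[str]]:
        if isinstance(node, str):
            return [node], [by_id[node].sequence]
        ids_a, rows_a = _build(node[0])
        ids_b, rows_b = _build(node[1])
        new_a, new_b = _align_profiles(rows_a, rows_b, blosum, gap_open, gap_extend)
        return ids_a + ids_b, new_a + new_b

    ids, rows = _build(tree)
    msa = Msa(ids, rows)
    for rid in ids:
        if msa.ungapped(rid) != by_id[rid].sequence:
            raise AssertionError(f"ungapping invariant violated for {rid}")
    # canonical row order: sorted by id (alignment itself is order-invariant)
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    return Msa([ids[i] for i in order], [rows[i] for i in order])
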
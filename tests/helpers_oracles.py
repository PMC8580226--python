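"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities by exhaustive enumeration (not by
the package's own dynamic programming) so that agreement is meaningful.
"""

import math

from skincomet import phmm


def enum_forward_bits(hmm, seq: str) -> float:
    """Sum over ALL local paths of the odds contribution, by explicit
    recursion: enter any match state (weight 1/M), walk the trained
    transitions, exit from any match state (weight 1/M).  Flanking
    residues are emitted by the null and contribute factor 1."""
    toks = phmm.encode_sequence(seq)
    L, M = len(toks), hmm.M
    bg = hmm.background

    def em(k, tok):
        return 1.0 if tok == 20 else hmm.match_emissions[k - 1, tok] / bg[tok]

    total = 0.0

    def walk(state, node, pos, w):
        nonlocal total
        if w == 0.0:
            return
        if state == "M":
            total += w / M  # exit here
            if node < M:
                if pos < L:
                    walk("M", node + 1, pos + 1, w * hmm.t_mm[node] * em(node + 1, toks[pos]))
                walk("D", node + 1, pos, w * hmm.t_md[node])
            if pos < L:
                walk("I", node, pos + 1, w * hmm.t_mi[node])
        elif state == "I":
            if node < M and pos < L:
                walk("M", node + 1, pos + 1, w * hmm.t_im[node] * em(node + 1, toks[pos]))
            if pos < L:
                walk("I", node, pos + 1, w * hmm.t_ii[node])
        else:  # D
            if node < M:
                if pos < L:
                    walk("M", node + 1, pos + 1, w * hmm.t_dm[node] * em(node + 1, toks[pos]))
                walk("D", node + 1, pos, w * hmm.t_dd[node])

    for i0 in range(L):
        for k in range(1, M + 1):
            walk("M", k, i0 + 1, (1.0 / M) * em(k, toks[i0]))
    return math.log2(total)


def enum_viterbi_bits(hmm, seq: str) -> float:
    """Best single local path, by the same explicit recursion."""
    toks = phmm.encode_sequence(seq)
    L, M = len(toks), hmm.M
    bg = hmm.background
    best = [-math.inf]

    def em(k, tok):
        return 1.0 if tok == 20 else hmm.match_emissions[k - 1, tok] / bg[tok]

    def walk(state, node, pos, w):
        if w == 0.0:
            return
        if state == "M":
            best[0] = max(best[0], w / M)
            if node < M:
                if pos < L:
                    walk("M", node + 1, pos + 1, w * hmm.t_mm[node] * em(node + 1, toks[pos]))
                walk("D", node + 1, pos, w * hmm.t_md[node])
            if pos < L:
                walk("I", node, pos + 1, w * hmm.t_mi[node])
        elif state == "I":
            if node < M and pos < L:
                walk("M", node + 1, pos + 1, w * hmm.t_im[node] * em(node + 1, toks[pos]))
            if pos < L:
                walk("I", node, pos + 1, w * hmm.t_ii[node])
        else:
            if node < M:
                if pos < L:
                    walk("M", node + 1, pos + 1, w * hmm.t_dm[node] * em(node + 1, toks[pos]))
                walk("D", node + 1, pos, w * hmm.t_dd[node])

    for i0 in range(L):
        for k in range(1, M + 1):
            walk("M", k, i0 + 1, (1.0 / M) * em(k, toks[i0]))
    return math.log2(best[0])


def random_tiny_model(rng, max_rows=4, max_cols=4, name="toy"):
    """A random small profile built from a random tiny alignment."""
    from skincomet.msa import Msa
    from skincomet.seqio import AA20

    n_rows = int(rng.integers(2, max_rows + 1))
    n_cols = int(rng.integers(1, max_cols + 1))
    rows = []
    for _ in range(n_rows):
        row = "".join(rng.choice(list(AA20 + "-"), size=n_cols))
        if not row.replace("-", ""):
            row = AA20[int(rng.integers(20))] + row[1:]
        rows.append(row)
    msa = Msa([f"s{i}" for i in range(n_rows)], rows)
    try:
        return phmm.build_profile(msa, name=name)
    except Exception:
        return None


def brute_force_global_score(a: str, b: str, blosum, gap_open=11.0, gap_extend=1.0):
    """Optimal global alignment score by exhaustive recursion (no DP
    reuse): a gap run of length k costs gap_open + k * gap_extend."""

    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(blosum[a[i]][b[j]] + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if last == "ga" else gap_open + gap_extend
            options.append(-cost + rec(i + 1, j, "ga"))
        if j < len(b):
            cost = gap_extend if last == "gb" else gap_open + gap_extend
            options.append(-cost + rec(i, j + 1, "gb"))
        return max(options)

    return rec(0, 0, None)


def random_additive_tree(rng, n_taxa=10):
    """A random binary tree with positive branch lengths and its exact
    patristic distance matrix.  Returns (taxon_ids, distance ndarray)."""
    import numpy as np

    ids = [f"t{i:02d}" for i in range(n_taxa)]
    # each cluster: dict taxon -> distance from cluster root
    clusters = [{t: 0.0} for t in ids]
    d = np.zeros((n_taxa, n_taxa))
    index = {t: i for i, t in enumerate(ids)}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi = rng.uniform(0.1, 1.0)
        bj = rng.uniform(0.1, 1.0)
        ci = {t: h + bi for t, h in clusters[i].items()}
        cj = {t: h + bj for t, h in clusters[j].items()}
        for ta, ha in ci.items():
            for tb, hb in cj.items():
                d[index[ta], index[tb]] = d[index[tb], index[ta]] = ha + hb
        clusters[i] = {**ci, **cj}
        clusters.pop(j)
    return ids, d
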
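"""Profile hidden Markov models for gene families, with gathering
thresholds.

A profile is estimated from a family alignment: columns with gap fraction
below ``max_gap_frac`` become match states, Laplace(+1) pseudocounts are
applied to emissions and transitions, and insert states emit the
background distribution.  Scoring is full-sequence log-odds against the
background null in a Smith-Waterman-style local architecture: a path
enters any match state (weight 1/M), traverses match/insert/delete states
with the trained transition probabilities, and exits from any match state
(weight 1/M); flanking residues are emitted by the null and contribute
zero.  Forward sums over all such paths, Viterbi takes the best one.
Scores are natural-log internally and bits (log2) at every interface.

The gathering threshold (GA) of a model is the midpoint between its
lowest-scoring true family member and the highest-scoring non-member
across the reference panel; a protein passes iff its bit score reaches
the GA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .msa import Msa
from .seqio import AA20, ProteinRecord, ValidationError

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
_LN2 = math.log(2.0)
_X_TOKEN = 20   # ambiguous residue: emits background, scores 0 bits
_PAD_TOKEN = 21

#: Background amino-acid frequencies (Robinson & Robinson averages),
#: used when no panel-derived background is supplied.
DEFAULT_BACKGROUND = np.array([
    0.0787, 0.0151, 0.0535, 0.0668, 0.0397, 0.0695, 0.0229, 0.0590,
    0.0595, 0.0963, 0.0238, 0.0425, 0.0484, 0.0340, 0.0512, 0.0683,
    0.0541, 0.0673, 0.0114, 0.0304,
])
DEFAULT_BACKGROUND = DEFAULT_BACKGROUND / DEFAULT_BACKGROUND.sum()


@dataclass
class ProfileHmm:
    """A calibrated profile HMM for one orthologous gene family.

    Transition arrays are indexed by node: node 0 is the begin state,
    nodes 1..M are match nodes and node M's outgoing "match" transition
    leads to the end state.  All probability rows sum to one.
    """

    name: str
    match_emissions: np.ndarray      # (M, 20)
    insert_emissions: np.ndarray     # (M+1, 20)
    t_mm: np.ndarray                 # (M+1,) M_k -> M_{k+1} (k=0 begin, k=M end)
    t_mi: np.ndarray                 # (M+1,) M_k -> I_k
    t_md: np.ndarray                 # (M+1,) M_k -> D_{k+1} (0 at k=M)
    t_im: np.ndarray                 # (M+1,) I_k -> M_{k+1}
    t_ii: np.ndarray                 # (M+1,) I_k -> I_k
    t_dm: np.ndarray                 # (M+1,) D_k -> M_{k+1} (unused at k=0)
    t_dd: np.ndarray                 # (M+1,) D_k -> D_{k+1} (0 at k=M)
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())
    ga_bits: float | None = None
    ga_overlap: bool = False
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        if self.M < 1:
            raise ValidationError("profile needs at least one match state")
        self.validate()

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        rows = [self.match_emissions, self.insert_emissions,
                np.stack([self.t_mm, self.t_mi, self.t_md], axis=1),
                np.stack([self.t_im, self.t_ii], axis=1),
                ]
        for r in rows:
            sums = np.asarray(r).sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("probability rows do not sum to 1")
        dsum = self.t_dm[1:] + self.t_dd[1:]
        if not np.allclose(dsum, 1.0, atol=1e-9):
            raise ValidationError("delete transition rows do not sum to 1")
        if self.ga_bits is not None and not math.isfinite(self.ga_bits):
            raise ValidationError("ga_bits must be finite when set")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer tokens (0-19 residues, 20 for 'X')."""
    if not seq:
        raise ValidationError("empty sequence")
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        tok = _AA_INDEX.get(c, _X_TOKEN if c == "X" else None)
        if tok is None:
            raise ValidationError(f"invalid residue {c!r} at position {i + 1}")
        out[i] = tok
    return out


def select_match_columns(msa: Msa, max_gap_frac: float = 0.5) -> list[bool]:
    """Flag alignment columns as match states.

    A column is a match column iff its gap fraction is strictly below
    ``max_gap_frac``; a column with exactly the threshold fraction of
    gaps becomes an insert column.
    """
    n_rows = len(msa.rows)
    if n_rows == 0:
        raise ValidationError("empty alignment")
    flags = []
    for j in range(msa.n_cols):
        gaps = sum(1 for row in msa.rows if row[j] == "-")
        flags.append(gaps / n_rows < max_gap_frac)
    if not any(flags):
        raise ValidationError("no match columns")
    return flags


def build_profile(msa: Msa, match_flags: Sequence[bool] | None = None,
                  pseudocount: float = 1.0,
                  background: np.ndarray | None = None,
                  name: str = "model") -> ProfileHmm:
    """Estimate a profile HMM from an alignment.

    Match emissions are ``(counts + pseudocount) / (residues + 20 *
    pseudocount)`` per column ('X' carries no information and is excluded
    from both counts); insert emissions are the background; transitions
    are counted from each row's path through the flagged architecture with
    a pseudocount of one on every transition type.  Insert regions
    adjacent to deletions are counted as if flanked by match states (a
    documented simplification; the classical architecture has no D<->I
    transitions).
    """
    if match_flags is None:
        match_flags = select_match_columns(msa)
    if len(match_flags) != msa.n_cols:
        raise ValidationError("match_flags length does not match alignment")
    bg = np.asarray(background if background is not None else DEFAULT_BACKGROUND,
                    dtype=float)
    bg = bg / bg.sum()
    match_cols = [j for j, f in enumerate(match_flags) if f]
    M = len(match_cols)
    pc = float(pseudocount)

    em_counts = np.zeros((M, 20))
    for k, j in enumerate(match_cols):
        for row in msa.rows:
            idx = _AA_INDEX.get(row[j])
            if idx is not None:
                em_counts[k, idx] += 1
    if pc == 0.0:
        totals = em_counts.sum(axis=1, keepdims=True)
        match_em = np.where(totals > 0, em_counts / np.maximum(totals, 1e-300),
                            bg)  # all-X column degenerates to background
    else:
        denom = em_counts.sum(axis=1, keepdims=True) + 20.0 * pc
        match_em = (em_counts + pc) / denom

    # transition counts per node; node 0 = begin, node M -> end
    c_mm = np.zeros(M + 1); c_mi = np.zeros(M + 1); c_md = np.zeros(M + 1)
    c_im = np.zeros(M + 1); c_ii = np.zeros(M + 1)
    c_dm = np.zeros(M + 1); c_dd = np.zeros(M + 1)
    insert_regions: list[list[int]] = [[] for _ in range(M + 1)]
    for row in msa.rows:
        # skeleton over match columns: 'm' (residue) or 'd' (gap)
        skeleton = ["m"]  # begin
        for j in match_cols:
            skeleton.append("d" if row[j] == "-" else "m")
        skeleton.append("m")  # end
        for k in range(M + 1):
            a, b = skeleton[k], skeleton[k + 1]
            if a == "m" and b == "m":
                c_mm[k] += 1
            elif a == "m":
                c_md[k] += 1
            elif b == "m":
                c_dm[k] += 1
            else:
                c_dd[k] += 1
        # insert regions: residues in non-match columns between nodes
        node = 0
        run = 0
        boundaries = set(match_cols)
        for j in range(msa.n_cols):
            if j in boundaries:
                if run:
                    c_mi[node] += 1
                    c_ii[node] += run - 1
                    c_im[node] += 1
                    if c_mm[node] > 0:
                        c_mm[node] -= 1
                    run = 0
                node += 1
            elif row[j] != "-":
                run += 1
        if run:
            c_mi[node] += 1
            c_ii[node] += run - 1
            c_im[node] += 1
            if c_mm[node] > 0:
                c_mm[node] -= 1

    def _norm_rows(stack: np.ndarray) -> np.ndarray:
        totals = stack.sum(axis=1, keepdims=True)
        zero = (totals[:, 0] == 0)
        stack = stack.copy()
        stack[zero, 0] = 1.0  # unobserved state: all mass on the ->M move
        totals = stack.sum(axis=1, keepdims=True)
        return stack / totals

    # node M cannot transition to D_{M+1}
    m_stack = np.stack([c_mm, c_mi, c_md], axis=1) + pc
    m_stack[M, 2] = 0.0
    t_mm, t_mi, t_md = _norm_rows(m_stack).T
    t_im, t_ii = _norm_rows(np.stack([c_im, c_ii], axis=1) + pc).T
    d_stack = np.stack([c_dm, c_dd], axis=1) + pc
    d_stack[M, 1] = 0.0
    d_stack[0] = [1.0, 0.0]
    t_dm, t_dd = _norm_rows(d_stack).T

    return ProfileHmm(
        name=name,
        match_emissions=match_em,
        insert_emissions=np.tile(bg, (M + 1, 1)),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
        background=bg,
        members=tuple(msa.row_ids),
    )


def _log_params(hmm: ProfileHmm):
    """Natural-log emission odds and transition tables for scoring."""
    with np.errstate(divide="ignore"):
        E = np.full((hmm.M, 22), -np.inf)
        E[:, :20] = np.log(hmm.match_emissions) - np.log(hmm.background)
        E[:, _X_TOKEN] = 0.0
        ln_mm = np.log(hmm.t_mm)
        ln_mi = np.log(hmm.t_mi)
        ln_md = np.log(np.maximum(hmm.t_md, 1e-300))
        ln_im = np.log(hmm.t_im)
        ln_ii = np.log(hmm.t_ii)
        ln_dm = np.log(np.maximum(hmm.t_dm, 1e-300))
        ln_dd = np.log(np.maximum(hmm.t_dd, 1e-300))
    return E, ln_mm, ln_mi, ln_md, ln_im, ln_ii, ln_dm, ln_dd


@njit(cache=True)
def _forward_kernel(X: np.ndarray, lengths: np.ndarray, em_odds: np.ndarray,
                    t_mm: np.ndarray, t_mi: np.ndarray, t_md: np.ndarray,
                    t_im: np.ndarray, t_ii: np.ndarray,
                    t_dm: np.ndarray, t_dd: np.ndarray) -> np.ndarray:
    """Forward DP in odds space with per-row rescaling.

    Cell values hold odds ratios divided by a running scale factor whose
    log is tracked per sequence; rescaling keeps everything inside double
    range, and contributions more than ~300 orders of magnitude below the
    row maximum underflow to zero (far beyond the 1e-9-bit contract).
    """
    B, L = X.shape
    M = em_odds.shape[0]
    entry = 1.0 / M
    exit_w = 1.0 / M
    out = np.empty(B)
    prevM = np.zeros(M + 1)
    prevI = np.zeros(M + 1)
    prevD = np.zeros(M + 1)
    curM = np.zeros(M + 1)
    curI = np.zeros(M + 1)
    curD = np.zeros(M + 1)
    for b in range(B):
        for k in range(M + 1):
            prevM[k] = prevI[k] = prevD[k] = 0.0
        log_scale = 0.0
        total = -np.inf  # log of summed exit odds
        for i in range(lengths[b]):
            x = X[b, i]
            scaled_entry = math.exp(-math.log(M) - log_scale) if log_scale < 700.0 else 0.0
            curM[0] = 0.0
            row_sum = 0.0
            row_max = 0.0
            for k in range(1, M + 1):
                inc = (scaled_entry
                       + prevM[k - 1] * t_mm[k - 1]
                       + prevI[k - 1] * t_im[k - 1]
                       + prevD[k - 1] * t_dm[k - 1])
                v = em_odds[k - 1, x] * inc
                curM[k] = v
                row_sum += v
                if v > row_max:
                    row_max = v
            for k in range(M + 1):
                # insert states emit the background: odds factor 1
                v = prevM[k] * t_mi[k] + prevI[k] * t_ii[k]
                curI[k] = v
                if v > row_max:
                    row_max = v
            curD[0] = 0.0
            if M >= 1:
                curD[1] = 0.0
            for k in range(2, M + 1):
                v = curM[k - 1] * t_md[k - 1] + curD[k - 1] * t_dd[k - 1]
                curD[k] = v
                if v > row_max:
                    row_max = v
            if row_sum > 0.0:
                contrib = math.log(row_sum * exit_w) + log_scale
                if contrib > total:
                    total, contrib = contrib, total
                d = contrib - total
                if d > -745.0:
                    total = total + math.log1p(math.exp(d))
            if row_max > 1e250 or (0.0 < row_max < 1e-250):
                inv = 1.0 / row_max
                for k in range(M + 1):
                    curM[k] *= inv
                    curI[k] *= inv
                    curD[k] *= inv
                log_scale += math.log(row_max)
            prevM, curM = curM, prevM
            prevI, curI = curI, prevI
            prevD, curD = curD, prevD
        out[b] = total
    return out


def _odds_params(hmm: ProfileHmm) -> np.ndarray:
    """Match-emission odds lookup (M x 22): residues 0-19, X -> 1, pad -> 0."""
    odds = np.zeros((hmm.M, 22))
    odds[:, :20] = hmm.match_emissions / hmm.background
    odds[:, _X_TOKEN] = 1.0
    return odds


def score_forward_many(hmm: ProfileHmm, seqs: Sequence[str]) -> np.ndarray:
    """Forward (sum over all local paths) log-odds scores in bits for a
    batch of sequences; equivalent to exhaustive path enumeration."""
    if not seqs:
        return np.zeros(0)
    toks = [encode_sequence(s) for s in seqs]
    L = max(len(t) for t in toks)
    X = np.full((len(seqs), L), _PAD_TOKEN, dtype=np.int64)
    lengths = np.empty(len(seqs), dtype=np.int64)
    for b, t in enumerate(toks):
        X[b, :len(t)] = t
        lengths[b] = len(t)
    nats = _forward_kernel(X, lengths, _odds_params(hmm),
                           hmm.t_mm, hmm.t_mi, hmm.t_md,
                           hmm.t_im, hmm.t_ii, hmm.t_dm, hmm.t_dd)
    return nats / _LN2


def score_forward(hmm: ProfileHmm, seq: str) -> float:
    """Forward log-odds score of one sequence, in bits."""
    return float(score_forward_many(hmm, [seq])[0])


def score_viterbi(hmm: ProfileHmm, seq: str) -> tuple[float, list[tuple[str, int]]]:
    """Best-path log-odds score in bits and the state path, as a list of
    (state, node) pairs with state in {'M', 'I', 'D'}.

    Viterbi never exceeds forward (a max never exceeds the sum).
    """
    E, ln_mm, ln_mi, ln_md, ln_im, ln_ii, ln_dm, ln_dd = _log_params(hmm)
    toks = encode_sequence(seq)
    M, L = hmm.M, len(toks)
    ln_entry = ln_exit = -math.log(M)
    neg = -np.inf
    Vm = np.full((L + 1, M + 1), neg)
    Vi = np.full((L + 1, M + 1), neg)
    Vd = np.full((L + 1, M + 1), neg)
    for i in range(1, L + 1):
        emit = E[:, toks[i - 1]]
        inc = np.maximum(np.maximum(Vm[i - 1, :-1] + ln_mm[:-1],
                                    Vi[i - 1, :-1] + ln_im[:-1]),
                         Vd[i - 1, :-1] + ln_dm[:-1])
        Vm[i, 1:] = emit + np.maximum(ln_entry, inc[:M])
        Vi[i] = np.maximum(Vm[i - 1] + ln_mi, Vi[i - 1] + ln_ii)
        for k in range(2, M + 1):
            Vd[i, k] = max(Vm[i, k - 1] + ln_md[k - 1], Vd[i, k - 1] + ln_dd[k - 1])
    ends = Vm[1:, 1:] + ln_exit
    best_flat = int(np.argmax(ends))
    best = float(ends.flat[best_flat])
    i, k = best_flat // M + 1, best_flat % M + 1

    path: list[tuple[str, int]] = []
    state = "M"
    tol = 1e-9

    def _close(a: float, b: float) -> bool:
        return math.isfinite(b) and abs(a - b) < tol

    while True:
        path.append((state, k))
        if state == "M":
            val = Vm[i, k] - E[k - 1, toks[i - 1]]
            i -= 1
            if _close(val, Vm[i, k - 1] + ln_mm[k - 1]):
                state, k = "M", k - 1
            elif _close(val, Vi[i, k - 1] + ln_im[k - 1]):
                state, k = "I", k - 1
            elif _close(val, Vd[i, k - 1] + ln_dm[k - 1]):
                state, k = "D", k - 1
            else:
                break  # local entry into this match state
        elif state == "I":
            val = Vi[i, k]
            i -= 1
            state = "M" if _close(val, Vm[i, k] + ln_mi[k]) else "I"
        else:  # D
            val = Vd[i, k]
            k -= 1
            state = "M" if _close(val, Vm[i, k] + ln_md[k]) else "D"
    path.reverse()
    return best / _LN2, path


@dataclass(frozen=True)
class ScoreReport:
    model_name: str
    protein_id: str
    bits: float
    passes_ga: bool


def calibrate_ga(hmm: ProfileHmm,
                 positives: Sequence[ProteinRecord],
                 negatives: Sequence[ProteinRecord],
                 pos_scores: np.ndarray | None = None,
                 neg_scores: np.ndarray | None = None,
                 empty_negative_margin: float = 0.5) -> float:
    """Calibrate the gathering threshold of a model.

    GA = (lowest true-positive score + highest true-negative score) / 2,
    with the family's orthogroup members as true positives and all other
    panel proteins as true negatives.  When the score ranges overlap
    (max negative >= min positive) the ``ga_overlap`` flag is raised.
    With no negatives, GA falls back to min(positives) minus a
    conservative margin, flagged the same way.

    Precomputed score arrays may be passed to avoid rescoring.
    """
    if not positives:
        raise ValidationError("calibration requires at least one positive")
    if pos_scores is None:
        pos_scores = score_forward_many(hmm, [p.sequence for p in positives])
    pos_scores = np.asarray(pos_scores, dtype=float)
    if negatives or (neg_scores is not None and len(neg_scores)):
        if neg_scores is None:
            neg_scores = score_forward_many(hmm, [p.sequence for p in negatives])
        neg_scores = np.asarray(neg_scores, dtype=float)
        ga = (float(pos_scores.min()) + float(neg_scores.max())) / 2.0
        hmm.ga_overlap = bool(neg_scores.max() >= pos_scores.min())
    else:
        ga = float(pos_scores.min()) - empty_negative_margin
        hmm.ga_overlap = True
    hmm.ga_bits = ga
    return ga


def score_report(hmm: ProfileHmm, proteins: Sequence[ProteinRecord]) -> list[ScoreReport]:
    if hmm.ga_bits is None:
        raise ValidationError(f"model {hmm.name!r} has no gathering threshold")
    bits = score_forward_many(hmm, [p.sequence for p in proteins])
    return [ScoreReport(hmm.name, p.protein_id, float(b), bool(b >= hmm.ga_bits))
            for p, b in zip(proteins, bits)]


# ----------------------------------------------------------------------
# model collection file (HMMER3-style text dialect)

def _fmt_neglog(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.10e}"


def _parse_neglog(tok: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError as exc:
        raise ValidationError(f"line {lineno}: bad probability token {tok!r}") from exc


def write_model_file(models: Sequence[ProfileHmm], path: str | Path) -> None:
    """Write a model collection as text: one block per model with NAME,
    LENG, optional GA, background, and per-node emission/transition lines
    holding negative natural-log probabilities ('*' for zero)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("SKINCOMET-HMM 1.0\n")
        for hmm in models:
            fh.write(f"NAME  {hmm.name}\n")
            fh.write(f"LENG  {hmm.M}\n")
            if hmm.ga_bits is not None:
                fh.write(f"GA    {hmm.ga_bits!r}\n")
            if hmm.members:
                fh.write(f"MEMB  {' '.join(hmm.members)}\n")
            fh.write("BG    " + " ".join(_fmt_neglog(p) for p in hmm.background) + "\n")
            fh.write("HMM\n")
            for k in range(hmm.M + 1):
                trans = [hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k],
                         hmm.t_im[k], hmm.t_ii[k], hmm.t_dm[k], hmm.t_dd[k]]
                fh.write(f"  {k} T " + " ".join(_fmt_neglog(p) for p in trans) + "\n")
                fh.write(f"  {k} I " + " ".join(_fmt_neglog(p) for p in hmm.insert_emissions[k]) + "\n")
                if k >= 1:
                    fh.write(f"  {k} M " + " ".join(_fmt_neglog(p) for p in hmm.match_emissions[k - 1]) + "\n")
            fh.write("//\n")


def read_model_file(path: str | Path) -> list[ProfileHmm]:
    """Read a model collection written by :func:`write_model_file`.

    Malformed or truncated files raise :class:`ValidationError` with the
    offending line number.  A model without a GA line loads with
    ``ga_bits`` unset.
    """
    models: list[ProfileHmm] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("SKINCOMET-HMM"):
        raise ValidationError(f"{path}:1: not a skincomet model file")
    i = 1
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        header: dict[str, str] = {}
        while i < n_lines and not lines[i].startswith("HMM"):
            parts = lines[i].split(None, 1)
            if len(parts) != 2:
                raise ValidationError(f"{path}:{i + 1}: malformed header line")
            header[parts[0]] = parts[1]
            i += 1
        if i >= n_lines:
            raise ValidationError(f"{path}:{i}: truncated model block")
        if "NAME" not in header or "LENG" not in header:
            raise ValidationError(f"{path}:{i + 1}: model missing NAME or LENG")
        M = int(header["LENG"])
        bg = np.array([_parse_neglog(t, i) for t in header.get("BG", "").split()])
        if bg.size != 20:
            raise ValidationError(f"{path}:{i + 1}: background must have 20 entries")
        i += 1  # past "HMM"
        match_em = np.zeros((M, 20))
        ins_em = np.zeros((M + 1, 20))
        trans = np.zeros((M + 1, 7))
        expected = []
        for k in range(M + 1):
            expected.append((k, "T"))
            expected.append((k, "I"))
            if k >= 1:
                expected.append((k, "M"))
        for k, kind in expected:
            if i >= n_lines:
                raise ValidationError(f"{path}:{n_lines}: truncated model {header['NAME']!r}")
            toks = lines[i].split()
            if len(toks) < 2 or toks[0] != str(k) or toks[1] != kind:
                raise ValidationError(f"{path}:{i + 1}: expected node {k} {kind} line")
            vals = [_parse_neglog(t, i + 1) for t in toks[2:]]
            need = 7 if kind == "T" else 20
            if len(vals) != need:
                raise ValidationError(f"{path}:{i + 1}: expected {need} values")
            if kind == "T":
                trans[k] = vals
            elif kind == "I":
                ins_em[k] = vals
            else:
                match_em[k - 1] = vals
            i += 1
        if i >= n_lines or lines[i].strip() != "//":
            raise ValidationError(f"{path}:{i + 1}: missing '//' terminator")
        i += 1
        ga = float(header["GA"]) if "GA" in header else None
        hmm = ProfileHmm(
            name=header["NAME"], match_emissions=match_em,
            insert_emissions=ins_em,
            t_mm=trans[:, 0], t_mi=trans[:, 1], t_md=trans[:, 2],
            t_im=trans[:, 3], t_ii=trans[:, 4], t_dm=trans[:, 5], t_dd=trans[:, 6],
            background=bg, ga_bits=ga,
            members=tuple(header.get("MEMB", "").split()),
        )
        models.append(hmm)
    return models
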
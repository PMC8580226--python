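"""Skin-aging statistics: the SA score, constrained ordination (RDA),
per-pathway linear models, and heatmap-ready normalized tables.

The skin-aging (SA) score aggregates eight clinical measurements into one
per-subject scalar: each measurement is z-scored, multiplied by an
orientation sign (+1 when larger values look older; skin color evenness
is oriented -1 because evenness decreases with aging), and averaged.
Higher SA = older-looking skin.

RDA here is ordination constrained by a single variable (the SA score or
a two-level age-group indicator): the response table is transformed
(Hellinger by default), column-centered, and projected onto the
constraint; variance explained is the fitted sum of squares over the
total, and significance comes from a seeded permutation test on the
pseudo-F statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import LabeledMatrix, ModuleDef, NormState, ValidationError

logger = logging.getLogger(__name__)

#: The eight clinical measurements, column names of a phenotype table.
EIGHT_MEASUREMENTS = (
    "pores_number",
    "roughness",
    "wrinkles_number",
    "porphyrins_number",
    "red_features_number",
    "skin_color_evenness",
    "spots_visible_number",
    "spots_invisible_number",
)

#: Default per-measurement orientation: +1 when a larger value is
#: associated with older-looking skin.  Evenness decreases with aging.
DEFAULT_ORIENTATION: dict[str, int] = {
    m: (-1 if m == "skin_color_evenness" else 1) for m in EIGHT_MEASUREMENTS
}


@dataclass
class RdaResult:
    var_explained: float
    pseudo_f: float
    perm_p: float
    site_scores: pd.Series
    arrow_scores: pd.Series
    n_perm: int
    seed: int


@dataclass(frozen=True)
class PathwayLmResult:
    pathway: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    q_value: float | None = None


def compute_sa_score(pheno: pd.DataFrame,
                     orientation: Mapping[str, int] | None = None) -> pd.Series:
    """Oriented z-score mean of the eight clinical measurements.

    Subjects with missing values are dropped with a warning; columns with
    zero variance carry no information and are dropped with a warning.
    """
    orient = dict(DEFAULT_ORIENTATION if orientation is None else orientation)
    missing = [c for c in EIGHT_MEASUREMENTS if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {', '.join(missing)}")
    df = pheno[list(EIGHT_MEASUREMENTS)].astype(float)
    has_na = df.isna().any(axis=1)
    if has_na.any():
        logger.warning("dropping subjects with missing values: %s",
                       ", ".join(map(str, df.index[has_na])))
        df = df[~has_na]
    if len(df) < 3:
        raise ValidationError("SA score needs at least three subjects")
    z_cols = {}
    for col in df.columns:
        sd = df[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("dropping zero-variance measurement %r", col)
            continue
        z_cols[col] = orient.get(col, 1) * (df[col] - df[col].mean()) / sd
    if not z_cols:
        return pd.Series(0.0, index=df.index, name="sa_score")
    sa = pd.DataFrame(z_cols).mean(axis=1)
    sa.name = "sa_score"
    return sa


def _transform(Y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return Y.astype(float)
    if transform == "log1p":
        return np.log1p(Y)
    if transform == "hellinger":
        totals = Y.sum(axis=1, keepdims=True)
        props = np.divide(Y, np.where(totals > 0, totals, 1.0))
        return np.sqrt(props)
    raise ValidationError(f"unknown transform {transform!r}")


def rda(response: LabeledMatrix | pd.DataFrame,
        constraint: pd.Series | Sequence[float],
        transform: str = "hellinger",
        n_perm: int = 999,
        seed: int = 0) -> RdaResult:
    """Redundancy analysis with one constraining variable.

    The permutation p-value is ``(1 + #{permuted F >= observed F}) /
    (1 + n_perm)`` with the constraint permuted over samples; it is
    invariant to affine rescaling of the constraint.
    """
    df = response.df if isinstance(response, LabeledMatrix) else response
    x = np.asarray(constraint, dtype=float)
    n = len(df)
    if x.shape != (n,):
        raise ValidationError("constraint length does not match samples")
    if n < 4:
        raise ValidationError("RDA needs at least four samples")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if np.ptp(x) == 0:
        raise ValidationError("constraint is constant")

    Y = _transform(df.to_numpy(dtype=float), transform)
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    ss_total = float((Yc ** 2).sum())
    if ss_total == 0:
        raise ValidationError("response has no variance")

    def _fit_ss(xv: np.ndarray) -> tuple[float, np.ndarray]:
        xtx = float(xv @ xv)
        b = (xv @ Yc) / xtx
        return float((xv @ xv) * (b @ b)), b

    ss_fit, b = _fit_ss(xc)
    q = 1
    ss_res = ss_total - ss_fit
    pseudo_f = (ss_fit / q) / (ss_res / (n - q - 1)) if ss_res > 0 else np.inf

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = rng.permutation(xc)
        ss_p, _ = _fit_ss(xp)
        ss_rp = ss_total - ss_p
        f_p = (ss_p / q) / (ss_rp / (n - q - 1)) if ss_rp > 0 else np.inf
        if f_p >= pseudo_f:
            exceed += 1
    perm_p = (1 + exceed) / (1 + n_perm)

    b_norm = float(np.linalg.norm(b))
    site = pd.Series(xc * b_norm, index=df.index, name="rda1")
    arrows = pd.Series(b * np.sqrt(float(xc @ xc)), index=df.columns,
                       name="rda1_loading")
    return RdaResult(
        var_explained=ss_fit / ss_total,
        pseudo_f=pseudo_f,
        perm_p=perm_p,
        site_scores=site,
        arrow_scores=arrows,
        n_perm=n_perm,
        seed=seed,
    )


def top_arrows(result: RdaResult, k: int) -> list[tuple[str, float]]:
    """The k variables with the largest absolute constrained-axis
    loadings, signed; ties broken lexicographically.  Defaults in the
    workflow: k=20 for OTU-level runs, k=15 for gene-level runs."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    scores = result.arrow_scores
    if k > len(scores):
        warnings.warn(f"k={k} exceeds {len(scores)} variables; returning all")
        k = len(scores)
    ranked = sorted(scores.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [(str(name), float(v)) for name, v in ranked[:k]]


def pathway_scores(gene_table: LabeledMatrix | pd.DataFrame,
                   catalog: Sequence[ModuleDef]) -> pd.DataFrame:
    """Per-sample pathway scores: the sum of member gene-model columns."""
    df = gene_table.df if isinstance(gene_table, LabeledMatrix) else gene_table
    out = {}
    for mod in catalog:
        missing = [m for m in mod.member_models if m not in df.columns]
        if missing:
            logger.warning("pathway %s: missing gene models zero-filled: %s",
                           mod.pathway, ", ".join(missing))
        present = [m for m in mod.member_models if m in df.columns]
        out[mod.pathway] = (df[present].sum(axis=1) if present
                            else pd.Series(0.0, index=df.index))
    return pd.DataFrame(out, index=df.index)


def pathway_lm(scores: pd.DataFrame, sa: pd.Series,
               fdr: bool = False) -> list[PathwayLmResult]:
    """Ordinary least squares of each pathway score on the SA score.

    Returns slope, intercept, r-squared and the two-sided p-value for the
    slope; with ``fdr`` a Benjamini-Hochberg q-value is added across
    pathways.
    """
    common = scores.index.intersection(sa.index)
    if len(common) < 4:
        raise ValidationError("pathway linear models need at least four subjects")
    X = sa.loc[common].to_numpy(dtype=float)
    results = []
    for pathway in scores.columns:
        y = scores.loc[common, pathway].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            results.append(PathwayLmResult(str(pathway), 0.0, float(y.mean()),
                                           0.0, 1.0))
            continue
        fit = stats.linregress(X, y)
        results.append(PathwayLmResult(
            pathway=str(pathway),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r2=float(fit.rvalue ** 2),
            p_value=float(fit.pvalue),
        ))
    if fdr:
        from statsmodels.stats.multitest import multipletests

        pvals = [r.p_value for r in results]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        results = [PathwayLmResult(r.pathway, r.slope, r.intercept, r.r2,
                                   r.p_value, float(q))
                   for r, q in zip(results, qvals)]
    return results


def rowmax_normalize(matrix: LabeledMatrix | pd.DataFrame) -> LabeledMatrix:
    """Scale each row by its maximum (for pathway x subject heatmaps);
    zero rows are preserved.  Idempotent."""
    df = matrix.df if isinstance(matrix, LabeledMatrix) else matrix
    maxima = df.max(axis=1)
    out = df.div(maxima.replace(0.0, 1.0), axis=0)
    return LabeledMatrix(out, NormState.row_max)


def order_by_sa(matrix: pd.DataFrame, sa: pd.Series) -> pd.DataFrame:
    """Order subject columns by ascending SA score (young-looking left,
    old-looking right), for heatmap export."""
    cols = [c for c in sa.sort_values().index if c in matrix.columns]
    return matrix[cols]
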
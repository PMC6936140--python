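"""Mass pairwise miRNA -> gene linear regression per pathological stage.

For every (miRNA, gene) pair within one stage's samples, gene expression is
regressed on miRNA expression by ordinary least squares (the Matrix-eQTL
convention, with the miRNA in the regulator slot):

    y_g = alpha + beta * x_m + eps

The Wald t statistic beta_hat / SE(beta_hat) on n-2 degrees of freedom gives
a two-sided p-value; Benjamini-Hochberg q-values are computed over all
m = n_mirnas * n_genes tests of the stage, and pairs with q <= fdr are kept.
Each significant pair is annotated with a genomic distance bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import FeatureAnnotation, FeatureAnnotationSet
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "fit_pair",
    "bh_fdr",
    "run_stage",
    "classify_distance",
    "summarize_bins",
    "DISTANCE_BINS",
    "records_to_frame",
]

#: Distance bins for same-chromosome pairs, upper-inclusive, in bp; plus CrossChr.
DISTANCE_BINS = ("(0,1MB]", "(1,10MB]", "(10,50MB]", "(50,100MB]", "(100,200MB]", ">200MB", "CrossChr")

_BIN_EDGES = (1e6, 1e7, 5e7, 1e8, 2e8)

# Smallest p kept after underflow clamping, so BH stays defined.
P_FLOOR = 1e-300


@dataclass
class AssociationRecord:
    """One significant miRNA-gene association within a stage."""

    mirna_id: str
    gene_id: str
    stage: str
    beta: float
    t_stat: float
    p_value: float
    q_value: float
    distance_bin: str | None = None  # None when either feature is unannotated


def fit_pair(x_mirna: np.ndarray, y_gene: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS of ``y`` on ``x``; returns (beta, t, two-sided p).

    Raises ``ValueError`` on unequal lengths, n < 3, missing values, or a
    zero-variance predictor (callers skip and log such pairs).
    """
    x = np.asarray(x_mirna, dtype=np.float64)
    y = np.asarray(y_gene, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed in fit_pair")
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        raise ValueError("zero variance in predictor")
    beta = float(xc @ yc) / ssx
    resid = yc - beta * xc
    ss_res = float(resid @ resid)
    df = n - 2
    if ss_res <= 0.0:
        # perfect fit: p underflows; clamp
        t = np.inf if beta != 0 else 0.0
        return beta, float(t), P_FLOOR
    se = np.sqrt(ss_res / df / ssx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(t), float(max(p, P_FLOOR))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.  All p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d array")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_distance(a: FeatureAnnotation, b: FeatureAnnotation) -> str:
    """Bin the minimal gap between two feature intervals.

    Cross-chromosome pairs go to ``CrossChr``.  Same-chromosome pairs use
    the minimal inter-interval distance (0 for overlapping or adjacent
    intervals), binned upper-inclusively; overlapping features land in
    ``(0,1MB]``.
    """
    if a.chrom != b.chrom:
        return "CrossChr"
    gap = max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
    for edge, name in zip(_BIN_EDGES, DISTANCE_BINS):
        if gap <= edge:
            return name
    return ">200MB"


def _vectorized_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs OLS of every row of Y on every row of X.

    Returns (beta, t, p, valid) of shape (n_x, n_y); ``valid`` is False for
    zero-variance predictors (those rows carry NaN statistics).
    """
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ssx = np.einsum("ij,ij->i", Xc, Xc)
    ssy = np.einsum("ij,ij->i", Yc, Yc)
    valid = ssx > 0
    ssx_safe = np.where(valid, ssx, 1.0)
    cross = Xc @ Yc.T  # (n_x, n_y)
    beta = cross / ssx_safe[:, None]
    ss_res = np.maximum(ssy[None, :] - beta * cross, 0.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta * np.sqrt(df * ssx_safe[:, None] / ss_res)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)  # perfect fits -> clamp below
    p = np.maximum(p, P_FLOOR)
    beta[~valid] = np.nan
    t[~valid] = np.nan
    p[~valid] = np.nan
    return beta, t, p, valid


def run_stage(
    mirna: ExpressionMatrix,
    gene: ExpressionMatrix,
    stage: str,
    fdr: float = 0.05,
    annotations: FeatureAnnotationSet | None = None,
) -> list[AssociationRecord]:
    """Test every miRNA-gene pair in one stage; return records with q <= fdr.

    Both matrices must carry the same samples in the same order (the stage's
    cohort).  BH correction spans all n_mirnas * n_genes tests of the stage.
    """
    if mirna.sample_ids != gene.sample_ids:
        raise ValueError("miRNA and gene matrices must share identically ordered samples")
    n = mirna.n_samples
    if n < 4:
        raise ValueError(
            f"stage {stage!r} has only {n} samples; at least 4 are required for a "
            "minimally powered regression"
        )
    X = mirna.values.to_numpy(np.float64)
    Y = gene.values.to_numpy(np.float64)
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("matrices must be preprocessed (no missing values)")
    beta, t, p, valid = _vectorized_ols(X, Y)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("run_stage[%s]: skipped %d zero-variance miRNAs", stage, n_skipped)
    flat_p = p[valid].ravel()
    q_flat = bh_fdr(flat_p)
    q = np.full(p.shape, np.nan)
    q[valid] = q_flat.reshape((int(valid.sum()), p.shape[1]))

    mirna_ids = mirna.feature_ids
    gene_ids = gene.feature_ids
    records: list[AssociationRecord] = []
    hit_i, hit_j = np.where(valid[:, None] & (q <= fdr))
    for i, j in zip(hit_i.tolist(), hit_j.tolist()):
        rec = AssociationRecord(
            mirna_id=mirna_ids[i],
            gene_id=gene_ids[j],
            stage=stage,
            beta=float(beta[i, j]),
            t_stat=float(t[i, j]),
            p_value=float(p[i, j]),
            q_value=float(q[i, j]),
        )
        if annotations is not None:
            fa = annotations.get(rec.mirna_id)
            fb = annotations.get(rec.gene_id)
            if fa is not None and fb is not None:
                rec.distance_bin = classify_distance(fa, fb)
            else:
                logger.warning("run_stage[%s]: %s or %s unannotated; no distance bin",
                               stage, rec.mirna_id, rec.gene_id)
        records.append(rec)
    return records


def summarize_bins(records: list[AssociationRecord]) -> pd.DataFrame:
    """Per-stage count of significant associations in each distance bin.

    Records lacking a distance bin (unannotated features) are excluded; row
    sums therefore equal the number of fully annotated records per stage.
    """
    stages = sorted({r.stage for r in records})
    table = pd.DataFrame(0, index=stages, columns=list(DISTANCE_BINS), dtype=int)
    for r in records:
        if r.distance_bin is not None:
            table.loc[r.stage, r.distance_bin] += 1
    table.index.name = "stage"
    return table


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna_id, "gene": r.gene_id, "stage": r.stage,
                "beta": r.beta, "t": r.t_stat, "p": r.p_value, "q": r.q_value,
                "distance_bin": r.distance_bin if r.distance_bin is not None else "NA",
            }
            for r in records
        ],
        columns=["mirna", "gene", "stage", "beta", "t", "p", "q", "distance_bin"],
    )
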
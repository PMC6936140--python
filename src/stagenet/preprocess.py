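"""Expression preprocessing: missingness filters and rank-based inverse
normal transform.

The rules mirror standard eQTL practice: drop features with more than 10%
missing entries, drop samples with unknown stage or remaining missing
values, then replace each feature's values by standard-normal quantiles of
their within-feature ranks ("inverse quantile normalization").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_features",
    "filter_samples",
    "inverse_quantile_normalize",
    "preprocess_stage",
    "EmptyCohortError",
]


class EmptyCohortError(RuntimeError):
    """Raised when filtering leaves no usable samples."""


def filter_features(m: ExpressionMatrix, max_missing_frac: float = 0.10) -> ExpressionMatrix:
    """Drop features whose missing fraction strictly exceeds ``max_missing_frac``.

    A feature missing in exactly 10% of samples survives the default
    threshold; only "over 10%" is removed.
    """
    if not (0 <= max_missing_frac < 1):
        raise ValueError("max_missing_frac must be in [0, 1)")
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_features: dropped %d/%d features over %.0f%% missing",
                    n_dropped, m.n_features, 100 * max_missing_frac)
    return ExpressionMatrix(m.values.loc[keep].copy(), dict(m.stage))


def filter_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop samples with unknown stage, then samples still containing
    missing values.  Column order of survivors is preserved."""
    known = [s for s in m.sample_ids if m.stage.get(s) in {"I", "II", "III", "IV"}]
    sub = m.values.loc[:, known]
    complete = sub.columns[~sub.isna().any(axis=0)]
    if len(complete) == 0:
        raise EmptyCohortError(
            "no samples survive stage/missingness filtering "
            f"(started with {m.n_samples}, {len(known)} had a known stage)"
        )
    dropped = m.n_samples - len(complete)
    if dropped:
        logger.info("filter_samples: dropped %d/%d samples", dropped, m.n_samples)
    return ExpressionMatrix(sub.loc[:, complete].copy(), dict(m.stage))


def _int_ranks_to_normal(row: np.ndarray, offset: str) -> np.ndarray:
    n = row.size
    r = stats.rankdata(row, method="average")
    if offset == "blom":
        q = (r - 3.0 / 8.0) / (n + 0.25)
    else:  # r/(n+1)
        q = r / (n + 1.0)
    return stats.norm.ppf(q)


def inverse_quantile_normalize(m: ExpressionMatrix, offset: str = "uniform") -> ExpressionMatrix:
    """Rank-based inverse normal transform, applied per feature row.

    Each value becomes ``Phi^{-1}(r/(n+1))`` with ``r`` its average rank
    within the row (``offset="blom"`` selects the Blom variant
    ``(r-3/8)/(n+1/4)``).  Constant rows map to all zeros and are logged.

    Requires a complete matrix (run the filters first).
    """
    if m.values.isna().any().any():
        raise ValueError("matrix contains missing values; filter before normalizing")
    if offset not in {"uniform", "blom"}:
        raise ValueError("offset must be 'uniform' or 'blom'")
    vals = m.values.to_numpy(dtype=np.float64)
    out = np.empty_like(vals)
    n_constant = 0
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.all(row == row[0]):
            out[i] = 0.0
            n_constant += 1
        else:
            out[i] = _int_ranks_to_normal(row, offset)
    if n_constant:
        logger.warning("inverse_quantile_normalize: %d constant rows mapped to zeros", n_constant)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        dict(m.stage),
    )


def preprocess_stage(
    m: ExpressionMatrix,
    stage: str,
    max_missing_frac: float = 0.10,
    offset: str = "uniform",
    per_stage_normalization: bool = True,
) -> ExpressionMatrix:
    """Full preprocessing for one stage's cohort.

    Order: feature filter -> sample filter -> restrict to the stage ->
    normalization (within the stage's samples by default; set
    ``per_stage_normalization=False`` to normalize over the full cohort
    before subsetting).
    """
    m = filter_features(m, max_missing_frac)
    m = filter_samples(m)
    if not per_stage_normalization:
        m = inverse_quantile_normalize(m, offset)
    cohort = m.samples_of_stage(stage)
    if not cohort:
        raise EmptyCohortError(f"no samples with stage {stage!r} survive filtering")
    m = m.subset_samples(cohort)
    if per_stage_normalization:
        m = inverse_quantile_normalize(m, offset)
    return m
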
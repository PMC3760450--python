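"""Presence filtering, replicate QC and quantile normalization.

The presence rule follows detection-call practice on expression arrays: a
probe is analyzable only if it was called Present in *all* replicates of at
least one condition (concentration x regime x harvest).  Marginal calls are
treated as not-Present.  Replicate QC flags samples whose log2 expression is
poorly correlated (pairwise R^2 below a threshold, default 0.93) with every
other replicate of the same condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import condition_groups, indexed_metadata, validate_matrix


def presence_filter(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Retain probes called Present in all replicates of >= 1 condition.

    Probe order is preserved.  Raises ``ValueError`` if the call matrix axes
    differ from the expression matrix or if any sample lacks metadata.
    """
    validate_matrix(matrix)
    if not calls.index.equals(matrix.index) or not calls.columns.equals(matrix.columns):
        raise ValueError("presence-call axes do not match the expression matrix")
    meta = indexed_metadata(metadata, matrix)

    keep = np.zeros(len(matrix), dtype=bool)
    for _, samples in condition_groups(meta).items():
        keep |= calls[samples].all(axis=1).to_numpy()
    return matrix.loc[keep]


def replicate_qc(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    r2_min: float = 0.93,
) -> list[str]:
    """Identify replicate samples that fail pairwise-correlation QC.

    A sample fails when its squared Pearson correlation with *every* other
    same-condition replicate is below ``r2_min``.  Conditions with a single
    sample are skipped with a warning.  The matrix is never mutated.
    """
    validate_matrix(matrix)
    meta = indexed_metadata(metadata, matrix)
    failing: list[str] = []
    for cond, samples in condition_groups(meta).items():
        if len(samples) < 2:
            warnings.warn(
                f"condition {cond} has a single sample; QC skipped", stacklevel=2
            )
            continue
        sub = matrix[samples].to_numpy(dtype=float)
        r2 = np.corrcoef(sub, rowvar=False) ** 2
        np.fill_diagonal(r2, np.nan)
        best = np.nanmax(r2, axis=0)
        failing.extend(s for s, b in zip(samples, best) if b < r2_min)
    return failing


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common (row-mean of sorted columns) scale.

    After normalization each column holds the identical sorted value multiset;
    ties receive the mean of the tied target values.  Idempotent.  Requires at
    least two samples.
    """
    validate_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    target = np.sort(x, axis=0).mean(axis=1)
    ranks = matrix.rank(method="average").to_numpy()  # 1..n, ties averaged
    positions = np.arange(1, x.shape[0] + 1, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
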
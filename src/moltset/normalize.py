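"""Intensity normalization and probe summarization.

Implements the two distribution-level steps of RMA-style preprocessing:
quantile normalization (every array is forced onto the common distribution
given by the row-wise mean of the sorted columns) and Tukey median-polish
summarization of multi-probe features into one log2 expression measure per
feature per array. Background correction is deliberately out of scope: the
statistics downstream operate on expression measures, not raw optics.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "log_transform",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
]

logger = logging.getLogger(__name__)

#: median polish iteration cap and convergence tolerance on total |change|
MEDIAN_POLISH_MAX_ITER = 10
MEDIAN_POLISH_TOL = 1e-6


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a linear-scale matrix to log2 scale.

    Raises
    ------
    ValueError
        If the matrix is already log2, or any value is non-positive
        (the offending feature/sample is named).
    """
    if matrix.scale != "linear":
        raise ValueError("log_transform expects a linear-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"cannot log-transform non-positive value at feature "
            f"{matrix.values.index[r]!r}, sample {matrix.values.columns[c]!r}"
        )
    out = pd.DataFrame(np.log2(vals), index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(out, scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common (mean-of-sorted) distribution.

    After normalization all columns share an identical sorted value vector:
    the element-wise mean of the sorted input columns. Ties within a column
    receive the mean of the normalized values at their tied ranks, so the
    operation is invariant to the order in which tied entries are listed.
    """
    df = matrix.values
    if df.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    vals = df.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    # reference distribution: mean across samples of each sorted column
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samp):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n_feat)
        ranked[order] = ref
        # average reference values over tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n_feat:
            sums = np.bincount(inv, weights=ranked)
            counts = np.bincount(inv)
            ranked = (sums / counts)[inv]
        out[:, j] = ranked
    return matrix.with_values(pd.DataFrame(out, index=df.index, columns=df.columns))


def median_polish(block: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D block.

    Returns ``(overall, row_effects, col_effects, residuals)`` with the
    fitted decomposition ``block = overall + row + col + residual``. Iterates
    row/column median sweeps until the total absolute adjustment falls below
    tolerance or the iteration cap is hit. At convergence residuals have
    (near-)zero median in every row and column.
    """
    resid = np.asarray(block, dtype=float).copy()
    n_rows, n_cols = resid.shape
    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    for _ in range(MEDIAN_POLISH_MAX_ITER):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        cmed_of_rows = np.median(row_eff)
        row_eff -= cmed_of_rows
        overall += cmed_of_rows

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        rmed_of_cols = np.median(col_eff)
        col_eff -= rmed_of_cols
        overall += rmed_of_cols

        delta = np.abs(rmed).sum() + np.abs(cmed).sum()
        if delta < MEDIAN_POLISH_TOL:
            break
    return overall, row_eff, col_eff, resid


def median_polish_summarize(
    matrix: ExpressionMatrix, annotation: Mapping[str, str]
) -> ExpressionMatrix:
    """Summarize probe rows into one expression measure per feature per array.

    Per feature, the probe x sample block is median-polished and the
    summarized value for a sample is ``overall + column effect`` (probe
    affinities are absorbed by the row effects). Single-probe features pass
    through unchanged. Probes absent from ``annotation`` are dropped with a
    logged count, mirroring the filtering of unmapped probe sets.

    Parameters
    ----------
    matrix
        Log2-scale probe-level matrix.
    annotation
        Probe id -> feature id map.
    """
    if matrix.scale != "log2":
        raise ValueError("median_polish_summarize expects a log2-scale matrix")
    df = matrix.values
    unmapped = [p for p in df.index if p not in annotation]
    if unmapped:
        logger.warning(
            "dropping %d probe(s) with no feature mapping (e.g. %s)",
            len(unmapped),
            unmapped[:3],
        )
        df = df.drop(index=unmapped)
    if df.empty:
        raise ValueError("no mapped probes left to summarize")

    feature_of = pd.Series({p: annotation[p] for p in df.index})
    rows: dict[str, np.ndarray] = {}
    # preserve first-appearance order of features
    for feat in feature_of.drop_duplicates().tolist():
        probes = feature_of.index[feature_of == feat]
        block = df.loc[probes].to_numpy(dtype=float)
        if block.shape[0] == 1:
            rows[feat] = block[0]
        else:
            overall, _row_eff, col_eff, _resid = median_polish(block)
            rows[feat] = overall + col_eff
    out = pd.DataFrame.from_dict(rows, orient="index", columns=df.columns)
    return matrix.with_values(out)
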
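"""Pearson correlation structure within and across the two feature banks.

The maps answer one question: how much of the deep bank is linearly
redundant with the engineered bank?  Pairwise Pearson r is computed on
the training cohort only, |r| is averaged within each bank (diagonal
excluded) and across banks, and the cross-bank map can be aggregated per
(filter, feature-class) catalog cell.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalog import CLASSES, FILTERS, FeatureCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationSummary",
    "pairwise_pearson",
    "summarize_bank_correlation",
    "aggregate_by_group",
    "abs_correlation_histogram",
]

from dataclasses import dataclass


@dataclass(frozen=True)
class CorrelationSummary:
    mean_abs_r: float
    sd_abs_r: float
    n_pairs: int
    scope: str  # within_R | within_T | cross


def pairwise_pearson(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every column of A and every column of B.

    Rows must be the same samples in the same order.  Zero-variance
    columns produce NaN entries; they are flagged here and excluded from
    downstream summaries.
    """
    if len(table_a) != len(table_b):
        raise ValueError("tables must have the same number of samples")
    if isinstance(table_a, pd.DataFrame) and isinstance(table_b, pd.DataFrame):
        if not table_a.index.equals(table_b.index):
            raise ValueError("tables must be indexed by the same samples in the same order")
    if len(table_a) < 3:
        raise ValueError("need at least 3 samples")
    a = table_a.to_numpy(dtype=float)
    b = table_b.to_numpy(dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a ** 2).sum(axis=0))
    sb = np.sqrt((b ** 2).sum(axis=0))
    bad_a, bad_b = sa == 0, sb == 0
    if bad_a.any() or bad_b.any():
        logger.warning("zero-variance columns: %d in A, %d in B (correlations undefined)",
                       int(bad_a.sum()), int(bad_b.sum()))
    sa[bad_a] = np.nan
    sb[bad_b] = np.nan
    r = (a.T @ b) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))
    return pd.DataFrame(r, index=table_a.columns, columns=table_b.columns)


def summarize_bank_correlation(matrix: pd.DataFrame, scope: str) -> CorrelationSummary:
    """Mean and sd of |r| over defined entries.

    For within-bank scopes the matrix is square (bank vs itself) and the
    diagonal plus the redundant lower triangle are excluded; for the
    cross scope every entry counts once.
    """
    if scope not in ("within_R", "within_T", "cross"):
        raise ValueError(f"unknown scope {scope!r}")
    r = matrix.to_numpy(dtype=float)
    if scope.startswith("within"):
        if r.shape[0] != r.shape[1]:
            raise ValueError("within-bank scope requires a square matrix")
        iu = np.triu_indices(r.shape[0], k=1)
        vals = r[iu]
    else:
        vals = r.ravel()
    vals = np.abs(vals[np.isfinite(vals)])
    if vals.size == 0:
        raise ValueError("no defined correlation entries to summarize")
    return CorrelationSummary(mean_abs_r=float(vals.mean()),
                              sd_abs_r=float(vals.std()),
                              n_pairs=int(vals.size), scope=scope)


def aggregate_by_group(matrix: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Per-(filter, class) mean |r| of bank-R features against all of bank T.

    Rows of ``matrix`` must be catalog-named bank-R features (columns are
    bank-T features).  Cells the catalog leaves empty come back as NaN,
    matching the blank cells of a filter-by-class table.
    """
    names = list(matrix.index)
    known = set(catalog.feature_names())
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"rows not named by the catalog: {unknown[:5]}")
    out = pd.DataFrame(np.nan, index=list(FILTERS), columns=list(CLASSES))
    absr = matrix.abs()
    for f in FILTERS:
        for c in CLASSES:
            cell = [n for n in catalog.cell_feature_names(f, c) if n in absr.index]
            if cell:
                vals = absr.loc[cell].to_numpy()
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    out.loc[f, c] = float(vals.mean())
    return out


def abs_correlation_histogram(matrix: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Histogram counts of |r| on [0, 1]; counts sum to the defined pairs."""
    vals = matrix.to_numpy(dtype=float).ravel()
    vals = np.abs(vals[np.isfinite(vals)])
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
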
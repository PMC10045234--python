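"""Cohort-level statistics: normality gate and Spearman correlation matrices.

The cohort analysis is deliberately nonparametric: %ATSF distributions across
subjects are strongly right-skewed (many near-zero freezers), so association is
measured with Spearman's rank correlation (Pearson correlation of average-ranked
values, ties receiving their mean rank). Shapiro-Wilk tests are provided to
record the normality check that justifies the choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedMetricError, UsageError


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with average-rank tie handling.

    Missing pairs (NaN in either argument) are dropped (pairwise-complete);
    at least 3 complete pairs are required. Raises
    :class:`UndefinedMetricError` when either variable has zero rank variance.
    """
    x, y = _pairwise_complete(x, y)
    if x.size < 3:
        raise UsageError(f"Spearman correlation needs at least 3 complete pairs, got {x.size}")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("Spearman correlation is undefined with zero rank variance")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value from the t approximation."""
    rho = spearman_rho(x, y)
    x, y = _pairwise_complete(x, y)
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def shapiro_wilk_p(x) -> float:
    """Shapiro-Wilk p-value (Royston approximation) for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise UsageError("Shapiro-Wilk requires between 3 and 5000 observations")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("Shapiro-Wilk is degenerate on a constant sample")
    return float(sps.shapiro(x).pvalue)


def correlation_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise Spearman rho with unit diagonal.

    Pairs whose correlation is undefined (zero rank variance, too few complete
    pairs) propagate as missing cells (NaN).
    """
    if columns is None:
        columns = list(table.columns)
    mat = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            try:
                rho = spearman_rho(table[a], table[b])
            except (UndefinedMetricError, UsageError):
                rho = np.nan
            mat.loc[a, b] = mat.loc[b, a] = rho
    return mat
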
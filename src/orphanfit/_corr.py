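"""Spearman correlation helpers shared by the assignment and co-fitness code.

Pairwise-complete handling: for each pair of vectors only the conditions
finite in both are used; pairs with fewer than ``min_overlap`` shared
conditions get NaN. Ranks use average-rank tie handling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MIN_OVERLAP_DEFAULT = 3


def spearman_pair(x: np.ndarray, y: np.ndarray, min_overlap: int = MIN_OVERLAP_DEFAULT) -> float:
    """Spearman rho of two vectors over their shared finite entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < min_overlap:
        return float("nan")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


def spearman_matrix(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = MIN_OVERLAP_DEFAULT
) -> pd.DataFrame:
    """Spearman correlations between every row of ``a`` and every row of ``b``.

    ``a`` and ``b`` must share the same column (condition) order. When both
    frames are complete (no NaN) the whole matrix is computed in one shot by
    rank-transforming rows and taking Pearson products; otherwise each pair
    falls back to pairwise-complete computation.
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("matrices must share an identical condition order")
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    if np.isfinite(av).all() and np.isfinite(bv).all():
        ra = _standardized_ranks(av)
        rb = _standardized_ranks(bv)
        corr = ra @ rb.T / ra.shape[1]
        return pd.DataFrame(corr, index=a.index, columns=b.index)
    out = np.full((av.shape[0], bv.shape[0]), np.nan)
    for i in range(av.shape[0]):
        for j in range(bv.shape[0]):
            out[i, j] = spearman_pair(av[i], bv[j], min_overlap=min_overlap)
    return pd.DataFrame(out, index=a.index, columns=b.index)


def _standardized_ranks(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit population std.

    Rows with zero rank spread (constant vectors) become all-zero, making
    their correlation with anything 0 rather than undefined.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    std = ranks.std(axis=1, ddof=0, keepdims=True)
    std[std == 0] = np.inf
    return ranks / std
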
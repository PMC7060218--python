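"""Pairwise compound-response similarity across the human isolate panel.

Each isolate is summarized by its vector of per-compound AUC values; every
unordered pair of isolates is compared with the paired-samples Wilcoxon
signed-rank test, and the resulting p-value matrix is categorized at 0.05
("similar" above, "different" below) and rendered as a two-color heat map.

The signed-rank test here uses the exact null distribution (all 2^n sign
assignments, computed by convolution over midranks) up to n = 25 paired
differences, and the normal approximation with continuity and tie
correction beyond.  Zero differences are dropped by default (Wilcoxon
convention); the Pratt variant (rank with zeros, then drop) is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "wilcoxon_signed_rank",
    "similarity_matrix",
    "plot_similarity_matrix",
    "EXACT_N_MAX",
]

logger = logging.getLogger(__name__)

#: exact null distribution used up to this many nonzero differences
EXACT_N_MAX = 25


def _exact_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic with midranks.

    The null distribution of W+ over the 2^n equiprobable sign vectors is
    built by convolving the polynomials (1 + z^{2 r_i}) on the doubled-rank
    lattice (midranks are multiples of 1/2, so doubling makes them
    integers).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = dist[:w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = ranks.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts ** 3 - counts) / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(x, y, zero_method: str = "wilcox",
                         method: str = "auto") -> float:
    """Two-sided paired-samples Wilcoxon signed-rank p-value.

    Pairs with a missing value are dropped; at least 5 complete pairs are
    required.  ``zero_method='wilcox'`` drops zero differences before
    ranking; ``'pratt'`` ranks them first and drops them after.  Ties in
    |difference| get midranks.  ``method`` is ``'exact'``, ``'approx'`` or
    ``'auto'`` (exact up to 25 nonzero differences).  All differences zero
    gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    if d.size < 5:
        raise ValueError("need at least 5 complete pairs")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if np.all(d == 0):
        return 1.0
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = rankdata(np.abs(d))
    else:
        ranks_all = rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if d.size <= EXACT_N_MAX else "approx"
    if method == "exact":
        return _exact_pvalue(ranks, w_plus)
    if method == "approx":
        return _approx_pvalue(ranks, w_plus)
    raise ValueError(f"unknown method {method!r}")


def similarity_matrix(auc: pd.DataFrame, alpha: float = 0.05,
                      zero_method: str = "wilcox",
                      min_common: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pairwise Wilcoxon comparison matrix of a panel.

    ``auc`` is a compounds x isolates table of AUC values (one column per
    isolate, NaN for missing compounds).  Returns ``(pvalues, category)``:
    a symmetric p-value DataFrame with unit diagonal, and the categorical
    map with ``"similar"`` where p > alpha would hold with p >= alpha
    (a p exactly at the threshold counts as similar) and ``"different"``
    below.  Isolates sharing fewer than ``min_common`` compounds with a
    partner get NaN for that pair (logged).
    """
    isolates = list(auc.columns)
    k = len(isolates)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = auc.iloc[:, i].to_numpy(float)
            yj = auc.iloc[:, j].to_numpy(float)
            common = np.isfinite(xi) & np.isfinite(yj)
            if common.sum() < min_common:
                logger.warning("pair %s/%s: only %d common compounds, excluded",
                               isolates[i], isolates[j], int(common.sum()))
                p[i, j] = p[j, i] = np.nan
                continue
            p[i, j] = p[j, i] = wilcoxon_signed_rank(
                xi[common], yj[common], zero_method=zero_method)
    pvals = pd.DataFrame(p, index=isolates, columns=isolates)
    cat = pvals.map(lambda v: np.nan if np.isnan(v)
                    else ("different" if v < alpha else "similar"))
    return pvals, cat


def plot_similarity_matrix(category: pd.DataFrame, ax=None, title: str = ""):
    """Two-color (similar = yellow / different = pink) heat map."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    code = category.map(
        lambda v: {"similar": 0.0, "different": 1.0}.get(v, np.nan)
    ).to_numpy(float)
    cmap = ListedColormap(["#f5e642", "#f58ab4"])
    ax.imshow(code, cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(len(category.columns)),
                  labels=category.columns, rotation=90)
    ax.set_yticks(range(len(category.index)), labels=category.index)
    if title:
        ax.set_title(title)
    return ax
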
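"""Feature screening: two-sample KS tests with BH-FDR control.

Each AUC feature is compared between groups with the nonparametric two-sample
Kolmogorov-Smirnov test; the resulting P values are corrected with the
Benjamini-Hochberg step-up procedure at q = 0.05 across all features of a
parcellation (a single family; per-metric families are available by screening
metric blocks separately).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import AUCFeatureTable

__all__ = ["ks_two_sample", "bh_fdr", "screen_features", "select_features"]


def ks_two_sample(x, y, method: str = "asymp") -> tuple[float, float]:
    """Two-sample KS statistic and P value.

    D = sup |ECDF_x - ECDF_y|.  ``method='asymp'`` (default) uses the
    asymptotic two-sample Kolmogorov distribution; ``'exact'`` the exact
    small-sample distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection mask and adjusted P values.

    With sorted p_(1) <= ... <= p_(m), rejects all i up to the largest i with
    p_(i) <= i*q/m; adjusted P is the cumulative minimum of m*p_(i)/i.
    """
    pvals = np.asarray(pvals, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("P values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def screen_features(
    table: AUCFeatureTable,
    q: float = 0.05,
    method: str = "asymp",
    family: str = "pooled",
) -> pd.DataFrame:
    """KS-screen every feature of a table; returns a per-feature report.

    Columns: feature, metric, node, D_KS, p, p_adj, selected, rank (raw-P
    ascending, ties by feature index).  ``family='pooled'`` corrects across
    all features at once; ``'per_metric'`` corrects each metric block
    separately.
    """
    if family not in ("pooled", "per_metric"):
        raise ValueError(f"unknown family {family!r}")
    patients = table.X[table.group == 1]
    controls = table.X[table.group == 0]
    stats_p = np.array(
        [
            ks_two_sample(patients[:, j], controls[:, j], method=method)
            for j in range(table.n_features)
        ]
    )
    d, p = stats_p[:, 0], stats_p[:, 1]
    out = table.meta[["feature", "metric", "node"]].copy()
    out["D_KS"] = d
    out["p"] = p
    if family == "pooled":
        selected, p_adj = bh_fdr(p, q)
    else:
        selected = np.zeros(p.size, dtype=bool)
        p_adj = np.empty(p.size)
        for m in out["metric"].unique():
            idx = (out["metric"] == m).to_numpy()
            selected[idx], p_adj[idx] = bh_fdr(p[idx], q)
    out["p_adj"] = p_adj
    out["selected"] = selected
    order = np.lexsort((np.arange(p.size), p))
    rank = np.empty(p.size, dtype=int)
    rank[order] = np.arange(p.size)
    out["rank"] = rank
    return out


def select_features(screen: pd.DataFrame, mode: str = "fdr", param: float = 0.05) -> np.ndarray:
    """Feature indices chosen by one of three screening policies.

    ``mode='fdr'``: all features with BH-adjusted significance at level
    ``param``; ``'top_k'``: the ``param`` smallest raw P values; or
    ``'p_threshold'``: raw P < ``param`` (used by the accuracy-vs-feature
    count sweep).  Ties always break by feature index; indices are returned
    in raw-P rank order.
    """
    p = screen["p"].to_numpy()
    order = np.lexsort((np.arange(p.size), p))
    if mode == "fdr":
        reject, _ = bh_fdr(p, q=param)
        return order[reject[order]]
    if mode == "top_k":
        k = int(param)
        if k > p.size:
            warnings.warn(f"top_k={k} exceeds feature count {p.size}; clipping")
            k = p.size
        return order[:k]
    if mode == "p_threshold":
        return order[p[order] < param]
    raise ValueError(f"unknown mode {mode!r}")
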
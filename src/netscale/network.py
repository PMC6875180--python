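"""Functional network construction: node series, nuisance regression,
correlation, and proportional sparsity thresholding.

The network pipeline mirrors standard resting-state practice: average the
voxel series within each node, regress out nuisance signals (motion- and
tissue-like regressors plus an intercept), correlate the residuals with
Pearson's r, then binarize the correlation matrix at a proportional sparsity
threshold S — keeping the E = round(S * n(n-1)/2) strongest edges.  Global
signal regression is deliberately not performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parcellation import ParcellationScheme

__all__ = [
    "BinaryNetwork",
    "extract_node_series",
    "nuisance_regress",
    "correlation_matrix",
    "threshold_by_sparsity",
    "sparsity_grid",
]


@dataclass
class BinaryNetwork:
    """Undirected binary graph at one sparsity threshold."""

    adjacency: np.ndarray
    sparsity: float
    edge_count: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def extract_node_series(subject_series: np.ndarray, parc: ParcellationScheme) -> np.ndarray:
    """Mean time course of every node.

    Parameters
    ----------
    subject_series
        4D array ``(nx, ny, nz, t)`` of voxel time series.
    parc
        Parcellation aligned with the series grid.

    Returns
    -------
    ndarray
        ``(n_nodes, t)`` matrix, rows in node-id order.
    """
    if subject_series.shape[:3] != parc.labels.shape:
        raise ValueError("series grid does not match parcellation grid")
    t = subject_series.shape[3]
    out = np.empty((parc.node_ids.size, t))
    for row, node in enumerate(parc.node_ids):
        mask = parc.labels == node
        if not mask.any():
            raise ValueError(f"node {node} has no voxels in the series grid")
        out[row] = subject_series[mask].mean(axis=0)
    return out


def nuisance_regress(node_series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Least-squares residual of every node series against the regressors.

    An intercept column is always included, so residuals are mean-centred and
    orthogonal to every regressor.  Raises if the design (with intercept) is
    rank deficient, naming the collinear columns.
    """
    node_series = np.asarray(node_series, dtype=float)
    t = node_series.shape[1]
    reg = np.asarray(regressors, dtype=float)
    if reg.ndim == 1:
        reg = reg[:, None]
    if reg.shape[0] != t:
        raise ValueError(f"regressors have {reg.shape[0]} rows, series have {t}")
    design = np.column_stack([np.ones(t), reg])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank on top of the preceding ones
        bad = []
        r_prev = 0
        for j in range(design.shape[1]):
            r_now = np.linalg.matrix_rank(design[:, : j + 1])
            if r_now == r_prev:
                bad.append(j - 1)  # regressor index (intercept is column -1)
            r_prev = r_now
        raise ValueError(f"rank-deficient nuisance design; collinear regressor columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, node_series.T, rcond=None)
    return node_series - (design @ beta).T


def correlation_matrix(node_series: np.ndarray) -> np.ndarray:
    """Pearson correlation between all node pairs of residual series."""
    node_series = np.asarray(node_series, dtype=float)
    if node_series.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = node_series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node series: {dead.tolist()}")
    r = np.corrcoef(node_series)
    return np.clip(r, -1.0, 1.0)


def threshold_by_sparsity(
    corr: np.ndarray,
    S: float,
    ranking: str = "signed",
) -> BinaryNetwork:
    """Binarize a correlation matrix at proportional sparsity ``S``.

    The E = round(S * n(n-1)/2) upper-triangle entries with the largest
    ranking value become edges.  ``ranking='signed'`` ranks by raw r (largest
    positive correlations first, the default); ``'absolute'`` ranks by |r|.
    Ties break lexicographically on (i, j) for determinism.
    """
    if not 0 < S <= 1:
        raise ValueError("S must lie in (0, 1]")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"unknown ranking {ranking!r}")
    n = corr.shape[0]
    max_e = n * (n - 1) // 2
    e = int(np.floor(S * max_e + 0.5))
    adj = np.zeros((n, n), dtype=np.int8)
    if e == 0:
        warnings.warn(f"S={S} keeps no edges on {n} nodes; returning empty graph")
        return BinaryNetwork(adjacency=adj, sparsity=float(S), edge_count=0)
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    # primary: value descending; ties: (i, j) ascending
    order = np.lexsort((ju, iu, -vals))
    keep = order[:e]
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return BinaryNetwork(adjacency=adj, sparsity=float(S), edge_count=e)


def sparsity_grid(start: float = 0.08, stop: float = 0.28, step: float = 0.05) -> np.ndarray:
    """Sparsity threshold grid; default {0.08, 0.13, 0.18, 0.23, 0.28}.

    The default traverses the threshold space (8%, 32%) in steps of 5%.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if stop < start:
        raise ValueError("stop must be >= start")
    n = int(np.floor((stop - start) / step + 0.5)) + 1
    grid = start + step * np.arange(n)
    grid = grid[grid <= stop + 1e-12]
    return np.round(grid, 10)
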
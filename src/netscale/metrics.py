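"""Nodal graph metrics and sparsity-AUC feature extraction.

Three local metrics — degree, betweenness centrality, and nodal efficiency —
are computed on every binary network of the sparsity grid, and each node's
metric-vs-sparsity curve is collapsed into a single trapezoidal AUC feature.
A cohort therefore yields a subjects x (3 * n_nodes) feature matrix.

Betweenness is normalized by (n-1)(n-2)/2 by default so values are
comparable across parcellation scales; unnormalized values are available.
Disconnected pairs contribute zero to nodal efficiency and are skipped in
betweenness, which matters for fragmented low-sparsity graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .network import (
    BinaryNetwork,
    correlation_matrix,
    extract_node_series,
    nuisance_regress,
    sparsity_grid,
    threshold_by_sparsity,
)
from .parcellation import ParcellationScheme

__all__ = [
    "AUCFeatureTable",
    "degree",
    "betweenness",
    "nodal_efficiency",
    "metric_curves",
    "auc",
    "build_feature_table",
]

METRIC_NAMES = ("degree", "betweenness", "nodal_efficiency")


def degree(net: BinaryNetwork) -> np.ndarray:
    """Number of edges incident to each node (adjacency row sums)."""
    return net.adjacency.sum(axis=1).astype(float)


def betweenness(net: BinaryNetwork, normalized: bool = True) -> np.ndarray:
    """Betweenness centrality of each node.

    Fraction of all-pairs shortest paths passing through the node, optionally
    normalized by (n-1)(n-2)/2.  Pairs in different components contribute 0.
    """
    g = nx.from_numpy_array(net.adjacency)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return np.array([bc[i] for i in range(net.n_nodes)])


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Mean inverse shortest-path length from each node to all others.

    E_nod(i) = (1/(n-1)) * sum_{j != i} 1/d(i, j), with 1/inf = 0 for
    unreachable pairs; 1 on a complete graph, 0 for an isolated node.
    """
    n = net.n_nodes
    if n < 2:
        return np.zeros(n)
    d = shortest_path(net.adjacency, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def metric_curves(
    corr: np.ndarray,
    grid: np.ndarray,
    ranking: str = "signed",
    normalized_betweenness: bool = True,
) -> dict[str, np.ndarray]:
    """Evaluate all three nodal metrics at every sparsity in ``grid``.

    Returns ``{metric: (len(grid), n_nodes) array}``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sparsity grid is empty")
    n = corr.shape[0]
    out = {m: np.empty((grid.size, n)) for m in METRIC_NAMES}
    for gi, s in enumerate(grid):
        net = threshold_by_sparsity(corr, float(s), ranking=ranking)
        out["degree"][gi] = degree(net)
        out["betweenness"][gi] = betweenness(net, normalized=normalized_betweenness)
        out["nodal_efficiency"][gi] = nodal_efficiency(net)
    return out


def auc(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Trapezoidal area under a metric-vs-sparsity curve.

    ``values`` may be a single curve (length = grid length) or a
    ``(len(grid), n_nodes)`` stack; integrates over the raw S grid without
    range renormalization.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    values = np.asarray(values, dtype=float)
    return np.trapezoid(values, grid, axis=0)


@dataclass
class AUCFeatureTable:
    """Subjects x features matrix of sparsity-AUC nodal metrics.

    ``features`` columns are ordered metric-major (all degree features, then
    betweenness, then nodal efficiency), each block in node-id order.
    ``meta`` carries one row per feature: metric, node, parent region, and
    node centroid in mm.
    """

    X: np.ndarray
    group: np.ndarray
    meta: pd.DataFrame

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def to_tsv(self, features_path: str, meta_path: str) -> None:
        df = pd.DataFrame(self.X, columns=self.meta["feature"].tolist())
        df.insert(0, "group", self.group)
        df.to_csv(features_path, sep="\t", index=False)
        self.meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, features_path: str, meta_path: str) -> "AUCFeatureTable":
        df = pd.read_csv(features_path, sep="\t")
        meta = pd.read_csv(meta_path, sep="\t")
        group = df.pop("group").to_numpy()
        return cls(X=df.to_numpy(), group=group, meta=meta)


def build_feature_table(
    cohort,
    parc: ParcellationScheme,
    grid: np.ndarray | None = None,
    ranking: str = "signed",
    normalized_betweenness: bool = True,
) -> AUCFeatureTable:
    """Run the per-subject network pipeline and collect AUC features.

    For each subject: node-mean series extraction, nuisance regression,
    Pearson correlation, thresholding across the sparsity grid, the three
    nodal metrics, and trapezoidal AUC.  Feature count = 3 * achieved node
    count.
    """
    if grid is None:
        grid = sparsity_grid()
    rows = []
    for s in range(cohort.n_subjects):
        ts = extract_node_series(cohort.series[s], parc)
        res = nuisance_regress(ts, cohort.nuisance[s])
        corr = correlation_matrix(res)
        curves = metric_curves(
            corr, grid, ranking=ranking, normalized_betweenness=normalized_betweenness
        )
        feats = np.concatenate([auc(curves[m], grid) for m in METRIC_NAMES])
        rows.append(feats)
    X = np.vstack(rows)

    node_ids = parc.node_ids
    cents = parc.centroid_array()
    meta = pd.DataFrame(
        {
            "feature": [
                f"{m}:{int(n)}" for m in METRIC_NAMES for n in node_ids
            ],
            "metric": np.repeat(METRIC_NAMES, node_ids.size),
            "node": np.tile(node_ids, len(METRIC_NAMES)),
            "parent": np.tile(
                [parc.parent_of[int(n)] for n in node_ids], len(METRIC_NAMES)
            ),
            "cx": np.tile(cents[:, 0], len(METRIC_NAMES)),
            "cy": np.tile(cents[:, 1], len(METRIC_NAMES)),
            "cz": np.tile(cents[:, 2], len(METRIC_NAMES)),
        }
    )
    return AUCFeatureTable(X=X, group=np.asarray(cohort.group), meta=meta)
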
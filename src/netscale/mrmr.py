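"""Minimum-redundancy-maximum-relevance (mRMR) feature evaluation.

Features are discretized into three states (below mean - alpha*SD, within,
above mean + alpha*SD) and scored with plug-in mutual information in bits.
For a feature set S and group label h:

    D   = (1/|S|)   * sum_{i in S}    I(h, i)        (relevance)
    R   = (1/|S|^2) * sum_{i,j in S}  I(i, j)        (redundancy, incl. i=j)
    MID = D - R                                       (information gap)

Per-feature "effectiveness" is the incremental mRMR score: the first selected
feature scores its relevance I(h, i); each later candidate scores
I(h, i) - mean_{j selected} I(i, j), and every feature keeps the score from
its selection step.  The set-level formulas above are also exposed directly.

The module also provides the pairwise redundancy matrix of a feature subset
and the OLS regression of redundancy on inter-node centroid distance used to
show that spatially close nodes carry redundant features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiscretizedFeatures",
    "discretize",
    "mutual_information",
    "mi_matrix",
    "table_scores",
    "per_feature_mid",
    "subset_mid_curve",
    "redundancy_matrix",
    "redundancy_distance_regression",
]


@dataclass
class DiscretizedFeatures:
    """Integer state matrix (subjects x features) plus binning parameters."""

    states: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    alpha: float


def discretize(X: np.ndarray, alpha: float = 1.0) -> DiscretizedFeatures:
    """Three-state discretization at mean +/- alpha*SD per feature.

    State -1 below mean - alpha*SD, +1 above mean + alpha*SD, 0 between.
    Location-scale invariant per feature.  Constant features map to all-zero
    states with a warning.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) mapped to state 0"
        )
    safe_sd = np.where(const, 1.0, sd)
    states = np.zeros(X.shape, dtype=np.int8)
    states[X < mean - alpha * safe_sd] = -1
    states[X > mean + alpha * safe_sd] = 1
    states[:, const] = 0
    return DiscretizedFeatures(states=states, mean=mean, sd=sd, alpha=float(alpha))


def mutual_information(a, b, base: float = 2.0) -> float:
    """Plug-in mutual information of two discrete sequences.

    I = sum p(a,b) * log[p(a,b) / (p(a) p(b))] over observed states, with
    0*log(0) = 0; bits by default (``base=2``), nats with ``base=e``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    ratio = joint[nz] / (pa @ pb)[nz]
    return float(np.sum(joint[nz] * np.log(ratio)) / np.log(base))


def mi_matrix(states: np.ndarray, base: float = 2.0) -> np.ndarray:
    """Symmetric pairwise MI among feature columns; diagonal = entropies."""
    f = states.shape[1]
    out = np.zeros((f, f))
    for i in range(f):
        for j in range(i, f):
            out[i, j] = out[j, i] = mutual_information(
                states[:, i], states[:, j], base=base
            )
    return out


def table_scores(
    disc: DiscretizedFeatures, labels: np.ndarray, subset, base: float = 2.0
) -> tuple[float, float, float]:
    """Set-level relevance D, redundancy R and MID = D - R for a subset.

    The redundancy double sum runs over all ordered pairs of the subset
    including i = j (self-information terms), as the set-level definition
    states; use :func:`redundancy_matrix` for the self-pair-free pairwise
    report.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    s = disc.states[:, subset]
    rel = np.array(
        [mutual_information(labels, s[:, i], base=base) for i in range(subset.size)]
    )
    mi = mi_matrix(s, base=base)
    D = float(rel.mean())
    R = float(mi.sum() / subset.size**2)
    return D, R, D - R


def per_feature_mid(
    disc: DiscretizedFeatures,
    labels: np.ndarray,
    base: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Incremental mRMR effectiveness score of every feature.

    Greedy selection over all features: the first pick maximizes relevance
    I(h, i); each subsequent pick maximizes
    I(h, i) - mean_{j in selected} I(i, j).  Every feature receives the score
    it had at its own selection step.  Ties break by feature index.

    Returns
    -------
    scores, order
        Per-feature score (bits, feature order) and the selection order.
    """
    states = disc.states
    f = states.shape[1]
    if f == 0:
        raise ValueError("no features")
    rel = np.array(
        [mutual_information(labels, states[:, i], base=base) for i in range(f)]
    )
    mi = mi_matrix(states, base=base)
    scores = np.empty(f)
    order = np.empty(f, dtype=int)
    selected = np.zeros(f, dtype=bool)
    red_sum = np.zeros(f)
    for step in range(f):
        if step == 0:
            cand = rel.copy()
        else:
            cand = rel - red_sum / step
        cand[selected] = -np.inf
        pick = int(np.argmax(cand))  # first max == lowest feature index on ties
        scores[pick] = cand[pick]
        order[step] = pick
        selected[pick] = True
        red_sum += mi[:, pick]
    return scores, order


def subset_mid_curve(
    scores: np.ndarray,
    p_ranking: np.ndarray,
    step: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-feature MID over growing prefixes of the P ranking.

    ``p_ranking`` lists feature indices by ascending screening P; prefixes
    grow in blocks of ``step`` (clipped to the feature count).  Returns
    (prefix sizes, mean score within each prefix).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    p_ranking = np.asarray(p_ranking, dtype=int)
    f = p_ranking.size
    sizes = list(range(step, f + 1, step))
    if not sizes or sizes[-1] != f:
        sizes.append(f)
    means = np.array([scores[p_ranking[:m]].mean() for m in sizes])
    return np.array(sizes), means


def redundancy_matrix(
    disc: DiscretizedFeatures, subset, base: float = 2.0
) -> np.ndarray:
    """Pairwise MI among subset features with self-pairs zeroed.

    Symmetric; entry (i, j) is the redundancy between subset features i and
    j, the diagonal is excluded (set to 0) because self-information is not a
    between-feature redundancy.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size < 2:
        raise ValueError("redundancy needs at least 2 features")
    mi = mi_matrix(disc.states[:, subset], base=base)
    np.fill_diagonal(mi, 0.0)
    return mi


def redundancy_distance_regression(
    redundancy: np.ndarray,
    distance: np.ndarray,
) -> dict:
    """OLS of pairwise redundancy on pairwise distance.

    ``redundancy`` and ``distance`` are aligned 1D pair vectors (or matching
    symmetric matrices, in which case the strict upper triangles are used).
    Returns slope, intercept, adjusted R^2 = 1 - (1-R^2)(n-1)/(n-2), and the
    two-sided slope P value.
    """
    red = np.asarray(redundancy, dtype=float)
    dist = np.asarray(distance, dtype=float)
    if red.ndim == 2:
        iu = np.triu_indices(red.shape[0], k=1)
        red, dist = red[iu], dist[iu]
    if red.shape != dist.shape:
        raise ValueError("redundancy and distance pairs are not aligned")
    n = red.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    reg = stats.linregress(dist, red)
    r2 = reg.rvalue**2
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - 2)
    return {
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "adjusted_r2": float(adj_r2),
        "p_value": float(reg.pvalue),
        "n_pairs": n,
    }
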
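"""Volume-proportional random-seed region-growing parcellation.

A parent atlas with R regions is refined into approximately N nodes: each
parent region of volume fraction V receives k = round(V * N) subregions
(floored at 1), grown from k random seed voxels by iteratively merging the
globally nearest (unassigned voxel, seed) pair in physical mm space.  After a
merge the seed moves to the running mass centre of its subregion's voxel
centres.  Subregions never cross parent-region boundaries, so the refinement
is a strict subdivision of the parent scheme.

The achieved node count deviates slightly from N because of the per-region
rounding; the deviation is bounded by half a voxel count per parent region in
expectation and is reported in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .atlas import LabelAtlas

__all__ = [
    "ParcellationScheme",
    "volume_fractions",
    "subregion_count",
    "subdivide_region",
    "subdivide_atlas",
    "centroid_distances",
]


@dataclass
class ParcellationScheme:
    """Refined label grid with parent bookkeeping and mm centroids."""

    labels: np.ndarray
    parent_of: dict[int, int]
    target_N: int
    achieved_N: int
    centroids: dict[int, np.ndarray]
    seed: int
    spacing: tuple[float, float, float]
    node_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ids = np.unique(self.labels)
        self.node_ids = ids[ids > 0]
        if self.achieved_N != self.node_ids.size:
            raise ValueError("achieved_N inconsistent with label grid")

    def centroid_array(self) -> np.ndarray:
        """Centroids stacked in node-id order, shape (achieved_N, 3), mm."""
        return np.vstack([self.centroids[int(i)] for i in self.node_ids])


def volume_fractions(atlas: LabelAtlas) -> dict[int, float]:
    """Volume fraction V of each parent region (voxel count / foreground).

    Fractions are positive and sum to 1; V plays the role the total
    grey-matter volume proportion of each parent node plays on real data.
    """
    total = atlas.n_foreground
    if total == 0:
        raise ValueError("atlas has empty foreground")
    return {
        int(r): int(np.count_nonzero(atlas.labels == r)) / total
        for r in atlas.region_ids
    }


def subregion_count(V: float, N: int) -> int:
    """Number of subregions for a region of volume fraction V at scale N.

    k = V*N rounded half-up, floored at 1 so every parent region survives
    the subdivision.
    """
    if not 0 < V <= 1:
        raise ValueError("V must lie in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    return max(1, int(np.floor(V * N + 0.5)))


def subdivide_region(
    atlas: LabelAtlas,
    region_id: int,
    k: int,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Grow ``k`` subregions inside one parent region.

    Returns a per-voxel subregion index in ``0..k-1``, aligned with the
    region's voxels in linear-index order (``atlas.region_voxels`` order).

    Seeds are drawn uniformly without replacement.  Growth merges, at every
    step, the globally closest (unassigned voxel, seed) pair by Euclidean
    distance in mm; ties break on (voxel linear index, seed index).  The
    seed's position is then updated to the arithmetic mean of all voxel
    centres merged into that subregion so far.
    """
    coords = atlas.region_voxels(region_id)  # linear-index order
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds region voxel count {n}")
    if k == 1:
        return np.zeros(n, dtype=np.int32)

    mm = atlas.voxel_mm(coords)
    rng = np.random.default_rng(seed)
    seed_rows = np.sort(rng.choice(n, size=k, replace=False))

    assign = np.full(n, -1, dtype=np.int32)
    assign[seed_rows] = np.arange(k)
    sums = mm[seed_rows].copy()
    counts = np.ones(k)
    positions = sums / counts[:, None]

    remaining = np.flatnonzero(assign < 0)
    while remaining.size:
        d = cdist(mm[remaining], positions)
        # first minimum in row-major order == smallest (voxel index, seed index)
        flat = int(np.argmin(d))
        vi, si = divmod(flat, k)
        row = remaining[vi]
        assign[row] = si
        sums[si] += mm[row]
        counts[si] += 1
        positions[si] = sums[si] / counts[si]
        remaining = np.delete(remaining, vi)
    return assign


def subdivide_atlas(atlas: LabelAtlas, N: int, seed: int = 0) -> ParcellationScheme:
    """Refine a parent atlas into approximately ``N`` compact subregions.

    Every parent region is subdivided independently with its own RNG stream
    (namespaced by parent id, so results do not depend on iteration order).
    Subregions are relabelled 1..achieved_N by (parent id, creation order).
    """
    if N < atlas.n_regions:
        raise ValueError(
            f"N={N} is below the parent region count {atlas.n_regions}"
        )
    fractions = volume_fractions(atlas)
    labels = np.zeros_like(atlas.labels, dtype=np.int32)
    parent_of: dict[int, int] = {}
    centroids: dict[int, np.ndarray] = {}
    next_id = 1
    for r in sorted(fractions):
        k = subregion_count(fractions[r], N)
        coords = atlas.region_voxels(r)
        k = min(k, coords.shape[0])
        sseq = np.random.SeedSequence([int(seed), int(r)])
        assign = subdivide_region(atlas, r, k, sseq)
        mm = atlas.voxel_mm(coords)
        for sub in range(k):
            rows = assign == sub
            node = next_id + sub
            labels[tuple(coords[rows].T)] = node
            parent_of[node] = int(r)
            centroids[node] = mm[rows].mean(axis=0)
        next_id += k
    achieved = next_id - 1
    return ParcellationScheme(
        labels=labels,
        parent_of=parent_of,
        target_N=int(N),
        achieved_N=achieved,
        centroids=centroids,
        seed=int(seed),
        spacing=atlas.spacing,
    )


def identity_parcellation(atlas: LabelAtlas) -> ParcellationScheme:
    """Treat the parent atlas itself as the parcellation (one node per region)."""
    return subdivide_atlas(atlas, N=atlas.n_regions, seed=0)


def centroid_distances(parc: ParcellationScheme) -> np.ndarray:
    """Pairwise Euclidean centroid distances (mm), node-id order.

    Symmetric with zero diagonal; used by the redundancy-vs-distance
    analysis.
    """
    pts = parc.centroid_array()
    return cdist(pts, pts)
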
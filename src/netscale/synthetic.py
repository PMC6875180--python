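"""Synthetic resting-state cohorts with planted group differences.

The generator produces everything the downstream pipeline consumes without any
external data: a compact synthetic label atlas, and a two-group cohort of
voxel-level time series in which selected regions are more strongly coupled in
the patient group than in the control group.

Signal model
------------
Each parent region r carries a zero-mean, unit-variance AR(1) latent series
(coefficient ``ar_coef``, default 0.3, mimicking BOLD autocorrelation).  A
shared "hub" latent g(t) is mixed into the latents of the affected regions for
patient subjects only::

    x_r  <-  sqrt(1 - w^2) * x_r + w * g,     w = sqrt(effect_size)

so the pairwise correlation between any two affected regions is raised by
approximately ``effect_size`` in patients, which in turn shifts nodal degree
and efficiency of the corresponding nodes.  Voxel series are the parent latent
plus iid Gaussian noise plus a linear combination of nuisance regressors
(6 motion-like low-frequency components and 2 tissue-like slow signals), whose
values are recorded exactly so nuisance regression can remove them.

Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .atlas import LabelAtlas

__all__ = ["CohortSpec", "SyntheticCohort", "generate_atlas", "generate_cohort"]

N_MOTION_REGRESSORS = 6
N_TISSUE_REGRESSORS = 2


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Foreground mask: the ellipsoid inscribed in the grid.

    Gives parent regions unequal volumes (regions near the rim are clipped),
    which exercises the volume-proportional rounding downstream.
    """
    centre = (np.asarray(shape) - 1) / 2.0
    radii = np.maximum(np.asarray(shape) / 2.0, 0.5)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
    return d2 <= 1.0


def generate_atlas(
    shape: tuple[int, int, int],
    n_regions: int,
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
) -> LabelAtlas:
    """Partition an ellipsoidal foreground into spatially compact regions.

    Regions are the Voronoi cells (in mm) of ``n_regions`` seed voxels drawn
    uniformly without replacement from the foreground; every cell contains at
    least its own seed, so all regions are nonempty.  Deterministic given
    ``seed``.
    """
    mask = _ellipsoid_mask(tuple(shape))
    fg = np.argwhere(mask)
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > fg.shape[0]:
        raise ValueError(
            f"n_regions={n_regions} exceeds foreground voxel count {fg.shape[0]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    seed_rows = rng.choice(fg.shape[0], size=n_regions, replace=False)
    seed_mm = fg[seed_rows] * np.asarray(spacing)
    fg_mm = fg * np.asarray(spacing)
    # nearest seed in physical space; ties resolved to the lowest seed index
    d2 = ((fg_mm[:, None, :] - seed_mm[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[tuple(fg.T)] = nearest + 1
    return LabelAtlas(labels=labels, spacing=spacing)


@dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror a two-group resting-state study: 38 patients vs 28
    controls with 238 retained volumes.
    """

    n_patients: int = 38
    n_controls: int = 28
    n_timepoints: int = 238
    effect_regions: frozenset[int] = frozenset()
    effect_size: float = 0.0
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    nuisance_amp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size is a correlation shift in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")
        self.effect_regions = frozenset(int(r) for r in self.effect_regions)

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls


@dataclass
class SyntheticCohort:
    """Generated cohort: per-subject voxel series plus ground truth.

    ``series[s]`` has shape ``(nx, ny, nz, t)``; ``group`` is 1 for patients
    and 0 for controls; ``nuisance[s]`` is the exact ``t x 8`` regressor
    matrix added to subject ``s``; ``truth`` is the set of parent regions that
    carry the planted effect.
    """

    series: list[np.ndarray]
    group: np.ndarray
    nuisance: list[np.ndarray]
    truth: frozenset[int]
    spec: CohortSpec = field(repr=False, default=None)

    @property
    def n_subjects(self) -> int:
        return len(self.series)


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-variance stationary AR(1) series."""
    innov = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = innov[0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + c * innov[t]
    return x


def _nuisance_regressors(rng: np.random.Generator, t: int) -> np.ndarray:
    """6 motion-like low-frequency + 2 tissue-like slow regressors (t x 8)."""
    time = np.arange(t) / t
    cols = []
    for i in range(N_MOTION_REGRESSORS):
        freq = 0.5 + 0.5 * i
        phase = rng.uniform(0, 2 * np.pi)
        drift = rng.normal(scale=0.3) * (time - 0.5)
        cols.append(np.sin(2 * np.pi * freq * time + phase) + drift)
    for _ in range(N_TISSUE_REGRESSORS):
        cols.append(_ar1(rng, t, 0.8))
    reg = np.column_stack(cols)
    reg -= reg.mean(axis=0)
    sd = reg.std(axis=0, ddof=0)
    reg /= np.where(sd > 0, sd, 1.0)
    return reg


def generate_cohort(
    atlas: LabelAtlas,
    spec: CohortSpec,
    parc_truth=None,
) -> SyntheticCohort:
    """Simulate a two-group cohort of voxel time series on ``atlas``.

    Parameters
    ----------
    atlas
        Parent label volume; each region receives its own latent series.
    spec
        Cohort design; see :class:`CohortSpec`.
    parc_truth
        Optional finer parcellation; accepted so callers can carry subregion
        level ground truth alongside, but the effect is always planted at the
        parent-region level.

    Returns
    -------
    SyntheticCohort
        Patients first (group label 1), then controls (0).
    """
    bad = spec.effect_regions - set(int(r) for r in atlas.region_ids)
    if bad:
        raise ValueError(f"effect_regions not in atlas: {sorted(bad)}")
    if spec.effect_size > 0 and not spec.effect_regions:
        warnings.warn("effect_size > 0 with empty effect_regions plants no effect")

    t = spec.n_timepoints
    w = np.sqrt(spec.effect_size)
    region_ids = [int(r) for r in atlas.region_ids]
    region_voxels = {r: atlas.region_voxels(r) for r in region_ids}

    group = np.array([1] * spec.n_patients + [0] * spec.n_controls, dtype=int)
    root = np.random.SeedSequence([int(spec.seed), 0xC0F0])
    subject_seeds = root.spawn(spec.n_subjects)

    series: list[np.ndarray] = []
    nuisance: list[np.ndarray] = []
    for s, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        hub = _ar1(rng, t, spec.ar_coef)
        latents = {}
        for r in region_ids:
            x = _ar1(rng, t, spec.ar_coef)
            if group[s] == 1 and r in spec.effect_regions and w > 0:
                x = np.sqrt(1.0 - w * w) * x + w * hub
            latents[r] = x
        reg = _nuisance_regressors(rng, t)
        vol = np.zeros(atlas.labels.shape + (t,), dtype=np.float64)
        for r in region_ids:
            vox = region_voxels[r]
            nvox = vox.shape[0]
            loadings = spec.nuisance_amp * rng.normal(size=reg.shape[1])
            base = latents[r] + reg @ loadings
            noise = spec.noise_sd * rng.standard_normal((nvox, t))
            vol[tuple(vox.T)] = base[None, :] + noise
        series.append(vol)
        nuisance.append(reg)

    return SyntheticCohort(
        series=series,
        group=group,
        nuisance=nuisance,
        truth=spec.effect_regions,
        spec=spec,
    )
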
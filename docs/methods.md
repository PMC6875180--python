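# Methods

## The analysis in brief

The package studies how the scale of a brain-network parcellation (its node
count *N*) affects group classification from resting-state functional
connectivity. For each scale it builds per-subject binary networks, extracts
AUC-integrated nodal graph metrics, screens them for group differences,
classifies with a linear SVM under repeated cross-validation, and evaluates
the selected features' effectiveness and redundancy with mutual-information
(mRMR) scores. Because clinical rs-fMRI data cannot be bundled, a synthetic
generator produces cohorts with known planted effects; every claim the test
suite makes is therefore a claim about recovery of planted structure, not
about any clinical population.

## Synthetic data generator

**Atlas.** The foreground is the ellipsoid inscribed in the requested grid;
parent regions are Voronoi cells (in mm) of seed voxels drawn uniformly from
the foreground. The ellipsoid clips rim regions, giving unequal region
volumes, which exercises the volume-proportional rounding of the
parcellation stage.

**Signals.** Each parent region carries a zero-mean, unit-variance AR(1)
latent series. The AR coefficient defaults to 0.3, a mild autocorrelation
comparable to band-limited BOLD at TR ≈ 2 s; the generator produces
already-band-limited signals, so no bandpass filter is applied downstream.
Voxel series are the parent latent plus iid Gaussian noise (`noise_sd`,
default 1.0, i.e. voxel SNR ≈ 1) plus a nuisance component.

**Planted effect.** For patient subjects only, the latents of the
`effect_regions` are replaced by sqrt(1−w²)·x + w·g with a shared hub series
g and w = sqrt(`effect_size`), so the pairwise correlation between any two
affected regions rises by ≈ `effect_size`. This directly raises the nodal
degree and efficiency of affected nodes at fixed sparsity. The magnitude of
real clinical effects is unknown; `effect_size` is a free simulation
parameter. Empirically, region-level screening recovers all planted regions
(top-2·|truth| ranking) from `effect_size` ≈ 0.4 at 15/15 subjects and 200
timepoints, which is the recovery threshold the unit tests document.

**Nuisance.** Six motion-like regressors (low-frequency sinusoids with random
phase plus linear drift) and two tissue-like AR(1) regressors, standardized,
scaled by `nuisance_amp` (default 0.5) with per-region random loadings. The
exact regressor matrix is recorded per subject so nuisance regression can
remove it exactly.

**What the generator does not emulate:** hemodynamics, scanner noise
spectra, spatial smoothing, subject motion spikes, or inter-subject
anatomical variability. Passing tests show the pipeline recovers planted
covariance structure; they do not show clinical effect sizes are detectable.

## Parcellation

k = V·N per parent region, rounded half-up and floored at 1 so every parent
survives (the floor guarantees a surjective parent map). Growth merges the
globally smallest (unassigned voxel, seed) pair by Euclidean mm distance;
ties break on (voxel linear index, seed index) so results are deterministic.
After each merge the seed moves to the arithmetic mean of all voxel centres
merged so far — the natural generalization of "centre of voxel and seed"
beyond the first merge. Each parent region uses an RNG stream namespaced by
(seed, region id), so results are independent of region iteration order.
The achieved node count deviates from N only through per-region rounding;
across seeds the deviation stays within half the parent-region count.
Centroids are voxel-centre mass centres in mm.

## Networks

Edges are Pearson correlations of nuisance-regressed node-mean series. The
regression residuals are used directly (the operational reading of
"partial correlation after motion regression"); a true inverse-covariance
partial correlation is deliberately out of scope. Proportional thresholding
keeps the E = round(S·n(n−1)/2) largest entries, ranking by signed r by
default (largest positive correlations become edges, the common
proportional-threshold practice); |r| ranking is available via
`ranking="absolute"`. Exact ties rank lexicographically by (i, j). The
default grid {0.08, 0.13, 0.18, 0.23, 0.28} traverses the threshold space
(8%, 32%) in 5% steps; both endpoints and step are configurable since the
exact grid inside that interval is a convention.

## Metrics

Degree, betweenness centrality, and nodal efficiency on each binary graph.
Betweenness is normalized by (n−1)(n−2)/2 by default so values are
comparable across scales (unnormalized available). Unreachable pairs
contribute 0 to efficiency and are skipped in betweenness — necessary
because low-sparsity, high-N graphs fragment. Each node's metric-vs-S curve
is integrated with the trapezoid rule over the raw S grid (no range
renormalization), so AUC values from different grids are not directly
comparable and the grid is recorded with every feature table.

## Screening

Two-sample KS per feature. Asymptotic P values are the default (common
practice at n ≈ 30 per group); the exact small-sample distribution is
available with `method="exact"` and is what the calibration tests use,
because the asymptotic test is conservative at these sizes (realized level
≈ 0.03–0.04 instead of 0.05). BH-FDR at q = 0.05 is applied across all
features of a parcellation as a single family by default; per-metric
families are a flag, since which family the convention intends is ambiguous.

## Classification

Linear SVM (LIBSVM backend), tol 1e−3, default C = 1. Folds are stratified
to avoid single-class folds at n ≈ 66; non-stratified mode exists. When a
class is smaller than k, k is clipped to the smallest class size with a
warning. Standardization uses training-fold statistics only; an
anti-leakage canary test verifies shuffled-label accuracy stays at chance.
Screening is performed once on the full sample before CV, mirroring the
screen-then-cross-validate order of the classic pipeline; this induces an
optimistic bias (the selected features have seen all subjects), which is
why absolute accuracies here should be read comparatively across scales,
not as unbiased estimates. The nested 70/30 holdout protocol with the
C = 2^c, c ∈ {−5,…,5} grid provides the honest-evaluation counterpart: the
"[−5, 5] range with step 1" for a positive penalty parameter is read as
log2 exponents, the standard LIBSVM grid convention.

## mRMR evaluation

Discretization at mean ± α·SD with α = 1 (three states), the common mRMR
discretization; α is configurable. Mutual information is the plug-in
estimate in bits. The set-level redundancy R = (1/|S|²) ΣΣ I(i,j) includes
the i = j self-information terms, as the set-level definition is written;
the pairwise redundancy report excludes self-pairs. Per-feature
"effectiveness" is the incremental mRMR score (relevance minus mean MI with
already-selected features, recorded at the feature's selection step); the
static set formula is exposed separately (`table_scores`). Feature-pair
distance is the centroid distance of the two features' nodes; pairs of
features on the same node are excluded from the distance regression (zero
distance is degenerate). Adjusted R² = 1 − (1−R²)(n−1)/(n−2).

## Scale-sweep experiment

`run_scale_sweep` shares one cohort across all scales in memory (the
per-scale stages are cheap relative to cohort generation at desk scale, so
no disk cache is kept) and derives every stage seed from the config seed,
making the report JSON byte-reproducible. The redundancy-vs-distance
regression is reported as null when the selected features span fewer than
three usable pairs or fewer than two distinct distances.

## Problem sizes and test conditions

Unit and acceptance tests run on grids of 10³–12³ voxels (≈ 500–900
foreground voxels), 5–8 parent regions, 12–48 nodes, 29–33 subjects, and
120–150 timepoints. The qualitative multiscale replications use
effect_size = 0.25 with 16/13 subjects, which places CV accuracy in the
70–90% band typical of small rs-fMRI classification studies, and judge each
directional claim by majority over 10 generator seeds. The acceptance
script uses 19/14 subjects (the 38/28 design at half size) at scales
{12, 24, 48}.

## Known limitations

* Weighted networks, global metrics, and connectivity-driven (functional)
  parcellation are out of scope; graphs are binary and parcellation is
  purely spatial.
* The region-growing rule's original description is ambiguous about merge
  order and seed updates; the global priority-queue reading implemented here
  is a documented choice, not the only one.
* The incremental mRMR score and the literal set-level formula differ for
  singleton sets (the latter subtracts the feature's own entropy); both are
  provided because which one a given toolkit emits varies.
* Synthetic cohorts have region-homogeneous signals, so node-mean extraction
  is nearly noiseless compared to real data; absolute accuracies on
  synthetic cohorts exceed what equivalent clinical data would give.
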
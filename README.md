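# netscale

Multiscale functional brain-network classification analysis: how does the
number of network nodes (the parcellation scale) affect discriminative
features, classifier accuracy, and feature redundancy in resting-state fMRI
group studies?

`netscale` is aimed at researchers studying connectome-based classification
(e.g., patients vs. controls) who want a tested, fully synthetic-data-capable
implementation of the classic pipeline:

1. **Parcellation.** A parent atlas (≈90 anatomical regions) is subdivided
   into approximately *N* nodes. Each region with volume fraction *V*
   receives *k* = round(*V·N*) subregions, grown from *k* random seed voxels
   by repeatedly merging the globally nearest (voxel, seed) pair in mm space,
   with the seed re-centred on its subregion's running mass centre. Subregions
   never cross parent boundaries.
2. **Network construction.** Node-mean time series are residualized against
   nuisance regressors (6 motion-like + 2 tissue-like; no global signal
   regression), correlated with Pearson's *r*, and binarized at proportional
   sparsity thresholds *S* ∈ {8%, 13%, 18%, 23%, 28%} (keep the
   *E* = round(*S·n(n−1)/2*) strongest edges).
3. **Features.** Three nodal metrics — degree, betweenness centrality
   (normalized by (*n*−1)(*n*−2)/2), nodal efficiency — on every binary graph,
   each node's metric-vs-*S* curve collapsed to a trapezoidal AUC. Feature
   count = 3 × node count.
4. **Screening.** Two-sample Kolmogorov–Smirnov tests per feature,
   Benjamini–Hochberg FDR at *q* = 0.05.
5. **Classification.** Linear SVM (LIBSVM via scikit-learn, tol 1e−3,
   C = 1), stratified 10-fold cross-validation repeated 100×, with
   training-fold-only standardization. Includes an accuracy-vs-feature-count
   sweep (features added in ascending-*P* blocks of 3) and a nested 70/30
   holdout protocol with C = 2^c, c ∈ [−5, 5] tuned by inner 10-fold CV.
6. **mRMR feature evaluation.** Features discretized at mean ± σ; for a
   feature set *S* and group label *h*:
   *D* = (1/|S|) Σ *I*(*h*,*i*), *R* = (1/|S|²) Σ *I*(*i*,*j*),
   MID = *D* − *R* (bits). Per-feature effectiveness is the incremental mRMR
   score; pairwise redundancy is regressed on inter-node centroid distance.

A synthetic-data module generates label atlases and two-group voxel-level
cohorts with *planted* connectivity effects (a shared hub signal mixed into
selected regions for patients only), so every downstream stage is testable
end-to-end without any scanner data.

## Worked example

```python
from netscale import *
from netscale.metrics import build_feature_table
from netscale.screening import screen_features, select_features
from netscale.classification import repeated_kfold
from netscale.mrmr import discretize, per_feature_mid

atlas = generate_atlas(shape=(12, 12, 12), n_regions=8, seed=0)
spec = CohortSpec(n_patients=19, n_controls=14, n_timepoints=150,
                  effect_regions={1, 2}, effect_size=0.3, seed=0)
cohort = generate_cohort(atlas, spec)

parc = subdivide_atlas(atlas, N=48, seed=0)
table = build_feature_table(cohort, parc)
screen = screen_features(table, q=0.05)
selected = select_features(screen, mode="fdr", param=0.05)
cv = repeated_kfold(table.X, table.group, feature_idx=selected,
                    repeats=100, seed=0)
disc = discretize(table.X)
scores, order = per_feature_mid(disc, table.group)
```

prints (via the obvious `print` statements):

```
parcellation: 48 nodes (target 48)
features: 33 subjects x 144 AUC features
screening: 30 discriminative features (KS, BH-FDR q=0.05)
classification: accuracy 84.6%, sensitivity 87.9%, specificity 80.1%
mRMR: best feature degree:2, MID score 0.417 bits
```

The cohort plants a correlation shift of 0.3 between regions 1 and 2 in the
19 patients; screening finds 30 of 144 AUC features significant, the linear
SVM separates the groups at 84.6% mean accuracy over 100 × 10-fold CV, and
the most effective single feature by incremental mRMR is the degree AUC of a
node inside an affected region (relevance 0.417 bits).

## Command line

Every stage is a subcommand: `netscale simulate | parcellate | network |
features | screen | classify | mrmr | sweep`, e.g.

```bash
netscale parcellate --atlas atlas.nii.gz --n 250 --seed 42 \
    --out parc250.nii.gz --node-table nodes.tsv
netscale sweep --config sweep.yaml --out report.json
```

Atlases and parcellations are NIfTI-1 integer label volumes; cohorts are 4D
NIfTI files with TSV manifests; feature tables, screens, and node tables are
TSV; reports are JSON.

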
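# Methods

`sabrrad` implements a radiomics pipeline for a specific clinical decision
point: a lung lesion treated with stereotactic ablative radiotherapy (SABR)
has just triggered RECIST 1.1 progressive disease on a follow-up CT, and the
question is whether the apparent growth is cancer recurrence or benign
radiation-induced lung injury (RILI). The pipeline covers ROI construction
from the clinician's RECIST line, texture/shape feature extraction, a
bootstrapped random-forest evaluation with correlation filters, and the
statistical analyses used to compare ROI designs and rank features. Because
clinical cohorts of this kind are not publicly available, the package ships a
synthetic CT phantom generator so every stage is exercised and tested
end-to-end on data with known ground truth.

## RECIST progressive disease

A measurement series is the lesion's longest axial diameter per scan, scan 0
being pre-treatment. Scan `t >= 1` triggers progressive disease when

    length[t] >= 1.2 * nadir(t)   and   length[t] - nadir(t) >= 5 mm,

where `nadir(t)` is the running minimum over scans `0..t` (the pre-treatment
size is included in the nadir). Ties at exactly 20% or exactly 5 mm count as
PD. The earliest triggering scan is the analysis scan; later scans are never
used. Only the single-lesion rule is implemented (no target/non-target sums).

## Phantom cohorts

Each case is a 3D grid (default 128 x 128 x 42 voxels at 0.74 x 0.74 x 5.0 mm;
optionally randomized within 0.57-0.84 mm in-plane / 1.5-5.0 mm slices to
exercise the resampling stage) containing:

* a lung volume (an ellipsoid filling ~96% of the grid) of smoothed Gaussian
  parenchyma noise at -850 +- 40 HU, inside a 20 HU body;
* one lesion: the union of a primary ellipsoid and 1-3 bump ellipsoids whose
  in-plane footprint is confined to a disc of the target diameter, so the
  continuous shape's longest axial chord equals the requested diameter and its
  margins are irregular enough that RECIST chords and graph-cut seeds are
  non-trivial;
* a ground-glass halo: a 10 mm shell around the lesion whose HU fades linearly
  from a -600 HU core value at the lesion edge back to parenchyma;
* a serial measurement schedule. Recurrence lesions grow monotonically
  (factors 1.0, 1.1, 1.35); RILI lesions shrink and regrow (1.0, 0.7, 1.0),
  the pseudo-progression pattern. Both trigger PD at the second follow-up for
  every diameter in the supported range. The PD-scan diameter is drawn from
  the *same* truncated normal (mean 55, sd 8, clipped to [30, 60] mm) in both
  classes, so lesion size carries no outcome information — mirroring the
  target population in which size at progression does not separate the
  classes. The whole series is re-anchored on the voxelized RECIST length of
  the rendered lesion so the configured schedule ratios hold exactly.

Class contrasts are planted in lesion appearance only, and only their
directions are clinically anchored (denser, more homogeneous recurrences;
noisier, positively skewed RILI); the effect sizes are free parameters of the
generator, not estimates of any clinical cohort:

| parameter                  | recurrence | RILI  |
|----------------------------|------------|-------|
| mean HU                    | -50        | -150  |
| texture noise sd (HU)      | 40         | 80    |
| texture correlation length | 3.0 mm     | 1.0 mm|
| marginal skew (skew-normal)| 0          | +4    |

Lesion texture is white (skew-)normal noise smoothed with a Gaussian of the
class correlation length and rescaled to the class noise sd. Longer
correlation plus lower amplitude yields higher GLCM maximum-probability and
joint energy for recurrences; the skew-normal marginal gives RILI a more
positive intensity skewness. `PhantomParams.null()` averages all four rows,
removing every class contrast, and is the no-signal control used in tests.

Labels are assigned by exact stratification (`round(prevalence * n)`
recurrences, default prevalence 0.41) and shuffled deterministically from the
cohort seed; per-case randomness comes from spawned `SeedSequence` children so
cohorts are bit-reproducible.

What the phantom does **not** emulate: airways, vessels, fibrosis patterns,
respiratory/cardiac artifacts, scanner reconstruction kernels, partial-volume
blur at lesion margins, or radiologist measurement variability. Passing tests
therefore demonstrate that the pipeline recovers planted effects of this kind,
not that the clinical effect sizes or AUCs are reproduced.

## Regions of interest

All six ROIs derive from the RECIST line on the PD scan, intersect the lung
mask, and use voxel-center inclusion (a voxel belongs to a region iff its
center does, in mm world space):

* **lung slice** — the lung in the axial slice holding the RECIST line (2D;
  shape features skipped);
* **spheres** (d = 20 mm, 40 mm, RECIST length) centered on the line midpoint;
* **cylinder** — 10 mm radius, the RECIST line as rotation axis, flat ends at
  the line endpoints;
* **solid + GGO** — a seeded min-cut solid component plus a 16 mm concentric
  expansion shell (GGO excludes the solid; anisotropic mm distances via a
  Euclidean distance transform).

The solid segmentation is a binary s-t min-cut on the 6-connected voxel graph
(igraph's `st_mincut`): hard foreground seeds are the voxels under the
rasterized RECIST line, hard background seeds a circle of radius
`ring_factor * L/2` (default 1.5) in the RECIST slice, and pairwise weights
`exp(-dI^2 / (2 sigma_d^2)) + 1e-4`. The scale `sigma_d` is estimated per
axis as the median squared 6-neighbor intensity difference around the seeds:
per axis because slice spacing is several times the in-plane spacing, so
intensities decorrelate across slices and a single scale lets the cut slab
through the lesion interior; median because seeds that touch strong edges
(line endpoints on the lesion boundary, ring segments crossing the lung
border) would otherwise inflate the scale and erase the boundary contrast.
The result is the connected component containing the line, intersected with
the lung. A uniform image (all medians zero) returns the line seeds flagged
degenerate; a ring that intersects the line raises a seed-conflict error. The
ring radius/width is not pinned by any published protocol and is exposed as
configuration.

## Feature extraction

Per ROI: 20 first-order + (21 GLCM + 11 GLRLM) x 5 direction options
= 180 features; the solid+GGO pair adds the second sub-ROI's 180 plus 24
shape features on the solid, 384 total. The exact name lists are frozen in
`sabrrad.manifest` (version 1.0) and pinned by tests.

* First-order features are computed on raw HU values; entropy and uniformity
  on discretized levels. Skewness is the third standardized central moment and
  kurtosis its excess analogue; both are defined as 0 for zero-variance ROIs,
  and the coefficient of variation is 0 when the mean is 0.
* Discretization: 32 equal-width bins over the ROI min-max by default (a
  fixed-HU-window mode is available); recorded in the extraction sidecar. The
  published protocol's parameter table is not available, so this default is a
  documented choice, not a reproduction.
* GLCM/GLRLM use the four unique axial-plane neighbor offsets (0, 45, 90,
  135 degrees); out-of-plane neighbors are excluded because of voxel
  anisotropy. GLCMs are accumulated symmetrically and normalized; runs are
  truncated at the ROI boundary. The fifth direction option ("avg") is the
  arithmetic mean of the four per-direction feature values (not of the
  matrices).
* Shape features come from a marching-cubes mesh of the mask indicator,
  anti-aliased with a 0.5-voxel Gaussian so the mesh area does not carry the
  stair-step bias of a binary iso-surface (tiny masks that smooth below the
  iso-level fall back to the binary surface). Principal-axis lengths are
  4*sqrt(eigenvalue) of the voxel-center covariance; the convex hull is taken
  over boundary-voxel corners so a digital cube has solidity 1.

## Bootstrap experiment engine

`BootstrapForestExperiment` (model) / `ExperimentResult` (results) follow the
model-fit-results convention. Each of B iterations (default 500):

1. draw a training multiset of size n with replacement; the test set is the
   unique never-drawn cases (~36.8% of the cohort in expectation at n = 68);
2. optionally apply the inter-feature correlation filter on the training set:
   pairs with |Pearson r| > 0.80, processed in descending |r|, lose the member
   with the smaller absolute point-biserial correlation to the outcome (ties
   keep the lower column index; constant features have r defined as 0);
3. optionally apply the volume filter: drop features with a significant
   (p < 0.05) |Pearson r| > 0.5 against ROI volume in the training set;
4. grid-search a random forest by out-of-bag AUC (trees {100, 300} x min leaf
   {1, 5} x sqrt(p) features per split — a deliberately small documented grid,
   chosen once; the published grid is not available) and keep the best;
5. read the operating threshold off the OOB ROC at the upper-left corner
   (minimum Euclidean distance to FPR 0 / TPR 1; ties favor specificity);
6. optionally decimate the test set by randomly dropping positives until the
   positive fraction is closest to a target prevalence (never below one
   positive);
7. score the test set: AUC, and sensitivity/specificity at the OOB threshold.

Aggregation: mean AUC with a normal-theory 95% CI (mean +- 1.96 sd/sqrt(B))
over iterations — consistent with the narrow intervals this construction
produces — plus the pooled ROC over all concatenated test probabilities for
plotting (both views are reported since "average ROC" is ambiguous).
Sensitivity/specificity CIs are built the same way and clipped to [0, 1].
Iteration seeds derive only from the experiment seed, so model variants run
with the same seed share their splits exactly, making filter comparisons
paired. Single-class training or test sets skip the iteration with a log
entry. Feature importances are the forest's impurity-based scores; per
iteration they are min-max normalized with filtered-out features set to 0,
averaged across iterations, re-normalized, and thresholded at > 0.80 for the
"top" set (so the top feature always scores exactly 1).

## Statistical analyses

Normality is tested with a Kolmogorov-Smirnov test against a normal with
estimated moments, using the Lilliefors correction (a plain one-sample KS
with estimated parameters is anticonservative). Group comparisons of
per-iteration AUC sets use ANOVA + pairwise t-tests when every group is
normal, otherwise Kruskal-Wallis + pairwise rank-sum tests; post-hoc p-values
are Bonferroni-multiplied by the number of pairs. Two-sample comparisons use
the t-test / rank-sum (paired variants for shared-seed designs). Correlations
with the binary outcome use the point-biserial coefficient when values are
normal, otherwise the rank-biserial coefficient `2U/(n1*n0) - 1` from the
Mann-Whitney U. Correlation filters use absolute correlations. Single-feature
ROCs min-max normalize the feature as the classifier confidence, flip the
labels when the biserial correlation is negative (flagged), and report
sensitivity/specificity at the upper-left-corner point. Alpha is 0.05
throughout.

## Testing the null correctly

The engine's sanity oracle is two-sided: planted effects must be detected
(mean-AUC CI excluding 0.5, planted families in the importance top set) and a
null phantom must show none. The null side is checked across several
independent null cohorts (a t-interval over per-cohort mean AUCs covering
0.5) rather than on one cohort's iteration CI. The iteration CI measures
bootstrap resampling noise only; a single fixed cohort of 68 cases with 180
features has its own chance-level achievable AUC whose dataset-to-dataset
standard deviation (~0.05, measured on pure-noise tables) exceeds the
iteration-CI half-width (~0.03), so a one-cohort CI check would fail about
half the time even for a bias-free engine. Per-cohort means are the
exchangeable unit for the no-signal claim.

## Problem sizes and numerical choices

Tests run cohorts of up to 100 cases at the default grid for generator
statistics, and 68-case cohorts with 100-iteration experiments for
signal-recovery checks (40 iterations per cohort for the multi-cohort null
check); plumbing smoke tests use 12-case cohorts on a 72 x 72 x 24 grid with
~27 mm lesions. These sizes were chosen to keep the full suite comfortably
reproducible on a single CPU while leaving the statistical checks
well-powered. Degenerate inputs are defined rather than rejected wherever a
convention is defensible (zero-variance skewness/kurtosis, constant-feature
correlations, OOB threshold fallback 0.5); empty ROIs, single-class label
vectors, seed conflicts and geometry leaving the grid raise errors naming the
offending input.

## Known limitations

* The solid segmentation is a seeded min-cut with a Gaussian boundary term,
  not the published OneCut energy (whose color-histogram term targets natural
  images); it preserves the same interface (line = foreground, ring =
  background) and is validated against phantom truth masks, not clinical
  contours.
* Phantom effect sizes are free parameters; absolute AUCs obtained on
  phantoms say nothing about clinical performance.
* Feature lists follow common radiomics usage but are not IBSI-certified;
  the discretization and RF hyperparameter grid are package defaults.
* The 2D lung-slice ROI reuses the 3D texture machinery on a single slice;
  its GLRLM run lengths are bounded by the slice extent.
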
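# Methods

This note documents the models, numerical choices and limitations of
`vasculomorph` — what each stage computes, why the defaults are what they
are, and what the synthetic-data experiments do and do not demonstrate
about real histology.

## Stain model and unmixing

Pixels follow the Beer–Lambert law: optical density `OD = −log10(I/I0)` is
linear in per-stain absorbance densities with fixed unit stain vectors in
OD-RGB space. The default basis uses the standard literature H&E vectors
(hematoxylin ≈ (0.65, 0.70, 0.29), eosin ≈ (0.07, 0.99, 0.11), unit-
normalized) and `I0 = 255` per channel; both are configurable
(`stains.StainBasis`). Unmixing projects OD onto the pseudo-inverse of the
stain matrix, clips negatives (physical non-negativity), and by default
rescales each channel by its own 99th percentile — robust to the bright
tail — so channels live in [0, 1] up to a per-tile scale. Because the
synthetic renderer uses exactly this forward model, unmixing has a known
inverse on noise-free tiles; the tests require Pearson r > 0.999 between
recovered and true densities there.

## IHC color segmentation (six-state Gaussian HMM)

IHC tiles are decoded row by row (left→right raster order, each row an
independent observation sequence) with a six-state hidden Markov model:
three ink states (DAB brown, CD31 purple, hematoxylin blue) and three
background states (white, light blue cytoplasm, light brown residual DAB).
Emissions are full-covariance Gaussians in RGB estimated from labeled
pixel samples (≥ 20 per state), regularized by `pseudo_count·I`
(default 5) to keep covariances positive definite for near-constant color
samples. Transitions start self-biased (0.9 on the diagonal — pixels of a
stain run in contiguous strokes) and are refined by segmental Viterbi
re-estimation until decoded assignments stabilize (≤ 20 sweeps). Decoding
is delegated to hmmlearn's Viterbi implementation. Output masks are
despeckled by dropping 8-connected components under 20 px; CD31 takes
precedence over CD45 where both decode, because endothelial identity
seeds the rest of the pipeline. The despeckle size and the 5-px mask
dilation used during label transfer are conventions, not measurements;
both are exposed as parameters.

## Co-registration

H&E and IHC tiles of the same tissue are aligned by maximizing intensity
agreement (mean squared error) of their hematoxylin absorbance channels —
the channel both stains share — over a 6-parameter affine (rotation,
translation, anisotropic log-scale, shear) about the image center.
Optimization is Powell's method over a 3-level Gaussian pyramid, coarse to
fine, which gives a capture range of tens of pixels while recovering
translations and rotations to ≈ 0.1 px / 0.1° on tile-scale images.
Non-convergence at the finest level is flagged on the returned transform
together with the final metric value rather than raised.

## Nuclear segmentation and the 63-feature roster

Nuclei are segmented from the hematoxylin channel: median filter (disc
radius 2), Otsu threshold, hole filling, then watershed on the negated
distance transform with markers at distance peaks ≥ 4 px apart (the
distance map is smoothed with σ = 1 first so an elongated nucleus
contributes one marker, not a ridge of them); components outside
[15, 2000] px² are discarded.

The 63-feature vector per nucleus comprises 13 shape descriptors (area,
perimeter, circularity 4πA/P², eccentricity, solidity, extent, major/minor
axis, aspect ratio, equivalent diameter, orientation, convex area,
perimeter convexity), 9 intensity statistics (mean, SD, skewness, excess
kurtosis, min, max, quartiles) per stain channel, and gray-level
co-occurrence texture (contrast, correlation, energy, homogeneity at unit
distance in 4 directions, 16 gray levels quantized inside the nucleus)
per channel: 13 + 2·9 + 2·16 = 63. The roster is frozen in
`config.NUCLEUS_FEATURE_NAMES`; every feature is translation-invariant
(verified to 1e-9 in tests), and kurtosis is excess kurtosis (normal = 0)
throughout the package. The classifier is an RBF SVM, one-vs-rest,
class-balanced, with C/γ chosen by stratified 5-fold grid search.

## Vascular-area classification and skeletonization

The 17 pixel features are five EC nearest-neighbour distances (ranks 1–5;
with fewer than five classified ECs the missing ranks saturate at the
tile diagonal, a documented cap) and twelve eosin window statistics
(mean, SD, max, min at half-widths 5, 15, 30 px, edge-replicated
padding). The classifier is a 100-tree random forest trained on 6,000
pixels sampled stratified from CD31-positive and negative areas. The
probability map is thresholded at 0.5, closed with a 3-px disc and
components under 50 px removed; closing radius and minimum component are
conventions and configurable.

Skeletonization uses topology-preserving thinning. Branch pixels are
skeleton pixels with ≥ 3 skeleton neighbours (8-connectivity); 8-connected
runs of branch pixels merge into a single branch point at their centroid,
so thick junctions are not double-counted. Arms are the 8-connected
components of the skeleton minus branch pixels; each carries its pixel
count as length and the orientation of its principal axis, reported
axially in [0, 180). Arm pixels plus branch pixels exactly partition the
skeleton (a tested invariant).

## Tile morphometry (22 primaries) and case profiles (88 VFs)

Per tile, over the four object sets (EC nucleus mask, branch-point mask,
arm mask, VAM): foreground density, sliding-box lacunarity and
box-counting fractal dimension (12 features); plus VAM object count, mean
object area, mean solidity, mean eccentricity and Euler–Poincaré
characteristic; arm count, mean arm length and the circular SD of arm
orientations (computed on doubled angles, since orientations are axial);
EC mean nearest-neighbour distance; and branch-point count — 22 in total,
frozen in `config.PRIMARY_FEATURE_NAMES`.

Numerical conventions: Euler–Poincaré counts 8-connected components minus
4-connected holes. Box counting uses the dyadic sizes {2, …, 256} on a
grid anchored at (0, 0) and a least-squares slope of log N(s) vs
log(1/s); it reproduces 2.0 on a full mask and log 3/log 2 on a Sierpinski
raster within 0.05. Lacunarity is Λ = E[M²]/E[M]² over dense stride-1 box
placements; the default box is 32 px, a single scale per feature to keep
the roster at 22. Features undefined on a tile (empty object set, zero
variance) carry a NaN sentinel, never a silent 0.

A case profile needs ≥ 3 tiles. Each primary's distribution over tiles is
summarized by sample mean, SD (n−1), skewness g1 and excess kurtosis g2
(sentinel when fewer than 3 finite values or zero variance), giving
22 × 4 = 88 named vascular features. Sentinel tiles are excluded
per-feature with valid-count bookkeeping.

## Prognostic workflow

- **CV filter:** keep features with |σ/μ| ≥ 0.3 across cases on the raw
  scale; zero-mean features are kept iff σ > 0 (logged), constant
  features always dropped.
- **Log-rank:** the two-group statistic is computed directly (vectorized
  observed−expected with hypergeometric variances, p from χ²₁); it matches
  lifelines to machine precision in the tests, which also compare it
  against an exhaustive permutation reference on a 4-subject fixture. The
  direct implementation exists because the backward search evaluates it
  tens of thousands of times.
- **Risk-group clustering:** Ward linkage on z-scored features, cut at
  k = 2; the group with the lower Kaplan–Meier survival at the median
  follow-up time is labeled high-risk.
- **Stochastic backward search:** each of `n_iter` iterations (default
  1500; reduced sizes are used in tests and the acceptance script, see
  below) subsamples 80% of cases with its own spawned RNG stream and runs
  a full greedy elimination — at every step removing the feature whose
  removal minimizes the log-rank p of the resulting 2-group clustering —
  recording the subset with the smallest p along the path (ties toward
  fewer features). Clusterings in which one group holds < 10% of cases
  score p = 1: risk groups are cohort fractions, and without this floor
  the search is dominated by chance splits that peel off outliers.
  Selection frequencies aggregate over iterations; the final set is
  everything above the knee (largest drop) of the sorted frequency curve,
  falling back to 0.5 when the curve is flat.
- **Consensus clustering:** per candidate k, repeated 80% subsampling and
  Ward clustering build a consensus matrix (fraction of co-subsampled
  pairs co-clustered); the selected k maximizes the average silhouette
  width of the consensus-distance partition.
- **Cox / C-index:** lifelines, Efron tie handling; Harrell's C with 0.5
  per tie; constant covariates and non-convergence yield flagged results.
- **Intra/inter-case variance:** one-way ANOVA F on tile-level values
  grouped by case; an infinite-F sentinel when within-case variance is 0.

### On p-minimizing searches (limitation)

At the simulated discovery scale (64 cases, ~40 events, hazard ratio 2.4,
9 informative among ~50 retained features) the backward search does *not*
concentrate selection frequency on the planted features: the planted
signal's own log-rank p (~0.02) is routinely beaten by chance clusterings
found among the ~1,300 subsets each elimination path examines, so
aggregated frequencies carry no planted-feature enrichment. This is a
multiplicity property of any p-value-minimizing search at this sample
size, not an implementation artifact — with a stronger planted effect
(hazard ratio 4, 4-SD feature separation) the planted feature outranks
every noise feature in the median replicate, and the corresponding test
asserts exactly that. Conclusions drawn from such searches on real
cohorts of this size should rest on external validation (as the
gene-model stage provides), not on the selection itself.

## Gene signature and risk models

Expression is transformed log2(x+1) before every correlation and model
fit: Pearson correlation on raw RPKM-like values is dominated by the
heavy right tail. Per selected VF, all genes are ranked by Pearson r
across shared cases (constant genes get r = 0, flagged); the top
⌈0.0005·n_genes⌉ per direction per VF form the candidate pool (boundary
ties broken lexicographically by gene id, logged). Candidates are
filtered by the information-gain ratio of their Fayyad–Irani
MDL-discretized expression against the binary risk labels: the best
binary cut is accepted only if its gain clears the MDL coding cost
`(log2(N−1) + Δ)/N`; accepted genes with positive gain ratio
(gain / split information) form the signature. A median-split criterion
is available as a pluggable alternative.

Risk models are binomial elastic-net fits (mixing α = 0.5 by default) on
z-scored log-expression, with the penalty chosen from a 20-point
logarithmic path by stratified cross-validated deviance and the
one-standard-error rule (a `lambda_rule="min"` option exists). Two
training targets are supported: the VF-derived risk groups, and 24-month
disease-free status, for which cases censored before 24 months without an
event are excluded (their status is unknowable) and evaluation follow-up
is administratively censored at 24 months. Predicted probabilities ≥ 0.5
define the high-risk group; when a heavily shrunken model places every
probability on one side of 0.5 — common for the noisier ground-truth
target at n ≈ 50, where cross-validated deviance barely improves on the
null model — evaluation falls back to the conventional median
risk-score split and flags the report. Evaluation computes KM curves,
log-rank p, univariate and stage/grade-adjusted Cox hazard ratios, and
the C-index per covariate set.

## Synthetic data: what it emulates, and what it does not

Tiles: vessels grow as biased random walks (1 px/step, Gaussian heading
jitter σ = 0.15 rad, Bernoulli branching with 40–80° deflection, disc
stamping with per-branch radius 4–8 px), capped at 12 branches so a
256-px tile carries ~20% vascular area. EC nuclei line the 3-px vessel
wall band with ~9 px blue-noise spacing; cancer nuclei (and 3%
lymphocytes) fill the stroma. Nuclei are jittered ellipses whose stored
contour polygons are exactly the rendered regions. H&E rendering is
Beer–Lambert with the default basis plus Gaussian noise (σ = 4 of 255);
the pseudo-IHC tile assigns each pixel one of the six HMM color states
(ink on vessel walls and nuclei, halo/smudge background states) and
renders the state colors with the same noise. A tile records full ground
truth: vessel mask, ink masks, per-pixel color states, density maps,
centroids and contours.

Cohorts: two planted phenotype groups (high-risk fraction 0.375, the
discovery cohort's 24/64). Tile counts per case are drawn from a clipped
normal(25, 18) on [3, 74]; spatial tile sampling is not modeled — tiles
are exchangeable draws, which is the one deliberate simplification of the
tile-per-case structure. Case-level features are tile means; the 9
informative features (EC density/texture, arm-orientation dispersion,
lacunarity moments) shift by 2 between-case SDs in the high-risk group,
with within-case (tile) SD half the between-case SD so intra-case
variance is genuinely smaller than inter-case variance. Signal genes
follow `log2(x+1) = a ± ρ·z(feature) + √(1−ρ²)·ε` against their assigned
informative feature (ρ = 0.6 by default), with correlation signs
alternating across the panel — vascular expression programs contain both
up- and down-regulated members. Survival is exponential per group
(low-risk median 36 months, planted hazard ratio 2.4), independently
censored at the requested rate (uniform over each case's follow-up) plus
administrative censoring at 120 months.

What passing tests show: every algorithmic contract (dimensionalities,
invariants, analytic oracles) and the statistical machinery's calibration
and power under known generative conditions. What they do not show:
performance on real slides — the renderer has no out-of-focus regions,
stain variability across labs, tissue folds, necrosis, red blood cells,
or touching-nucleus clutter at real densities, and real gene–morphology
correlations are far weaker and more structured than the planted ones.
Operating points reported for pipelines of this kind on real
whole-slide renal-carcinoma cohorts (VAM AUC ≈ 0.78, EC AUC ≈ 0.95,
κ ≈ 0.68) are therefore treated as floors that the synthetic conditions
must exceed, not as values this package claims to reproduce.

## Problem sizes

Tests and `scripts/acceptance.py` run the generators at 256-px tiles,
64-case discovery cohorts (100-case validation), 20–30 backward-search
iterations and 30-replicate Monte-Carlo summaries. These are the
package's chosen study sizes for reproducible desk-scale runs; all
defaults that matter scientifically (cohort composition, effect sizes,
noise levels, the 1,500-iteration search default) live in
`synthetic.SyntheticCohortSpec` and the function signatures, and scale up
unchanged.
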
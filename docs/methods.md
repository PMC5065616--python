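# Methods

`nephroscreen` implements an imaging-based pipeline for predicting whether a
xenobiotic damages human renal proximal tubular cells (PTCs) in vivo, from
phenotypic changes the compound induces in cultured PTCs. The pipeline runs
in five stages: per-cell feature extraction, dose–response condensation,
random-forest classification, recursive feature elimination, and descriptive
profiling analyses. A synthetic-data generator with known ground truth
exercises every stage.

## Phenotypic features

Each cell is described by 129 features computed from four fluorescence
channels — DNA, a secondary marker (RelA or γH2AX depending on the screen),
actin, and a whole-cell stain (WCS) used for segmentation:

* **78 Haralick texture features** — 13 statistics of the gray-level
  co-occurrence matrix (GLCM), aggregated as mean and standard deviation over
  the four standard pixel offsets (0°, 45°, 90°, 135°), for each of the three
  fluorescent markers (13 × 2 × 3 = 78; the WCS contributes no texture).
  The GLCM is computed over the cell's bounding box with non-cell pixels set
  to zero, after quantization to N_g = 256 gray levels. Quantization bins the
  global 16-bit range by default; a per-cell min–max mode is available (the
  choice rescales levels and is absorbed by downstream normalization, but
  global binning keeps absolute intensities comparable across cells).
* **29 intensity features** — mean, total and coefficient of variation (CV =
  SD/mean) per marker and subcellular region (nuclear, cytoplasmic =
  cellular − nuclear, whole-cell) for the three fluorescent markers, plus
  WCS whole-cell mean and total. The composition is catalog-driven and can
  be replaced without code changes; the default is a reconstruction
  consistent with the printed family counts, not a verbatim published list.
* **9 intensity-ratio features** — total-intensity ratios including the
  nuclear-to-whole-cell ratio per marker and the secondary-to-DNA whole-cell
  ratio (the γH2AX-generation readouts).
* **6 correlation features** — Pearson correlation of pixel intensities for
  each unordered channel pair within the cellular mask.
* **6 morphology features** — area, perimeter and form factor (4πA/P²) of
  the nuclear and cellular regions. The perimeter uses the Crofton
  estimator, which is asymptotically unbiased for smooth shapes so a disc
  has form factor ≈ 1 at any radius.
* **1 cell count**, attached at the condition level; per-condition profiles
  are the mean over cells (population-averaged readout).

Numerical conventions for the texture statistics: gray levels enter the
formulas as 1-based values (so the sum distribution runs over k = 2..2N_g);
entropies use the natural logarithm with 0·log 0 = 0; the offset aggregation
uses the population SD (4 fixed offsets are a complete set, not a sample);
the correlation statistic is the centered cross-moment divided by both
marginal SDs (bounded in [−1, 1]), and is defined as 0 for degenerate
marginals. The six statistics beyond the seven commonly printed ones
(contrast, variance, inverse difference moment, difference variance,
difference entropy, IMC1) follow the original co-occurrence definitions.

Rolling-ball background correction (default radius 50 px, the common
ImageJ-style setting) is available ahead of extraction; output is clamped
nonnegative. Segmentation is an input (nuclear and cellular label masks,
nuclei nested in cells); a thresholding fallback (Otsu on DNA, Otsu on WCS
plus nucleus-seeded watershed) is provided for synthetic images only.

## Dose–response condensation (Δ and Δmax)

For every feature and treated condition, Δ = log₂(treated / vehicle), with
the vehicle control matched to the compound's solvent (DMSO or water) and
replicate. Each feature × compound × replicate series over the seven-dose
grid (1.6–1000 μg/mL, converted to molar units via the compound's molecular
mass) is fitted with the standard 4-parameter log-logistic model

    Δ(x) = c + (d − c) / (1 + exp(b·(log x − log e)))

where c and d are the lower/upper limits, e the half-way concentration and b
the relative slope. Because responses need not plateau within the tested
range, the curve readout Δmax is fixed as the fitted response at a reference
concentration of 5 mM (≈ the top tested dose for typical molecular masses)
rather than the asymptote d; entries where 5 mM exceeds the tested molar
range are computed by extrapolation and flagged. Fitting is nonlinear least
squares over (b, c, d, log e), initialized at c₀/d₀ = min/max response,
log e₀ = mean log-concentration, trying both slope signs and keeping the
lower-cost solution. Unconverged fits fall back to the observed Δ at the
highest tested dose and are flagged in the provenance table. The final
matrix entry is the median Δmax across biological replicates.

## Classification and performance estimation

Features are normalized to [−1, 1] by f ← 2(f − f_min)/(f_max − f_min) − 1
with f_min/f_max estimated **on training compounds only** (constant training
features map to 0); test values may leave [−1, 1]. Classifiers are random
forests with parameters N_tree ∈ {10, 50, 150, 250, 400, 500} and N_trial
(features per split) ∈ {1..5}, tuned by exhaustive grid search; ties break
toward the smaller model.

Generalization is estimated by a four-set nested stratified 10-fold
cross-validation over compounds (all data of a compound stays together):
the outer fold X_test is held out completely; the remaining compounds are
split 60/20/20 (stratified) into X_training (model fitting and
normalization), X_FStest (grid search) and X_RFtest (feature-subset
evaluation). The final fold classifier is refitted with the tuned
parameters and selected features on all inner compounds
(X_training ∪ X_FStest ∪ X_RFtest) — the held-out fold never influences
normalization, tuning or selection. The procedure repeats over trials with
different fold divisions; reported accuracies average over every fold and
trial with standard errors of the means. Metrics: sensitivity =
TP/(TP+FN)·100 %, specificity = TN/(TN+FP)·100 %, balanced accuracy =
(sensitivity + specificity)/2, whose chance level is 50 %. Classes smaller
than the fold count degrade gracefully to fewer folds with a warning.

## Feature selection

Recursive feature elimination per fold: train a forest on X_training, rank
features by out-of-bag permutation importance (per tree, the drop in
out-of-bag accuracy when one feature column is permuted, averaged over
trees; ties break by catalog order), drop the least important feature,
record the retained subset's balanced accuracy acc_j on X_RFtest, repeat to
one feature. The default drops one feature per iteration; a geometric speed
option drops a fraction of the retained set per iteration while more than
10 features remain, keeping the small-subset region densely sampled.
Parameter re-tuning each iteration is optional (`tune_every_iteration`).

Because acc_j trajectories are not smooth at small sample sizes, the final
subset is not the argmax: acc_j values are clustered by 1-D Gaussian
mixtures with 2–4 components (EM, k-means initialization, 10 restarts,
fixed seed), the component count minimizes BIC = −2·L_m + N_d·log N_s with
N_d = 3K − 1 (K means, K variances, K − 1 free weights), and the smallest
subset in the highest-mean-accuracy component is selected. An all-equal
trajectory degenerates to the single-feature subset. A spline/local-maximum
selector (smoothing spline, Gaussian band around the smallest-size local
maximum) is provided as an explicit alternative; the mixture selector is
the canonical one. The cross-fold consensus subset F_s ranks features by
importance averaged over folds and keeps the top k, with k the median
selected subset size across folds.

## Profiling analyses

Two-way hierarchical clustering of the Δmax matrix uses average linkage on
Euclidean distances (a configurable default; the linkage is not dictated by
the method). The two-cluster cut of compounds is tested for enrichment of
each cluster's majority toxicity class with an upper-tail hypergeometric
test. Feature-pair analyses report Pearson r across compounds, the
toxic-minus-non-toxic mean difference per feature, and one-sided two-sample
t-tests. Multidimensional scaling is classical (Torgerson): double-center
the squared dissimilarities, eigendecompose, take the top-2 coordinates;
chemical dissimilarity is 1 − Tanimoto over binary fingerprints (T defined
as 1 for two empty fingerprints), phenotypic dissimilarity is Euclidean
after scaling each feature to [0, 1]. Percent-positive cell-death scoring
thresholds treated single-cell distributions at the vehicle-control mean
plus 3 control SDs (a replaceable policy object; ≈ 0.13 % of control-like
cells score positive under a Gaussian control).

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: 24 PTC-toxic and 20 non-PTC-toxic
compounds, 129 features, seven doses (1.6–1000 μg/mL), three biological
replicates, DMSO/water solvents, and molecular masses drawn once per
compound from 150–600 g/mol. Planted effects are log-logistic on molar
concentration, so the analytic response at 5 mM is known exactly and the
dose–response stage can be validated against it. Replicate noise is
multiplicative log-normal (feature values are positive intensities and the
analysis is ratio-based); its default SD of 0.3 log₂ units, and the default
informative effect size of 2.0 log₂ units (strong planted runs use 3.0),
are free parameters chosen once as plausible for high-content data — the
source screens report no vehicle-control variance to calibrate against.
Cell-level heterogeneity is a two-component responder model: a fraction of
cells realizes the full fold change, the rest none; at responder fraction 1
the population multiplier is exactly 2^Δ.

Direct Δmax-matrix generation supports two class-conditional structures:
`shared` (every informative feature shifts, with alternating sign, for every
toxic compound — a fully redundant signal matching the simplest reading of a
class-dependent mean shift) and `complementary` (half of the toxic compounds
respond in all informative features, the rest respond in exactly one,
round-robin — every feature individually informative yet none redundant,
mirroring the observation that different toxicants induce different injury
phenotypes and that multi-feature classifiers beat the best single feature).
Redundant signals make single-feature subsets genuinely optimal, so subset-
recovery studies use the complementary structure.

Synthetic images are elliptical cells on a grid (never overlapping) with
elliptical nuclei; the chromatin-punctateness dial in [0, 1] adds bright
heterogeneous DNA foci (spatial Poisson process) over a dimming, speckled
diffuse background — reproducing the punctate, high-CV, high-GLCM-entropy
chromatin phenotype of DNA-damage responses. The dial acts superlinearly so
mid-dial settings land mid-way in the texture statistics instead of
saturating them; focus amplitudes stay below the 16-bit ceiling so their
gray levels remain distinct. The images are not photorealistic: no optics
(PSF, chromatic shifts), no spectral bleed-through, no confluency or
cell-cycle structure, no illumination gradients. Tests passing on these
images validate the measurement code and the monotone response of texture
statistics to chromatin reorganization, not biological realism.

## Problem sizes and stochastic-check design

Simulation-based checks use study-scale matrices (129 × 44) for
classification and chance-level controls, and 30-feature matrices for
elimination-trajectory studies, with reduced parameter grids (singletons to
small subsets of the full 6 × 5 grid) — the package's own choice of desk-
scale problem sizes; the full grid is the library default. The chance-level
control requires the 10 × 10-fold mean balanced accuracy of label-permuted
data to fall in [45, 55] % (it can dip below 50 % in finite samples).

## Known limitations

* With 44 compounds the elimination trajectory is evaluated on ~8 held-out
  compounds per fold (12.5 %-quantized accuracies), so the mixture selector
  occasionally accepts very small subsets whose high acc_j is a sampling
  artifact; the consensus size (median over folds) inherits some of this
  noise. This is a property of the printed procedure at this sample size,
  not of the implementation.
* The exact identities of the 29 intensity and 9 ratio features in the
  original screens are only available in their supplementary material; the
  default catalog is a documented reconstruction, configurable so a
  corrected list can be swapped in.
* The deposited screen matrices are required to reproduce published
  accuracies; without them the corresponding acceptance checks report the
  missing input rather than a number.
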
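# Methods

`lesionet` implements a multimodal prediction framework for chronic
post-stroke deficits: behavioural factor scores are predicted from (i) the
structural lesion, via cross-validated voxel-based correlational mapping and
lesion-load regression, and (ii) functional and structural connectomes, via
elastic-net regression over all ROI-pair features — together with the
machinery needed to ask whether connectivity explains variance the lesion
does not. Because patient imaging of this kind is not openly shareable, the
package ships a synthetic cohort generator whose planted ground truth makes
every claim testable as a parameter-recovery or calibration property.

## The synthetic cohort

A cohort lives on one isotropic grid (default 24³ voxels at 2 mm). Left and
right are split on the first voxel axis at `floor(nx/2)`.

**Lesions.** Each patient carries a single ellipsoidal lesion confined to the
left half. Lesion centres are drawn from a Gaussian around a vascular
"territory core" (default scatter 0.2 of each dimension), reflecting that
stroke lesions share an arterial territory rather than tiling the
hemisphere; when a parcellation is supplied the core snaps to the centroid of
the nearest left-half parcel so planted effects are resolved at parcel
granularity. Per-patient target volumes are uniform over
`lesion_volume_range_mm3` and the ellipsoid scale is bisected until the voxel
count lands in range. The continuous abnormality image is the
Gaussian-smoothed mask (default FWHM 2 voxels), standing in for a normalized,
smoothed structural abnormality map; values stay in [0, 1].

**Behaviour.** Each latent factor has a unit variance budget:

    f = sqrt(effect_r2) * z(1 - load) + sqrt(sc_independent_r2) * z(u) + e

where `load` is the mean abnormality-image value in that factor's critical
ROI (the glossary meaning of lesion load; equal to damaged proportion for
binary masks), `u` is a per-subject latent carried only by SC edges (factor 1
only, and only when `sc_collinear` is off), `z` is empirical
standardization, and `e` is Gaussian with the residual variance. So
`effect_r2 = 1` makes the factor an exact affine function of lesion load, and
`effect_r2 = 0` decouples it entirely. Critical ROIs are the left-half
parcels whose load varies most across the generated patients — one per
factor, guaranteeing identifiability at the configured n. Raw test scores
are `max_m * clip(0.6 + 0.15 * (L f)_m + noise_sd * eps, 0, 1)` with a
block-structured loading matrix L (disjoint test support per factor, hence
orthogonal columns); every third test has no recorded maximum, so the
group-maximum normalization rule is always exercised.

**Time series.** ROI k of subject s follows
`(1 - d_sk) * g_c(k)(t) + noise_sd * eps(t)` where `g_c` is a fresh
community latent per subject and `d_sk` the damaged fraction — a destroyed
ROI emits pure noise, intact ROIs within a community correlate. Controls use
zero damage; their 4D volumes are reconstructed on demand (voxel = ROI series
plus voxel noise), deterministic in the seed.

**Structural connectomes.** The base connectome has within-community
strength 0.6 and between 0.15 (±0.05 jitter). Subject matrices are
`base_ij * (1 - d_i) * (1 - d_j)` — streamline probability decays with
damage at either end. With `sc_collinear` this is the *entire* model: SC is
an exact deterministic function of the lesion, operationalizing the
collinearity claim. Otherwise `u` modulates (amplitude 0.2, u clipped to ±2
to avoid clipping the matrix into nonlinearity) a fixed edge pattern among
right-hemisphere ROIs.

**What the generator does not emulate:** haemodynamics, realistic anatomy or
atlas geometry, multifocal or non-ellipsoidal lesions, distance-dependent
connectivity, scanner noise structure, or behavioural floor/ceiling
pathologies beyond clipping. Passing recovery tests therefore show the
*machinery* is sound under the stated generative assumptions, not that the
effect sizes transfer to patients.

## Behavioural factors

Scores are converted to percentages of the stated maximum (observed group
maximum where unstated; a test whose effective maximum is zero raises). PCA
is computed on the correlation matrix — tests remain on heterogeneous scales
even as percentages. Components with eigenvalue ≥ 1.0 are retained (the
boundary value is retained; only eigenvalues strictly below 1 are excluded),
then varimax-rotated (raw criterion, via statsmodels' GPA rotation,
tolerance 1e-8). Each factor is flipped so its dominant test loads
positively. Factor scores use the regression method,
`W = V diag(ev^-1/2) T`, which gives exactly mean-0, unit-variance scores on
the fitting sample; a brute-force check against 10,000 random orthogonal
rotations confirms the rotation maximizes its own criterion.

## Lesion mapping (LOOCV VBCM)

For each left-out subject: Pearson correlation of every voxel's abnormality
value with the training targets (two-tailed p from the t transform, n−2 df;
zero-variance voxels are excluded, not treated as r = 0), Benjamini–Hochberg
FDR at q = 0.05, face-connected components, clusters strictly larger than
`min_cluster_volume_mm3` (default 2 cm³) kept, multiple linear regression of
the target on mean abnormality per cluster (rank-deficiency resolved by
least-squares pseudoinverse), and prediction of the held-out subject. Folds
with no surviving cluster predict the training mean (logged) — note that
leave-one-out mean predictions are perfectly *anti*-correlated with the
target, so an all-empty model reports r ≈ −1; this is harmless for the
permutation test because the same artifact appears under every shuffle.
Accuracy is the Pearson r between out-of-fold predictions and targets;
significance is `p = (1 + #{null r ≥ observed}) / (n_perm + 1)` with the
entire procedure (ROI rediscovery included) re-run per shuffle. The
stability map counts, per voxel, the folds whose surviving clusters covered
it. No lesion-volume covariate and no one-tailed option are implemented.

## Connectivity features

ROI series are linearly detrended and band-passed 0.01–0.08 Hz with a
4th-order zero-phase Butterworth. FC is Fisher-z of pairwise Pearson
correlations, r clamped to ±(1 − 1e−7) before atanh so identical series stay
finite. Any ROI overlapping the subject's lesion by one voxel or more has
all incident FC pairs zeroed. SC averages the two reciprocal streamline
probabilities and zeroes ROIs whose damaged fraction strictly exceeds 0.95.
Matrices collapse to the strictly-lower-triangle vector in a fixed
column-scan order ((2,1), (3,1), …, (K,1), (3,2), …), so feature c maps to
one ROI pair for every subject; K = 200 gives 19,900 features. A sidecar
JSON records the column → pair map.

## Elastic net with nested LOOCV

The objective is the standard one: `(1/2n)·RSS + λ[(1−α)/2·Σβ² + α·Σ|β|]` on
features standardized within each training fold only, coefficients reported
on the original scale. The λ path is 100 log-spaced values from the training
λ_max down to 0.001·λ_max (recomputed per training set and per α; α below
0.001 anchors the path at α = 0.001); the default α grid is
{0.01, 0.05, …, 1.0} — pure ridge is excluded from the default because its
path anchor is undefined, but α = 0 is available explicitly and solved in
closed form. Inner LOOCV over the outer training set selects (α, λ) jointly
by minimum squared prediction error, ties broken toward larger α then larger
λ (deterministic scan order). The outer loop refits at the chosen pair and
predicts the held-out subject; per-fold weight vectors are kept for network
summaries, and the fold-averaged chosen α is reported as the model's
sparsity level. Permutation significance re-tunes everything per shuffle —
the conservative reading of re-fitting "the model" under the null.

The coordinate-descent solver (cyclic, covariance-free, glmnet-style active
set, warm starts along the path) is written in-package and numba-compiled:
the permutation scheme above multiplies nested LOOCV by the permutation
count, which demands hundreds of thousands of path fits per test — orders of
magnitude beyond what generic solver call overhead allows. Unit tests pin
the solver to closed-form OLS/ridge limits, to the LASSO null point
(λ ≥ λ_max ⇒ β = 0), and to an independent reference implementation at
tolerance 1e-5. Convergence is declared when the largest coefficient change
in a sweep falls below `tol` (default 1e-5 on standardized data).

## Model comparison

Squared out-of-fold errors of two models on matched subjects enter a
Wilcoxon signed-rank test: zero differences dropped (Wilcoxon's original
treatment), tied |d| mid-ranked, z from the tie-corrected normal
approximation with continuity correction, sign negative when the second
model's errors dominate. For ≤ 25 nonzero differences the p-value is exact —
a dynamic program over doubled mid-ranks that reproduces full 2ⁿ
enumeration. Residual targets are the *out-of-fold* residuals of the lesion
model: training-set residuals would leak the training fit into downstream
models. Comparisons across modalities with different samples restrict to the
subject intersection.

## Network summaries

Per-fold weights are averaged feature-wise; z-scores are computed over the
features with nonzero fold-mean weight (structural zeros of sparse models
would otherwise dominate the standardization; the all-features alternative
is a one-line change and is logged); |z| > 3.29 (two-sided P < 0.001)
defines the significant set. Nodal degree sums *absolute* incident
significant weights by default — the signed sum sits behind a flag — along
with the proportion of positive incident connections (undefined for isolated
nodes). Top-k nodes (default 10) break ties toward the lower node id. The
node-filtered connection view is a visualization aid and is labelled as such;
it is not a refitted model.

## Healthy seed networks

Control 4D volumes are seeded with the lesion-derived stable region
(intersected with the grey mask — the synthetic grid is all "grey");
seed-mean-to-voxel correlations are Fisher-z'd and enter a one-sample t-test
(zero-variance voxels excluded). Cluster-extent correction is Monte-Carlo:
white noise smoothed to the data's estimated FWHM (lag-1 autocorrelation
moment estimator, user-overridable), re-standardized in-mask, thresholded at
the two-sided voxel p, maximum cluster size recorded per simulation; the
threshold is the ceiling of the (1 − cluster_p) quantile. Overlap scoring is
positive-tail by default and counts a node as overlapping when ≥ 1 of its
atlas voxels is suprathreshold (centroid-in-mask is available as a flag).
The procedure is calibrated by its own family-wise error property, not
against any legacy simulation binary.

## Orchestration and reproducibility

`run_study` executes simulate → factors → lesion models → features →
connectivity models → comparisons → residual models → summaries → seed
networks from one config. Stage seeds fan out as
`SeedSequence([global_seed, stage_index])`, so stages are independently
reproducible; identical configs reproduce reports bit-for-bit (timestamps
aside). An optional `connectivity_subset` mirrors studies where only some
patients carry imaging of every modality: connectivity models use the first
m patients and comparisons restrict to the intersection. Any cell failure is
recorded per-cell with its reason and the pipeline continues.

## Problem sizes in the shipped tests

The test suite and the acceptance script run on miniature phantoms chosen as
the smallest cohorts at which each property is identifiable: recovery and
collinearity cohorts use a 16³ grid at 2.5 mm (a 4 cm field of view), 8–16
parcels, lesions of 0.8–4 cm³, n = 60 patients for lesion mapping with
imaging subsets of 20–30 for connectivity models, 99 permutations, a λ path
of 6–10 values down to 0.1–0.15·λ_max and a solver tolerance of 1e-4–3e-4
for the permutation-heavy properties. The cluster-extent floor is 500 mm³ in
these runs: the whole-brain default of 2 cm³ is proportionate to a ~1.3
litre brain, not to a 64 cm³ phantom, and volume thresholds must scale with
the field of view. Calibration of the Monte-Carlo threshold uses
24³ null fields at FWHM 2.5 voxels, 2,000 simulations for the threshold and
1,000 fresh fields for the family-wise-error estimate.

## Known limitations

- The VBCM stage needs n ≳ 40 before whole-grid BH-FDR reliably clears
  threshold at moderate effect sizes; below that, folds legitimately return
  empty ROI sets and fall back to mean predictions (reported and logged).
- At desk scale the FC models are markedly weaker than SC: the
  lesion-overlap masking rule binarizes FC's main lesion channel (one voxel
  of overlap zeroes a pair regardless of the damaged fraction), and with few
  parcels and short series the masking pattern is coarse while correlation
  estimates are noisy. SC, being a continuous deterministic function of
  damage, predicts well in the same cohorts. Fine parcellations (hundreds of
  regions) and long acquisitions would be needed for FC power; FC's null
  behaviour (type-I control) is unaffected and is what the shipped
  properties assert.
- The exact Wilcoxon p is used only up to 25 nonzero differences; beyond
  that the tie-corrected normal approximation applies.
- The stability/Dice recovery property depends on lesion geometry: localized
  (territory-clustered) lesions localize well; lesions tiling the hemisphere
  produce anticorrelated distant voxels that the two-tailed map correctly
  flags but that dilute Dice.
- Factor-score estimation uses the regression method only; no oblique
  rotations; complete cases only.
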
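# Methods

This note documents the models and procedures implemented in
`habitatmri`, the assumptions behind the synthetic cohort generator, the
numerical conventions, and the design decisions taken where the
methodology was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. The analysis chain

### Preprocessing

Images are conditioned in the order **bias correction → isotropic
resampling → intensity standardization**.

*Bias field.* The intensity inhomogeneity is modelled as a smooth,
strictly positive multiplicative field. The default estimator fits a
low-order polynomial (degree 3) to the log-intensities and divides it
out; `method="n4"` delegates to SimpleITK's N4 with iteration schedule
(50, 50, 50, 50) and a 200 mm control-point mesh. In the per-patient
chain the field is estimated once, on the peak-enhancement phase, over
**body tissue excluding the tumor**, and divided out of every phase: the
field is a property of the coil, not of the contrast phase, and fitting
it over the bright lesion would absorb anatomy into the "bias" and
imprint an artificial radial gradient on the tumor (we observed exactly
this failure mode — surface-versus-interior intensity strata dominating
the downstream clustering — before excluding the lesion from the fit).

*Resampling.* B-spline (degree 3) interpolation to 3 mm isotropic
voxels; output axis length is `ceil(n·spacing/3)` so physical extent is
preserved within one voxel; masks and label maps use nearest-neighbour
and are re-binarized.

*Standardization.* Default is a per-patient affine map giving the
within-mask voxels mean 0 / sd 1 (applied to the whole volume); a
Nyul-style landmark mode is available. Standardization is applied to
the peak phase only — the kinetic features are computed from the
corrected but unstandardized series, because forcing every phase to
mean 0 / sd 1 would destroy the time–intensity curve that those
features measure. Whether the source protocol standardized per patient
or against a cohort reference is unstated; per-patient is the default
and is recorded in the provenance.

### Voxel features (8 + 10 + 4 = 22)

Per tumor voxel, from its 3×3×3 neighbourhood clipped to the mask:

- **8 gray-level statistics** — mean, median, sd, min, max, skewness,
  kurtosis (Fisher), histogram entropy (16 bins). Single-voxel windows
  take sd = skewness = kurtosis = 0 by convention.
- **10 GLCM texture descriptors** — contrast, correlation, joint
  energy, homogeneity, dissimilarity, joint entropy, cluster shade,
  cluster prominence, maximum probability, inverse difference moment;
  symmetric co-occurrence pooled over the 13 unique distance-1 3-D
  directions. Windows are quantized **per window min–max** to 16 levels
  (default), which makes the texture features invariant to monotone
  intensity scaling; a patient-global quantization mode exists.
  Single-gray-level windows take correlation = 1, energy = 1,
  contrast = 0.
- **4 enhancement parameters** — peak relative enhancement
  (S_peak − S0)/max(S0, ε); time-to-peak (post-contrast phase index of
  the maximum); wash-in rate (S_peak − S0)/t_peak; wash-out rate
  (S_last − S_peak)/(t_last − t_peak), zero when the peak is last.

The exact identity of the original 22-feature list is not public; the
8/10/4 family split is preserved and each formula follows the public
radiomics feature standard. The set sits behind a stable, documented
column order so an alternative 22-feature bank can be swapped in.

The smallest window (radius 1) is the default: it maximizes the spatial
resolution of the habitat map. Boundary windows are clipped to the
mask, so edge voxels use fewer neighbours — note that the
*sample-size-dependent* descriptors (entropies, energy, maximum
probability) therefore carry a mild window-size gradient near the tumor
surface.

### Habitat clustering

Training-cohort voxel vectors are pooled and z-scored with the pooled
statistics (unscaled features would let the enhancement parameters
dominate Euclidean distances). For each candidate k in 2..5, k-means
(k-means++ initialization, ≤1,000 Lloyd iterations) is restarted 10
times with derived seeds; the per-k score is the **mean
Calinski–Harabasz index over restarts** (the source text does not say
over what the mean is taken; restarts are the only repeated unit in a
single pooled fit, and per-patient clustering is ruled out because the
fitted subregions are applied unchanged to test patients). The selected
k maximizes the mean CH, ties toward smaller k. Centroids come from
the best-inertia restart at the selected k and are renumbered by
decreasing training cluster size, so "habitat 1" is reproducible.
Assignment standardizes a patient's voxels with the *training*
statistics and takes the nearest centroid, ties toward the lower id.

### Region radiomics and the ICC filter

From the standardized peak-phase volume, per region (whole tumor and
each habitat): first-order statistics, 3-D shape (volume, surface area
by marching cubes, sphericity, maximum diameter, elongation, flatness),
GLCM (13-direction pooled symmetric), GLRLM and GLSZM
(26-connectivity), each quantized to 32 equal-width levels over the
region range. Optional Laplacian-of-Gaussian and single-level wavelet
filter banks multiply the intensity families; the default bank is the
original image only (the full 1,197-feature configuration of the source
study is not recoverable from its text, and the count is deliberately
not a test surface — the bank is configurable and its hash is recorded).
Regions below 8 voxels yield flagged missing rows that are mean-imputed
within the training data during selection.

Reproducibility filtering uses ICC(2,1) — two-way random effects,
absolute agreement, single measure — between the feature tables of two
delineations; features with ICC > 0.75 are retained, separately per
region tag. In the synthetic pipeline the second rater is emulated by
flipping each boundary-layer voxel of the mask with probability 0.15
(a perturbation comparable to routine inter-observer Dice); full-voxel
erosion/dilation at 3 mm voxels proved far harsher than real
inter-rater variability and left almost nothing above threshold.

### Selection cascade

1. Two-sided Mann-Whitney U per feature (exact for small tie-free
   samples, tie-corrected normal approximation otherwise), keep
   p < 0.05. A one-way ANOVA screen is available
   (`univariate="anova"`) because the source is internally inconsistent
   about which was used; the Methods-section choice is the default.
2. Greedy Pearson pruning in ascending-p order: a feature survives iff
   |r| ≤ 0.9 against every survivor so far, so each correlated group
   keeps its most significant representative.
3. LASSO on the standardized survivors against the 0/1 outcome
   (squared-error loss — the literal reading of "minimizing the MSE"),
   λ on a 100-point logarithmic grid from λ_max down four decades,
   chosen by stratified, seeded 5-fold cross-validated MSE. Nonzero
   coefficients define radscore = intercept + Σ coef_i·z(feature_i).

### Models, nomogram, evaluation

Signatures are logistic regression (maximum likelihood with a weak L2
stabilizer, ε = 1e-4·n) or a single-hidden-layer MLP (16 logistic
units, early stopping on a 20% inner split, fully seeded — the
architecture is unspecified in the source and recorded in the report).
The decision threshold is the Youden optimum on training scores, frozen
for test. The clinicopathologic signature uses the superset of
reported variable lists (age, ER, PR, Her-2, Ki-67, cT, cN; the
variants disagree across sections, and the superset is configurable
down). The nomogram is a multivariate logistic on (habitat radscore,
clinical score); following the source, the clinical component defaults
to the MLP score (`nomogram_clinical_kind`). Point scales are affine
per component with the largest |coefficient|·range spanning 0–100.

Evaluation per cohort: AUC as the tie-corrected Mann-Whitney statistic
with a DeLong structural-component 95% CI; accuracy / sensitivity /
specificity / PPV / NPV at the frozen threshold; Hosmer–Lemeshow
χ² = Σ_g (O_g−E_g)²/(n_g ē_g(1−ē_g)) over risk deciles (tie-heavy
groups merged; df = max(groups−2, 1) — the 2-group hand-computable case
is admitted); decision curves with treat-all/treat-none references.

## 2. The synthetic cohort generator

The generator defines the study conditions for every test. A phantom
is an ellipsoidal tumor (semiaxes 30/26/22 mm) in low-signal background
on a 24×22×19 grid at 3 mm isotropic spacing, partitioned into three
compact subregions by Voronoi cells of farthest-point-sampled seeds.
Each habitat has a spatially correlated Gaussian intensity field
(mean, sd, correlation length) defining its peak-enhancement
appearance and a piecewise-linear enhancement curve (baseline,
time-to-peak phase, wash-out slope); acquisition noise is additive
Gaussian and a smooth multiplicative bias field (amplitude 0.08) is
applied. Habitat mean/kinetic maps are softened across boundaries with
a 1.5 mm Gaussian — tumor subregions do not have razor-sharp edges, and
hard edges create a strong artifactual "interface voxel" texture class.

Default habitat profiles (all pairs distinct in both intensity and
kinetics):

| habitat | peak mean | texture sd | time-to-peak | wash-out | role |
|---|---|---|---|---|---|
| 1 | 330 | 20 | phase 5 | mild | outcome-linked subregion |
| 2 | 120 | 5  | phase 8 | none (persistent) | nuisance |
| 3 | 500 | 50 | phase 2 | marked | nuisance; fixes the peak phase |

Design rationale, learned the hard way and verified by the recovery
tests:

- **Why blobs, not shells.** At 3 mm working resolution equal-volume
  concentric shells are about one voxel thick, so nearly every voxel's
  window mixes adjacent habitats and the Calinski–Harabasz criterion
  collapses to k = 2 regardless of contrast. Compact Voronoi cells
  keep interiors dominant. Farthest-point seeding makes cell volumes
  near-equal, which also stabilizes the measured peak-enhancement
  phase across patients.
- **Why 3 mm native generation.** Generating at 1 mm and downsampling
  mixes habitat kinetics at interfaces by partial volume; generating at
  the working grid keeps each voxel's enhancement curve pure. The
  resampling operator is still exercised by tests on finer-spacing
  inputs.
- **Why one bright early-washout habitat.** The gray-level and texture
  features are computed on the single peak-enhancement phase chosen
  from the mean time–intensity curve; one habitat must dominate that
  choice or the chosen phase flips between patients and the features
  become cross-patient incommensurable.

**Outcome model.** A per-patient latent severity u ~ N(0,1) scales
habitat 1's texture correlation length by exp(0.4·u) — its texture
burden, i.e. the spatial coarseness of its heterogeneity. ALN pCR is
drawn from P = σ(logit(0.433)·κ + 2.5·u), with κ = √(1+(0.5875·2.5)²)
the logistic-normal correction that keeps the marginal prevalence at
the target 0.433. The effect size 2.5 places the habitat signature's
achievable AUC in the reported 0.8–0.9 range. The other habitats
receive independent per-patient coherence variation (log-sd 0.6) and
mean jitter (sd 10) — biological nuisance that degrades whole-tumor
features. The signal sits in the **middle-intensity** habitat
deliberately: monotone gray-level weightings in whole-tumor GLRLM/GLSZM
features (high-/low-gray-level emphasis) can isolate intensity-extreme
subregions from whole-tumor matrices, but no standard feature isolates
the middle band, so whole-tumor signatures are genuinely diluted — the
mechanism the habitat analysis is supposed to demonstrate.

**Clinical covariates** are drawn conditionally on the outcome from the
published group marginals (ER/PR negativity, Her-2 positivity,
menopausal status, cT/cN categories; Ki-67 and age as truncated
normals matched to the reported medians and quartiles) — the Bayes
inversion of the target marginals at prevalence 0.433. A null variant
(no imaging effect, outcome-independent covariates) supports the
negative-control tests.

**What the generator does not emulate:** pharmacokinetic (Tofts-type)
enhancement, MR physics, inter-phase motion, registration error,
non-ellipsoidal tumor shape, and any real-data relationship between
clinical covariates and imaging phenotype (covariates and imaging are
conditionally independent given the outcome). Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under
controlled, favourable conditions — not clinical performance.

## 3. Study-scale experiments

`habitatmri.experiments` bundles the two multi-seed studies asserted in
the acceptance tests, at sizes chosen to keep a full run at desk scale:

- **Model-selection recovery** — 20 independent 6-patient default
  cohorts (≈16,000 pooled voxels each); the mean-CH argmax is compared
  with the planted count of 3. The standalone results script uses a
  single 40-patient cohort (≈106,000 pooled voxels).
- **Habitat-vs-whole-tumor ordering** — per seed, a 40-patient training
  cohort and an independently generated 40-patient evaluation cohort.
  The pipeline's own 8:2 split remains the default for reports, but a
  20%-of-40 test set measures AUC with sampling noise of roughly ±0.15,
  which would drown the ordering; the independent evaluation cohort
  estimates the same quantity with ±0.07. The habitat carrying the
  signal is identified post hoc as the fitted cluster with the largest
  training overlap with planted habitat 1, mirroring how the
  best-performing habitat was singled out in the source design.

## 4. Numerical conventions and edge cases

- Constant features are dropped from the clustering space (with a
  warning) and take p = 1 in the univariate screen.
- W = 0 clusterings return an infinite CH sentinel.
- Empty predicted-positive/negative sets report PPV/NPV as NaN.
- Zero between-subject variance defines ICC = 0.
- All randomness flows from explicit integer seeds; derived seeds stay
  below 2³¹.
- Degenerate inputs (empty masks, non-positive in-mask intensities for
  the log-domain bias fit, single-class outcomes, oversized tumors)
  raise informative errors rather than propagating NaNs.

## 5. Known limitations

- The habitat label maps are spatially unregularized; voxel-level
  agreement with planted truth is limited by interface voxels whose
  windows genuinely mix habitats. The ≥95% held-out agreement property
  holds under a well-separated two-habitat configuration; under the
  default three-habitat conditions agreement is lower and the clustering
  is validated instead through model-selection recovery.
- The region feature bank implements five families; GLDM and NGTDM are
  not provided.
- The DeLong interval is slightly anti-conservative at moderate n
  (measured coverage ≈92–93% at n = 500), a known property of the
  estimator rather than of this implementation (which matches the
  brute-force structural components exactly).
- LASSO uses squared-error loss on the binary outcome by design; a
  logistic-deviance variant would differ near the path's sparse end.
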
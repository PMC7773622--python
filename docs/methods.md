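# Methods

This note documents the models and procedures trabpipe implements, the
conventions that make its outputs reproducible voxel-for-voxel, the design
choices made where the method description leaves room, and what the synthetic
data can and cannot establish.

## VOI standardization

Clinical CT arrives with heterogeneous resolution, so every trabecular region
is reduced to a fixed physical volume of 16 × 16 × 24 mm resampled onto a
0.8 × 0.8 × 3 mm grid (20 × 20 × 8 voxels).  The chain is HU windowing →
slice selection → in-plane crop → resampling.

* **HU window**: [−150, 600] HU mapped linearly to 8-bit gray; values outside
  clip to 0/255.  The window targets trabecular bone on uncalibrated CT.  The
  linear rescale (rather than clip-only) is assumed; rounding is
  half-away-from-zero.
* **Slice selection**: count = round(depth / thickness), centered on the
  marked slice; even counts take the extra slice below the center (a fixed,
  documented convention — parity is otherwise ambiguous).  Ratios farther
  than 0.25 from an integer trigger a warning.
* **Coordinates**: 0-based (row, col, slice); a voxel center sits at
  (index + 0.5)·spacing.  All mm↔voxel conversions use voxel centers, which
  makes the identity resample exact.
* **Resampling**: bicubic (cubic-spline) in-plane; linear through-plane,
  because the slice axis carries at most 8 samples — too few for meaningful
  cubic support (`through_plane_order=3` switches it).  Crop → concatenate →
  resample ordering is fixed; for separable interpolation the order is
  immaterial.  Output clamps to [0, 255].

## Density features

BV/TV is **apparent**: no density phantom, no HU→mg/cm³ calibration.  Otsu's
threshold is computed per-VOI from the 256-bin histogram (the standard
reading of a histogram-adaptive method); the returned level is the first
*bone* level, ties in the between-class variance break to the lowest cut, and
voxels with value ≥ threshold count as bone.  The GV statistics use SD and
variance with the n−1 denominator and skewness/kurtosis from central moments
with the n denominator (kurtosis non-excess, normal = 3) — the common
statistics-package mix.  Variance is stored raw; report layers print it in
units of 10³ to match how such tables are conventionally scaled (GV SD ≈ 35
alongside GV variance ≈ 1.3).  A constant VOI yields SD 0 and *missing*
skewness/kurtosis, never 0.

## Texture features

Gray values are quantized to 16 levels on **fixed global bins** over [0, 255]
(level = ⌊v·16/256⌋ + 1), not per-VOI min–max, so features are comparable
across VOIs.  Co-occurrences are counted at distance 1 along the 13 unique
directions of the 3D 26-neighborhood (antipodal pairs deduplicated by
lexicographic rule); out-of-bounds pairs are skipped.  Counts are
**symmetrized first, then normalized** per direction — normalizing before
adding the transpose would double the mass.  Nine Haralick descriptors are
computed per direction and averaged over the 13 directions: contrast,
correlation, entropy, difference entropy, difference variance, homogeneity
(inverse difference moment 1/(1+(i−j)²); the 1/(1+|i−j|) dialect is a flag),
maximum probability, sum variance (centered on the mean of the sum
distribution, the corrected form; the sum-entropy-centered 1973 form is a
flag), and IMC — the first information measure of correlation,
(HXY − HXY1)/max(HX, HY), which is non-positive for any joint distribution.
All entropies use the natural logarithm with 0·log 0 ≡ 0.  For a constant
VOI, correlation and IMC are undefined (missing), the rest are computed.

## Femur geometry

NSA is the angle between the neck axis (start point below the greater
trochanter → femoral head center) and the shaft axis, passed
distal-to-proximal so the anatomical obtuse-side angle is returned.  FNALa
and FNALb are Euclidean distances from the same neck-axis start point to the
head anterior point and head center respectively — the reading consistent
with FNALb ≈ 76–78 mm; measuring FNALb from an intermediate point instead
would give values far shorter than printed.  Landmarks arrive as labeled CSV
rows; extracting them from images or meshes is out of scope.

## Group statistics

Per variable and stratum: Shapiro–Wilk per group at α = 0.05 routes to a
pooled-variance Student t test (Welch by flag) when both groups pass, else a
two-sided Mann–Whitney U (scipy's implementation: exact for small untied
samples, tie- and continuity-corrected normal approximation otherwise).  No
multiple-comparison correction is applied, deliberately mirroring the
univariate screening design.  A zero-variance group diverts to the U test
with a warning.  Pearson correlation screening flags |r| > 0.8 (configurable;
"strong multicollinearity" has no canonical cutoff).

## Classifiers

**BLR.**  Features are z-scored; PCA retains the smallest prefix of
descending-eigenvalue components reaching ≥ 98% cumulative variance; the
logistic model places independent Student-t priors on coefficients (df = 1,
scale 2.5 for slopes on the standardized scale, 10 for the intercept — the
defaults of the approach this follows).  The MAP fit uses EM-augmented IRLS:
the t prior is a scale mixture of normals, so each IRLS step adds the
conditional prior precision (df+1)/(df·s² + β²) as a ridge term.
Convergence: max coefficient change < 1e−8, ≤ 100 iterations.  Only the MAP
point and curvature-based uncertainty are produced; full posterior sampling
is out of scope.  Standardization and PCA are fit **inside each training
fold** and applied to the held-out fold — no leakage; reported AUCs may
therefore be slightly more conservative than a leaky variant.

**EN.**  The penalty is λ[(1−α)/2·Σβ² + α·Σ|β|].  Although the penalty is
often written around a least-squares loss, the response here is binary, so
the implementation minimizes penalized **binomial deviance** (1/N·NLL) by an
outer quadratic approximation and inner cyclic coordinate descent with
soft-thresholding — the glmnet scheme (the least-squares loss remains
available for regression responses in principle; it is not used here).
Features are standardized internally (population SD); the intercept is
unpenalized; coefficients are reported on the original scale.  λ = 0
reproduces the unpenalized MLE to < 1e−4; λ large with α = 1 gives the
all-zero model with intercept at the class log-odds.

**Cross-validation.**  Stratified k folds (stratification prevents
empty-class folds at n ≈ 90–200), default 10 folds × 50 repeats, every
random stream derived from one integer seed.  Per repeat, either the pooled
held-out scores give one AUC (default) or the per-fold AUCs are averaged
(`auc_method="per_fold"`, matching the resampling summary of the R caret
machinery this emulates).  The summary is the mean AUC with a percentile 95%
CI over repeat AUCs; an analytic CI is not provided.  AUC itself is the
rank/U-statistic (ties ½), identical to the trapezoidal area of the
threshold-sweep curve.  Grid-search ties break toward larger λ, then larger
α — the sparser model.

## Synthetic data

**What it emulates.**  (a) Two-group trabecular VOIs: seeded white noise
smoothed by an anisotropic Gaussian kernel (correlation lengths in mm) and
pushed through a two-plateau sigmoid whose cut quantile equals 1 − target
BV/TV; plateau levels are solved from the target GV mean/SD of the two-point
mixture.  Density (cut, levels) and texture (correlation length) are
independently controllable, which is exactly what the extractors must
measure.  (b) Femur-geometry tables: per-subject (NSA, FNALa, FNALb) from a
correlated normal model.  Default means are the printed group summaries at
n = 98 (fracture) and 107 (control); SDs are back-derived from the printed
95% CIs as half-width·√n/1.96 (a derivation, not a printed value).  FNALa
group means are not printed anywhere accessible; its defaults (90/88 mm,
SD 7) are a package choice satisfying FNALa > FNALb and are never used by
the headline simulation.  Landmark CSVs can be emitted whose measured
geometry reproduces the drawn triples exactly (constructive inverse).

**What it does not emulate.**  Plate/rod trabecular morphology, anisotropy
tensors, beam-hardening or scanner noise, inter-feature correlation
structure beyond one latent density factor per subject (inter-region
correlation default 0.7), or any biomechanics.  Passing tests demonstrate
that the *pipeline* measures what it claims on fields with known parameters —
not that the features are biologically valid on real CT.

**Calibration knobs.**  Default cohort recipes place group contrasts in the
direction of the printed summaries: lower GV mean and BV/TV and longer
correlation length (lower contrast) on the fracture side, with
between-subject SDs near the printed table SDs (GV mean ≈ 27.5).  The
correlation length carries per-subject lognormal jitter (σ = 0.2); without
it the texture knob would separate the groups almost deterministically, which
no real cohort does.  The
sigmoid sharpness (12) trades plateau purity against smoothness; the
realized GV SD sits ~5–10% below target because smoothing populates the
transition band — BV/TV and GV mean are recovered essentially unbiased
(verified over 50 seeds).

## Problem sizes and Monte-Carlo design

Simulation checks run at sizes chosen to keep results statistically stable:

* The geometry-model simulation reports the mean over 100 independently
  drawn cohorts (each n = 98/107 with its own 10-fold × 10-repeat CV),
  because a single cohort's mean CV AUC carries sampling noise of ~0.04 —
  replicate averaging shrinks it to ~0.004 without touching the estimand.
  Under these conditions the value settles near 0.66; the closed-form
  binormal ceiling for the same parameters is Φ(d/√2) ≈ 0.67.
* The null-cohort diagnostic averages 4 full-pipeline runs at 250 subjects
  per group: cross-validation on a finite null cohort is *pessimistically*
  biased (an O(1/n) effect of sampling without replacement) and a single
  small cohort fluctuates by ±0.04, so small single-cohort checks sit below
  chance more often than not.  At the diagnostic size the measured center is
  ≈ 0.48 with per-cohort SD ≈ 0.033.

## Known limitations

* The EN grid search at the full 34 × 30 grid with 50-repeat CV is
  computationally heavy; grid evaluations default to fewer repeats
  (configurable) and the full design remains available.
* The BLR uncertainty is the curvature at the MAP point, not a posterior.
* Entropy-family texture values depend on the logarithm base; natural log is
  used throughout, which matters when comparing absolute entropies to tables
  computed with log₂.
* The PNG reader expects single-channel 8-bit slices with equal shapes and
  zero-padded names; DICOM ingestion is deliberately out of scope.
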
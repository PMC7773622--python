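# trabpipe

Trabecular bone texture, density and hip-geometry analysis from clinical CT,
with cross-validated discrimination of low-energy acetabular fracture cases
from controls.

Low-energy acetabular fractures in the elderly are usually assessed on
clinical abdominopelvic CT, whose coarse resolution rules out direct
micro-structural measurement.  This package implements the quantitative
alternative: fixed-size trabecular volumes of interest (VOIs) are standardized
to a common voxel grid and summarized by **apparent bone volume fraction**
(BV/TV via Otsu segmentation), **nine 3D gray-level co-occurrence matrix
(GLCM) texture descriptors** averaged over the 13 unique displacement
directions of the 26-neighborhood, and **five first-order gray-value (GV)
histogram statistics** — 15 variables per region.  Proximal femur geometry
(PFG) adds the neck shaft angle (NSA) and two femoral neck axis lengths
(FNALa, FNALb) computed from labeled landmarks.  Group differences use
normality-routed univariate tests (Shapiro–Wilk gating a Student t test vs a
Mann–Whitney U), and two classifiers discriminate fracture from control under
repeated stratified 10-fold cross-validation scored by ROC AUC:

* **Bayesian logistic regression (BLR)** — PCA on z-scored inputs retaining
  components explaining ≥ 98% of variance, then logistic regression with
  independent Student-t priors (Cauchy, scale 2.5) on the coefficients,
  fitted to the MAP point by EM-augmented IRLS.  The prior keeps estimates
  finite under separation and multicollinearity.
* **Elastic net (EN)** — penalized logistic regression minimizing
  `(1/N)·NLL + λ[(1−α)/2·Σβ² + α·Σ|β|]` by cyclic coordinate descent with
  soft-thresholding, with an (α, λ) grid search (α 0.01…1 step 0.03,
  λ 0.001…0.15 step 0.005) by cross-validated AUC.

Because the underlying hospital imaging cannot be redistributed, the package
ships a first-class synthetic-data module: trabecular-like VOIs as thresholded
Gaussian random fields with independently controllable density and texture,
and femur-geometry cohorts parameterized from the study's printed group
summaries.  Every pipeline stage is testable end-to-end without any download.

## Worked example

Generate one synthetic VOI, extract its 15 trabecular features, then build a
geometry cohort from the printed group summaries and cross-validate the
Bayesian logistic model:

```python
from trabpipe import VOIRecipe, gen_voi, density_features, texture_features

voi = gen_voi(VOIRecipe(target_bvtv=0.5, gv_mean=140.0, gv_sd=40.0, seed=7))
print(density_features(voi).as_series().round(3))
# bvtv              0.500      <- Otsu bone fraction, recovers the 0.5 target
# gv_mean         140.205      <- 8-bit gray mean, recovers the 140 target
# gv_sd            37.321
# gv_variance    1392.869      (reports print this /1000, i.e. 1.393)
# gv_skewness      -0.008
# gv_kurtosis       1.094      (non-excess; near 1 for a two-plateau field)

print(texture_features(voi).as_series().round(3))
# contrast                8.148
# correlation             0.261
# entropy                 2.316
# ...
# imc                    -0.109   <- IMC1 is non-positive by construction

from trabpipe.synth import gen_pfg_table, pfg_cohort_recipe
from trabpipe.classify import repeated_kfold, make_blr_fitter

table = gen_pfg_table(**pfg_cohort_recipe(seed=1))   # NSA/FNALb, n=98 vs 107
X = table[["nsa", "fnalb"]].to_numpy()
y = (table["group"] == "fracture").astype(int).to_numpy()
cv = repeated_kfold(X, y, make_blr_fitter(), k=10, repeats=10, seed=1)
print(cv.summary())
# repeated 10-fold CV, 10 repeats: mean AUC 0.630 [0.622-0.637]
```

The held-out AUC of ~0.63 for this single cohort draw says the two geometry
variables alone separate the groups well above chance; averaged over many
cohort draws the value settles near 0.66 (see below).  `CVResult.plot_roc()`
draws the repeat-averaged ROC curve, and the fitted model objects
(`BayesLogit`, `ElasticNetLogit`) expose `params`, `predict` and `summary()`.

An end-to-end run (synthesis → features → group statistics → classification,
with all artifacts written to disk) is one call or one command:

```sh
trabpipe run --config run.yaml
```

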
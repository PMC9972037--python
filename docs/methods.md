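# Methods

`protsig` implements a dual-approach statistical pipeline for circulating-
protein biomarker discovery in patients undergoing surgery for suspected
pancreatic ductal adenocarcinoma (PDAC).  The input is a cohort of patients
sampled before surgery, each with 93 serum markers — 92 immuno-oncology
proteins on the Olink NPX (log2) scale plus CA19-9 — joined to clinical
covariates and right-censored overall survival (OS).  This note describes
the models, the synthetic data that stand in for the clinical cohort, the
numerical choices, and what the tests do and do not establish.

## Data model and comparisons

All markers live on a log2 scale inside the pipeline.  CA19-9 arrives in
U/ml and is transformed to log2(U/ml) on ingest so that penalized-
regression weights are comparable across all 93 channels; the raw value is
retained in the clinical table.  This pooling convention is a design choice
— z-scoring CA19-9 instead would change nothing downstream because every
penalized fit standardizes its inputs anyway.

Seven two-group contrasts form the comparison catalog: resectable vs
unresectable; resectable short-term survivors (death within 1 year) vs
survivors past 1, 3, 4 and 5 years; and below- vs above-median OS within
the unresectable and resectable subgroups (medians computed from each
subgroup's observed OS).  Censoring interacts with survival
dichotomization as follows: a patient censored before the defining
threshold is excluded from the contrast (their class is unknowable), while
a patient who survived past the threshold counts as a long survivor
regardless of later censoring.  OS exactly at a threshold goes to the long
arm; ties at a subgroup median are excluded from the short arm.  These
rules are stated here because no convention is universal; any alternative
only reassigns a handful of boundary patients.

## Differential expression

Each marker is tested per comparison with the routed two-group test: a
Welch t-test when both arms have at least 40 samples (the central-limit
regime; Welch rather than Student because equal variances are not
assumed), otherwise Shapiro–Wilk normality checks on both arms at
alpha = 0.05 and a two-sided Wilcoxon rank-sum test if either fails.  The
Wilcoxon uses the exact null distribution for untied samples of size <= 25
and the normal approximation with continuity correction otherwise.  Fold
changes are ratios of geometric means on the linear scale, i.e.
`2**(mean1 - mean2)` for log2 data.  Benjamini–Hochberg adjustment is
applied across the 93 markers *within* one comparison — one family per
volcano table.  The exploratory PCA runs on centered, unit-scaled markers
(assay scales differ), k = 2 by default.

## Approach 1: stability selection and Ridge evaluation

The cohort is split (stratified by label) into discovery and replication
at a 2/3 discovery fraction — chosen so that after the discovery cohort is
halved again, the training halves remain comparable in size to the
replication cohort; the fraction is configurable.  For each of 500
iterations the discovery cohort is freshly halved (stratified, sizes
within one sample); an L1-penalized logistic model with 10-fold
cross-validated penalty is fitted on the training half.  Each marker's
**proportion score** is the fraction of the 500 models that kept it with a
nonzero coefficient (|w| > 1e-10 on the standardized scale).  Re-drawing
the half-split every iteration is deliberate: with a fixed split the 500
models would differ only through CV fold noise and the proportion scores
would collapse toward 0/1.

Candidate signatures are the marker sets at proportion thresholds 0, 0.05,
…, 1.0; identical sets keep only the highest threshold and empty sets are
dropped, producing a strictly nested family with strictly decreasing
sizes.  Each signature is evaluated with Ridge logistic models (penalty by
10-fold CV deviance): fitted on one seeded half of discovery and scored on
the other, then fitted on all of discovery and scored on replication.
Reported per evaluation: ROC/AUC, the Youden best point (ties broken
toward higher specificity, then the larger cutoff), sensitivity,
specificity, and predictive values at the evaluation-set prevalence, each
with a 95% percentile CI from 2000 class-stratified bootstrap resamples of
the evaluation set (the fitted model is held fixed).

## Approach 2: median-lambda penalized models

Markers are standardized (sample SD, n−1 convention — stated once, used
everywhere).  The penalty for the L1 logistic classifier and the L1 Cox
model is selected by repeating 10-fold cross-validation (fresh folds each
time, default 500 repetitions) over a shared 100-point log-spaced grid
from lambda_max down to `1e-3 * lambda_max`, taking each repetition's
deviance-minimizing lambda, and using the **median** of the repeated
lambdas for a single final fit on all data.  The CV criterion is binomial
deviance for the classifier and the Verweij–Van Houwelingen cross-
validated partial-likelihood deviance for the Cox model.  Only lambda is
pooled across repetitions; the final weights come from one fit, while the
per-repetition weights (read off the full-data path at each repetition's
lambda) are summarized per marker (median, IQR, selection fraction) as a
robustness report.

The OS risk model constrains weights to be non-negative; markers whose
true association is protective are pushed to exactly zero by the one-sided
soft threshold.  Ties in the Cox partial likelihood use the Breslow
approximation (the synthetic survival times are continuous, so ties are
rare).  The prediction score is the linear combination of standardized
marker levels and weights (plus intercept for logistic families); Cox
scores are oriented so higher means higher hazard.

### Solvers

Both penalized fits are solved in-package: a cyclic coordinate-descent
path solver for the logistic LASSO (IRLS outer loop, active-set inner
sweeps, unpenalized intercept, warm starts down the grid, deviance-
saturation early stopping) and the analogous IRLS/coordinate-descent
solver for the Cox partial likelihood with an optional non-negativity
projection.  Convergence is declared when the largest coefficient move in
a sweep falls below `1e-5 * max(1, |coef|_max)`.  The test suite pins both
solvers to independent references on shared instances: scikit-learn's saga
solver (logistic, ~1e-4 along the path), scikit-survival's Coxnet
(penalized Cox, ~5e-4), and lifelines (unpenalized Cox, 1e-6).

## Survival evaluation layer

* **ROC/AUC** — trapezoid over the empirical step curve; equals the
  tie-corrected Mann–Whitney statistic.  Positivity is `score >= cutoff`.
* **Kaplan–Meier / logrank / Cox PH** — via lifelines (Breslow ties);
  covariate encoding: age continuous, stage and ASA as ordinal integers,
  adjuvant chemotherapy dummy-coded against a configurable reference,
  CA19-9 on the log2 scale.  Rows with missing covariates are dropped and
  counted.  Univariate mode loops covariates one at a time.
* **Time-dependent ROC** — the cumulative-case / dynamic-control
  Kaplan–Meier estimator: cases have died by the horizon, controls are
  alive at it; sensitivity and specificity are recovered from the overall
  KM curve and conditional KM curves within score strata.  The AUC
  integrates along the cutoff-ordered path (under censoring the estimated
  curve need not be monotone; signed trapezoids follow the estimator).
  Nearest-neighbor smoothing is not implemented.  Without censoring before
  the horizon the estimator reduces exactly to the static ROC of the
  "event by t" label, and the tests assert that identity.
* **Horizon classification** — predicted-vs-actual survival status at
  6/12/24 months, "positive" meaning predicted alive (score below the
  cutoff for risk scores); patients censored before a horizon are excluded
  at that horizon rather than imputed.
* **Cutpoints** — median split (ties to the low group) and the maximally
  selected logrank statistic over all midpoints of adjacent distinct
  scores between the 10th and 90th score percentiles.  The maxstat
  logrank p is reported *uncorrected* and carries an explicit
  selection-biased flag; a Lausen–Schumacher-type correction is out of
  scope.
* **Per-marker KM screen** — for each of the 93 markers, a median-NPX
  split within a subgroup with logrank p and hazard ratio, flagging
  p < 0.05 unadjusted (a screening display, not an inference).

## Synthetic cohorts

The generator reproduces the structure the methods assume without
attempting to imitate the real panel's empirical correlation matrix:

* 273 patients by default, 193 resectable / 80 unresectable;
* marker levels = baseline + latent factors + Gaussian noise.  Defaults:
  3 latent factors, loadings drawn N(0, 0.5²), noise SD 1.0 NPX —
  off-diagonal correlations average ≈ 0.2, comparable to co-regulated
  inflammatory panels, while leaving most marker pairs weakly coupled;
* informative markers get an additive NPX shift between groups
  (default scenario: 5 markers at 1.0 NPX, about one assay doubling);
* OS is exponential (constant hazard) per group, scaled so the uncensored
  median matches 22.6 months (resectable) and 8.2 months (unresectable)
  when no survival effects are planted; survival effects multiply the
  hazard by `exp(beta * centered NPX)` (default scenario: |beta| = 0.5 per
  NPX unit on 5 markers, one protective).  Exponential rather than Weibull
  because the median then has a closed form for calibration; the
  config leaves room for a shape parameter;
* censoring = administrative horizon at 150 months (mirroring roughly a
  decade of follow-up) plus an independent 8% uniform early-censoring
  mechanism, giving ~10% censoring overall — the observed-event fraction
  of the study population;
* clinical covariates (age, stage, ASA, chemotherapy) are drawn with
  realistic marginals but carry **no** survival effect, so the ground
  truth for marker recovery stays clean.

Because the latent factors couple markers, a planted effect "leaks" into
correlated null markers; tests therefore compare *mean* proportion scores
of informative vs null markers rather than demanding that null markers are
never selected.  Passing tests show the machinery recovers planted
structure under these conditions; they cannot certify performance on real
serum panels, where effect sizes are smaller and correlation is stronger
and block-structured.

## Problem sizes used by the tests and the acceptance script

The study-scale defaults (500 stability iterations, 500 CV repetitions,
100-point penalty grid, 2000 bootstrap replicates) remain the package
defaults and are exercised at full scale by the analysis drivers when
requested.  The automated suite runs the same code at reduced resampling
counts chosen as the package's own desk-scale test sizes: stability
selection at 20–40 iterations with a 20-point grid (the monitored
quantity, a mean over 500-odd models, is unbiased at any iteration count),
median-lambda fits at 10–20 CV repetitions, and a `1e-2` grid floor where
training sets have fewer samples than markers (the standard convention in
that regime).  Type-I calibration uses 200 null cohorts; signal-recovery
checks use 20 master seeds.

## Known limitations

* No LOD/QC handling or missing-NPX imputation: operations receiving
  missing marker values fail loudly, naming the markers.
* The maxstat p-value is selection-biased by construction and flagged, not
  corrected.
* No competing risks, PH diagnostics, or calibration curves.
* The elastic-net mixing parameter is fixed at its endpoints (LASSO for
  selection, Ridge for signature evaluation); intermediate alphas are out
  of scope.
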
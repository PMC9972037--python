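# protsig

Circulating-protein signature discovery and prognostic evaluation for
pre-surgery pancreatic-cancer cohorts.

## The problem

Only a minority of pancreatic ductal adenocarcinoma (PDAC) patients are
eligible for resection, and a substantial fraction of those taken to
surgery turn out to have unresectable disease on the table.  A blood-based
marker panel that flags unresectable disease — or stratifies prognosis
before surgery — would directly change treatment decisions.  `protsig`
implements, as a tested and reusable pipeline, the statistical machinery
for hunting such panels in a samples × 93 marker table (92 immuno-oncology
proteins measured on the Olink NPX log2 scale plus CA19-9 in U/ml) joined
to clinical covariates and right-censored overall survival.

Two complementary approaches are implemented end to end:

1. **Stability selection + Ridge evaluation.**  The cohort is split into
   discovery and replication; the discovery cohort is repeatedly halved
   (500×) and an L1 logistic model with 10-fold cross-validated penalty is
   fitted on each training half.  Each marker's *proportion score* is the
   fraction of models that kept it.  Thresholding the scores at 0, 0.05,
   …, 1.0 (deduplicated) yields a nested family of candidate signatures,
   each evaluated by Ridge logistic models with ROC/AUC, Youden best
   points, and 2000-replicate stratified bootstrap CIs.
2. **Median-lambda penalized models.**  After standardization, an L1
   logistic classifier (resectable vs unresectable) and a non-negative L1
   Cox model for overall survival are fitted with the penalty chosen as
   the median of 500 repeated 10-fold cross-validations
   (`argmin` deviance per repetition).  Risk scores — linear combinations
   `sum_m w_m z_m` of standardized marker levels — feed a survival
   evaluation layer: Kaplan–Meier splits at the median and at the
   maximally selected logrank cutpoint, time-dependent ROC at 6/12/24
   months, horizon confusion tables, and uni-/multivariate Cox
   proportional-hazards models with the clinical covariates.

Because the underlying clinical cohort is not publicly deposited, the
package ships a synthetic-cohort generator that reproduces the data's
statistical structure (correlated log2 markers, group mean shifts,
proportional-hazards survival calibrated to median OS 22.6 / 8.2 months,
right-censoring) with exported ground truth, so every stage is testable.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_stability_signatures.py --seed 1
python analysis/04_penalized_models.py --seed 1
python analysis/05_survival_evaluation.py
```

prints, among other lines:

```
cohort: 273 samples, 93 markers
  resectable:   193 (median OS 25.8 mo)
  unresectable:  80 (median OS 9.8 mo)
resectable_vs_unresectable (n=80+193): 6 raw / 5 BH significant; top: P001, P004, P003
top proportion scores:
P001    1.00
P002    1.00
P003    1.00
P004    1.00
P005    1.00
P018    0.56
9 nested sets; best replication AUC 0.914 [0.847, 0.966] with 6 markers (threshold 0.55)
non-negative L1 Cox: lambda = 0.05848, 23 markers with positive weight: P001, P002, P003, P006, ...
median cutoff -0.041: HR 4.27 [3.24, 5.63], logrank p 9.5e-28
maxstat cutoff +0.218: HR 5.60 [4.16, 7.54], logrank p 5.2e-35 (selection-biased p)
time-dependent AUC: 6mo 0.820, 12mo 0.855, 24mo 0.875
```

Reading this: the generator planted a 1.0-NPX resectability shift on
markers P001–P005 and survival effects on P006–P010.  Differential
expression finds exactly the five planted markers after BH correction; the
proportion scores rank them at 1.0, far above every null marker; the best
nested signature replicates at AUC 0.91; and the non-negative Cox risk
score separates survival strongly at both cutpoints (the maxstat p is
flagged because the cutoff was chosen to maximize that very statistic).
Plot-ready tables (volcano, KM step curves, td-ROC grids, Cox summaries)
are written under `results/`.

The same stages are available as a CLI for file-based workflows:

```bash
protsig --seed 7 --out-dir run simulate
protsig --out-dir run de --comparison resectable_vs_unresectable
protsig --out-dir run stability --comparison resectable_vs_unresectable
protsig --out-dir run fit --family cox --nonneg
protsig --out-dir run survival-eval --scores run/scores_cox_all_nonneg.csv --cutoff maxstat
```

Running a chain twice with one seed reproduces every output byte for byte.

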
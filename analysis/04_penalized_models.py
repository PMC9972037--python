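#!/usr/bin/env python
"""Approach 2: median-lambda penalized classifiers and Cox risk models.

Fits (i) the L1 logistic classifier separating resectable from unresectable
tumors and (ii) the non-negative L1 Cox model predicting overall survival
for all patients, each with the penalty chosen as the median of repeated
10-fold cross-validations.  Weight tables (published-style layout), the
per-repetition weight-robustness summary, and per-sample prediction scores
go to results/models/.

The study default repeats the CV 500 times (--repeats 500); the default
here is a lighter 50.
"""

import argparse
from pathlib import Path

import protsig as ps


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--repeats", type=int, default=50)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/models"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = ps.PipelineConfig(seed=args.seed, n_lambda_repeats=args.repeats,
                            n_lambda=30, lambda_min_ratio=1e-2)
    cohort = ps.read_cohort(args.cohort_dir / "markers.csv",
                            args.cohort_dir / "clinical.csv")
    spec = ps.get_comparison(cohort, "resectable_vs_unresectable")
    X, y = ps.extract_design(cohort, spec)

    logistic = ps.fit_median_lambda_logistic(X, y, cfg)
    logistic.weights_table().to_csv(args.out_dir / "logistic_weights.csv",
                                    index=False)
    logistic.weight_distribution.to_csv(
        args.out_dir / "logistic_weight_distribution.csv")
    ps.predict_score(logistic, X).to_csv(args.out_dir / "logistic_scores.csv")
    print(f"L1 logistic: lambda = {logistic.lambda_selected:.4g} "
          f"(median of {args.repeats} CV repeats), "
          f"{len(logistic.nonzero_markers)} markers kept: "
          f"{', '.join(logistic.nonzero_markers[:8])}"
          f"{' ...' if len(logistic.nonzero_markers) > 8 else ''}")

    clin = cohort.clinical
    cox = ps.fit_median_lambda_cox(cohort.npx, clin.os_months.to_numpy(),
                                   clin.event.to_numpy(), nonneg=True,
                                   cfg=cfg)
    cox.weights_table().to_csv(args.out_dir / "cox_weights.csv", index=False)
    cox.weight_distribution.to_csv(
        args.out_dir / "cox_weight_distribution.csv")
    ps.predict_score(cox, cohort.npx).to_csv(
        args.out_dir / "cox_risk_scores.csv")
    print(f"non-negative L1 Cox: lambda = {cox.lambda_selected:.4g}, "
          f"{len(cox.nonzero_markers)} markers with positive weight: "
          f"{', '.join(cox.nonzero_markers[:8])}"
          f"{' ...' if len(cox.nonzero_markers) > 8 else ''}")


if __name__ == "__main__":
    main()
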
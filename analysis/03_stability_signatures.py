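#!/usr/bin/env python
"""Approach 1: stability-selected signatures with Ridge evaluation.

Splits the cohort into discovery and replication, runs the resampled
logistic-LASSO stability selection on the resectable-vs-unresectable
contrast, builds the nested proportion-score signature sets, and evaluates
each with Ridge models (discovery half -> other half, discovery ->
replication) including Youden best points and stratified bootstrap CIs.
Tables land in results/stability/.

The resampling count is configurable; the study default is 500 iterations
(--iterations 500), which takes a few minutes at the full cohort size.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import protsig as ps
from protsig.stability_signature import evaluations_to_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--iterations", type=int, default=100)
    ap.add_argument("--comparison", default="resectable_vs_unresectable")
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/stability"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = ps.PipelineConfig(seed=args.seed, n_stability_iter=args.iterations,
                            n_lambda=30, lambda_min_ratio=1e-2)
    cohort = ps.read_cohort(args.cohort_dir / "markers.csv",
                            args.cohort_dir / "clinical.csv")
    spec = ps.get_comparison(cohort, args.comparison)
    X, y = ps.extract_design(cohort, spec)
    plan = ps.make_split_plan(pd.Series(y, index=X.index), cfg)
    print(f"{args.comparison}: discovery {len(plan.discovery_ids)}, "
          f"replication {len(plan.replication_ids)}, "
          f"{args.iterations} resampled LASSO fits")

    prop = ps.run_stability(X, y, plan, cfg)
    prop.to_frame().to_csv(args.out_dir / "proportion_scores.csv")
    print("top proportion scores:")
    print(prop.proportions.nlargest(8).to_string())

    sets = ps.build_signature_sets(prop, cfg.proportion_step)
    with open(args.out_dir / "signature_sets.json", "w") as fh:
        json.dump([{"threshold": s.threshold, "markers": s.markers}
                   for s in sets], fh, indent=2)
    evals = []
    for s in sets:
        try:
            evals.extend(ps.evaluate_signature(s, X, y, plan, cfg))
        except ValueError as exc:
            print(f"  threshold {s.threshold:.2f} skipped: {exc}")
    frame = evaluations_to_frame(evals)
    frame.to_csv(args.out_dir / "signature_evaluations.csv", index=False)
    best = frame[frame.cohort == "replication"].nlargest(1, "auc").iloc[0]
    print(f"{len(sets)} nested sets; best replication AUC "
          f"{best.auc:.3f} [{best.auc_lo:.3f}, {best.auc_hi:.3f}] "
          f"with {best.n_markers} markers (threshold {best.threshold:.2f})")


if __name__ == "__main__":
    main()
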
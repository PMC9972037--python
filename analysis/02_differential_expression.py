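#!/usr/bin/env python
"""Per-marker differential expression across the seven catalog comparisons.

For every comparison (resectable vs unresectable and the survival-threshold
contrasts) each of the 93 markers is tested with the routed two-group test
(Welch t when both arms have >= 40 samples, otherwise Shapiro-checked
Wilcoxon), fold changes are computed on the linear scale, and p-values are
BH-adjusted within the comparison.  Volcano-ready tables and a principal
component overview go to results/de/.
"""

import argparse
from pathlib import Path

import pandas as pd

import protsig as ps


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/de"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = ps.read_cohort(args.cohort_dir / "markers.csv",
                            args.cohort_dir / "clinical.csv")
    for spec in ps.build_comparison_catalog(cohort):
        if not spec.usable:
            print(f"{spec.name}: skipped ({spec.note})")
            continue
        results, volcano = ps.run_comparison(cohort, spec)
        volcano.to_csv(args.out_dir / f"volcano_{spec.name}.csv", index=False)
        n_raw = int(volcano.significant_raw.sum())
        n_adj = int(volcano.significant_adjusted.sum())
        top = volcano.nsmallest(3, "p_raw")
        print(f"{spec.name} (n={len(spec.group1_ids)}+{len(spec.group2_ids)}): "
              f"{n_raw} raw / {n_adj} BH significant; "
              f"top: {', '.join(top.marker)}")

    scores, ev = ps.pca_scores(cohort, k=2)
    scores["group"] = pd.Categorical.from_codes(
        cohort.clinical.resectable.astype(int), ["unresectable", "resectable"])
    scores.to_csv(args.out_dir / "pca_scores.csv")
    print(f"PCA: PC1 {ev[0]:.1%}, PC2 {ev[1]:.1%} of variance "
          f"-> results/de/pca_scores.csv")


if __name__ == "__main__":
    main()
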
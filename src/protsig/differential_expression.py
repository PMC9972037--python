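"""Per-marker two-group differential expression and exploratory PCA.

Test routing follows the study's rule: a Welch t-test for independent
samples when both groups have at least 40 samples (central limit theorem);
otherwise each group is checked for normality with Shapiro-Wilk and a
two-sided Wilcoxon rank-sum test is used if either group departs from
normality at the 0.05 level.  Fold changes are reported on the linear scale
as the ratio of the groups' geometric means, which for log2 data is
``2**(mean1 - mean2)``.  P-values are Benjamini-Hochberg adjusted across the
93 markers within one comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortTable, ComparisonSpec, extract_design

CLT_MIN_N = 40


@dataclass
class DEResult:
    marker: str
    test_used: str            # "t" or "wilcoxon"
    p_raw: float
    p_adjusted: float
    fold_change_linear: float
    mean1_log2: float
    mean2_log2: float
    n1: int
    n2: int


def choose_test(values1: np.ndarray, values2: np.ndarray,
                alpha_normality: float = 0.05) -> str:
    """Route to 't' or 'wilcoxon' per the <40-samples normality rule."""
    v1 = np.asarray(values1, float)
    v2 = np.asarray(values2, float)
    if len(v1) < 3 or len(v2) < 3:
        raise ValueError("each group needs >= 3 samples (Shapiro undefined)")
    if len(v1) >= CLT_MIN_N and len(v2) >= CLT_MIN_N:
        return "t"
    for v in (v1, v2):
        if np.ptp(v) == 0:
            # Shapiro is undefined on a constant sample; clearly non-normal
            return "wilcoxon"
        if stats.shapiro(v).pvalue < alpha_normality:
            return "wilcoxon"
    return "t"


def _wilcoxon_p(v1: np.ndarray, v2: np.ndarray) -> float:
    # exact null distribution for small untied samples, normal approximation
    # with continuity correction otherwise
    has_ties = len(np.unique(np.r_[v1, v2])) < len(v1) + len(v2)
    method = "exact" if (len(v1) <= 25 and len(v2) <= 25 and not has_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(v1, v2, alternative="two-sided",
                                    method=method).pvalue)


def compare_marker(values1: np.ndarray, values2: np.ndarray,
                   alpha_normality: float = 0.05) -> tuple[float, float, str]:
    """Two-sided p-value and linear-scale fold change for one marker.

    Fold change = geometric mean of group 1 over geometric mean of group 2
    on the linear scale, i.e. ``2**(mean1 - mean2)`` for log2 input.
    Returns ``(p_raw, fold_change_linear, test_used)``.
    """
    v1 = np.asarray(values1, float)
    v2 = np.asarray(values2, float)
    test = choose_test(v1, v2, alpha_normality)
    fold = float(np.exp2(v1.mean() - v2.mean()))
    if np.ptp(v1) == 0 and np.ptp(v2) == 0:
        p = 1.0 if v1.mean() == v2.mean() else 0.0
        return p, fold, test
    if test == "t":
        p = float(stats.ttest_ind(v1, v2, equal_var=False).pvalue)
    else:
        p = _wilcoxon_p(v1, v2)
    return p, fold, test


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_comparison(cohort: CohortTable, spec: ComparisonSpec,
                   alpha: float = 0.05
                   ) -> tuple[list[DEResult], pd.DataFrame]:
    """All markers tested in one comparison, plus a volcano-plot table.

    Group 1 is the comparison's positive arm.  BH adjustment is applied
    across the markers of this comparison only (one family per volcano).
    """
    X, y = extract_design(cohort, spec)
    results: list[DEResult] = []
    for marker in X.columns:
        v1 = X.loc[y == 1, marker].to_numpy()
        v2 = X.loc[y == 0, marker].to_numpy()
        try:
            p, fold, test = compare_marker(v1, v2)
        except ValueError as exc:
            raise ValueError(f"marker {marker!r}: {exc}") from exc
        results.append(DEResult(marker, test, p, np.nan, fold,
                                float(v1.mean()), float(v2.mean()),
                                len(v1), len(v2)))
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adjusted):
        r.p_adjusted = float(pa)

    volcano = pd.DataFrame(
        {
            "marker": [r.marker for r in results],
            "log2_fold_change": [np.log2(r.fold_change_linear) for r in results],
            "neg_log10_p": [-np.log10(max(r.p_raw, 1e-300)) for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "test_used": [r.test_used for r in results],
            "significant_raw": [r.p_raw < alpha for r in results],
            "significant_adjusted": [r.p_adjusted < alpha for r in results],
        }
    )
    return results, volcano


def pca_scores(cohort: CohortTable, k: int = 2, scale: bool = True
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first k principal components of the marker matrix.

    Markers are centered and, by default, unit-scaled (NPX baselines differ
    per assay).  Returns the score table and explained-variance fractions.
    """
    cohort.require_complete()
    X = cohort.npx.to_numpy(float)
    if k > min(X.shape):
        raise ValueError("k exceeds min(n_samples, n_markers)")
    sd = X.std(axis=0, ddof=1)
    if scale:
        const = np.asarray(cohort.markers)[sd == 0]
        if len(const):
            raise ValueError(f"constant markers cannot be scaled: {const.tolist()}")
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    table = pd.DataFrame(scores, index=cohort.sample_ids,
                         columns=[f"PC{i+1}" for i in range(k)])
    return table, pca.explained_variance_ratio_
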
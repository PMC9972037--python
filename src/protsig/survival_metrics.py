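"""Evaluation layer: ROC/Youden with bootstrap CIs, Kaplan-Meier, logrank,
Cox proportional hazards, time-dependent ROC, horizon classification and
risk-score cutpoints.

Conventions used throughout:

* ROC positivity means ``score >= cutoff`` unless a model declares the
  opposite orientation; AUC is the trapezoid over the empirical step curve
  and equals the tie-corrected Mann-Whitney statistic.
* Youden's best point maximizes sensitivity + specificity - 1; ties are
  broken toward higher specificity and then toward the larger cutoff.
* Confidence intervals are percentile intervals over stratified bootstrap
  resamples of the evaluation set (the fitted model is held fixed).
* The time-dependent ROC uses the cumulative-case / dynamic-control
  Kaplan-Meier estimator: with horizon t, cases have died by t and controls
  are still alive at t, with censoring handled through conditional KM
  curves inside the score strata.
* The "best cutoff" is the maximally selected logrank statistic over
  candidate cutpoints between the 10th and 90th score percentiles; its
  naive logrank p-value is flagged as selection-biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort_io import CohortTable

# ---------------------------------------------------------------------------
# ROC / Youden / bootstrap
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    cutoffs: np.ndarray      # decreasing; positivity is score >= cutoff
    fpr: np.ndarray          # 1 - specificity, non-decreasing
    tpr: np.ndarray          # sensitivity, non-decreasing
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Empirical ROC step curve and its trapezoid AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # collapse tied scores to single curve points
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    cutoffs = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(cutoffs, fpr, tpr, auc)


@dataclass
class BestPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float


def youden_best_point(roc: ROCResult, prevalence: float | None = None,
                      n_pos: int | None = None, n_neg: int | None = None
                      ) -> BestPoint:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties are broken by higher specificity, then by the larger cutoff value.
    PPV/NPV are computed at the evaluation-set prevalence (supply either
    ``prevalence`` or the class counts); they are NaN when undefined.
    """
    j = roc.tpr - roc.fpr
    best = 0
    for i in range(1, len(j)):
        if (j[i] > j[best] + 1e-12
                or (abs(j[i] - j[best]) <= 1e-12
                    and (roc.fpr[i] < roc.fpr[best] - 1e-12
                         or (abs(roc.fpr[i] - roc.fpr[best]) <= 1e-12
                             and roc.cutoffs[i] > roc.cutoffs[best])))):
            best = i
    sens, spec = float(roc.tpr[best]), float(1.0 - roc.fpr[best])
    if prevalence is None and n_pos is not None and n_neg is not None:
        prevalence = n_pos / (n_pos + n_neg)
    ppv = npv = float("nan")
    if prevalence is not None:
        tp = sens * prevalence
        fp = (1 - spec) * (1 - prevalence)
        tn = spec * (1 - prevalence)
        fn = (1 - sens) * prevalence
        ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
        npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    return BestPoint(float(roc.cutoffs[best]), sens, spec, ppv, npv,
                     float(j[best]))


def bootstrap_ci(metric, scores: np.ndarray, labels: np.ndarray,
                 n: int = 2000, stratified: bool = True,
                 seed: int | np.random.Generator = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile CI of ``metric(scores, labels)`` over bootstrap replicates.

    Stratified resampling redraws each class separately, so every replicate
    retains both classes.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    values = np.empty(n)
    for b in range(n):
        if stratified:
            take = np.r_[rng.choice(idx_pos, len(idx_pos)),
                         rng.choice(idx_neg, len(idx_neg))]
        else:
            take = rng.choice(len(labels), len(labels))
        values[b] = metric(scores[take], labels[take])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Kaplan-Meier / logrank / Cox PH
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    times: np.ndarray          # event-time grid (observed event times)
    survival: np.ndarray       # S(t) just after each grid time
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit estimator with right-censoring (via lifelines)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if len(times) == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter().fit(times, events)
    event_t = np.unique(times[events == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0])
                     for t in event_t])
    # number at risk just before each event time
    at_risk = np.array([(times >= t).sum() for t in event_t])
    return KMCurve(event_t, surv, at_risk, np.unique(times[events == 0]))


def logrank_test(times: np.ndarray, events: np.ndarray,
                 group: np.ndarray) -> tuple[float, float]:
    """Two-group logrank chi-square (1 df) and its p-value."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    m = group == levels[0]
    res = _ll_logrank(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


def _encode_covariates(cov: pd.DataFrame,
                       chemo_reference: str = "none") -> pd.DataFrame:
    """Study covariate encoding: age continuous, stage and ASA ordinal,
    adjuvant chemotherapy dummy-coded against a reference level, CA19-9 on
    the log2 scale."""
    out = pd.DataFrame(index=cov.index)
    for col in cov.columns:
        if col == "adjuvant_chemo":
            dummies = pd.get_dummies(cov[col].astype(str), prefix="chemo",
                                     dtype=float)
            ref = f"chemo_{chemo_reference}"
            out = out.join(dummies.drop(columns=[ref], errors="ignore"))
        elif col == "ca199_uml":
            out["log2_ca199"] = np.log2(cov[col].astype(float))
        else:
            out[col] = pd.to_numeric(cov[col])
    return out


def cox_ph(times: np.ndarray, events: np.ndarray, covariates: pd.DataFrame,
           multivariate: bool = True,
           chemo_reference: str = "none") -> pd.DataFrame:
    """(Multi/uni)variate Cox PH fits: HR, Wald 95% CI and p per covariate.

    Rows with missing covariates are dropped and counted in the
    ``n_dropped_missing`` attribute of the returned frame.
    """
    times = pd.Series(np.asarray(times, float), index=covariates.index)
    events = pd.Series(np.asarray(events, int), index=covariates.index)
    if events.sum() < 10:
        raise ValueError("need >= 10 observed events")
    enc = _encode_covariates(covariates, chemo_reference)
    const = [c for c in enc.columns if enc[c].nunique(dropna=True) <= 1]
    if const:
        raise ValueError(f"zero-variance covariates: {const}")
    full = enc.assign(_time=times, _event=events)
    n_before = len(full)
    full = full.dropna()
    dropped = n_before - len(full)

    def _fit(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        cph.fit(full[cols + ["_time", "_event"]], "_time", "_event")
        summ = cph.summary
        return pd.DataFrame({
            "covariate": summ.index,
            "hr": np.exp(summ["coef"]),
            "hr_lower": np.exp(summ["coef lower 95%"]),
            "hr_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }).reset_index(drop=True)

    if multivariate:
        res = _fit(list(enc.columns))
        res.insert(0, "model", "multivariate")
    else:
        parts = []
        for col in enc.columns:
            part = _fit([col])
            part.insert(0, "model", "univariate")
            parts.append(part)
        res = pd.concat(parts, ignore_index=True)
    res.attrs["n_dropped_missing"] = dropped
    return res


# ---------------------------------------------------------------------------
# time-dependent ROC (cumulative/dynamic, KM estimator)
# ---------------------------------------------------------------------------


@dataclass
class TDROCResult:
    horizon: float
    auc: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    estimator: str = "km_cumulative_dynamic"


def _km_surv_scalar(times: np.ndarray, events: np.ndarray, t: float) -> float:
    """S(t) of the plain product-limit estimator, numpy-only for speed."""
    order = np.argsort(times, kind="stable")
    ts, ev = times[order], events[order]
    n = len(ts)
    surv = 1.0
    i = 0
    while i < n and ts[i] <= t:
        j = i
        d = 0
        while j < n and ts[j] == ts[i]:
            d += ev[j]
            j += 1
        if d:
            surv *= 1.0 - d / (n - i)
        i = j
    return surv


def time_dependent_roc(scores: np.ndarray, times: np.ndarray,
                       events: np.ndarray, horizon_t: float) -> TDROCResult:
    """Cumulative-case / dynamic-control ROC at one horizon.

    sensitivity(c) = P(score > c | death by t) and specificity(c) =
    P(score <= c | alive at t), both estimated from the overall KM curve
    and the conditional KM within the ``score > c`` stratum (the Bayes
    inversion used by the classical KM-based estimator).
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    died_by_t = (times <= horizon_t) & (events == 1)
    alive_at_t = times > horizon_t
    if not died_by_t.any():
        raise ValueError(f"no cases (deaths) by t={horizon_t}")
    if not alive_at_t.any():
        raise ValueError(f"no controls (alive) at t={horizon_t}")

    s_all = _km_surv_scalar(times, events, horizon_t)
    # cutoffs in decreasing order; the path runs from (0,0) (nobody
    # positive) to (1,1) (everybody positive, virtual cutoff -inf)
    cuts = np.r_[np.unique(scores)[::-1], -np.inf]
    sens = np.empty(len(cuts))
    spec = np.empty(len(cuts))
    for i, c in enumerate(cuts):
        above = scores > c
        p_above = above.mean()
        if p_above == 0.0:
            s_above = 1.0
        else:
            s_above = _km_surv_scalar(times[above], events[above], horizon_t)
        num_sens = (1.0 - s_above) * p_above
        num_spec = s_above * p_above
        sens[i] = num_sens / (1.0 - s_all) if s_all < 1.0 else 0.0
        spec[i] = 1.0 - (num_spec / s_all if s_all > 0.0 else 0.0)
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    fpr = 1.0 - spec
    # integrate along the cutoff-ordered path (fpr need not be strictly
    # monotone under censoring; signed trapezoids follow the estimator)
    auc = float(np.trapezoid(np.r_[0.0, sens], np.r_[0.0, fpr]))
    return TDROCResult(float(horizon_t), auc, cuts, sens, spec)


def td_auc_grid(scores, times, events,
                horizons: tuple[float, ...]) -> pd.DataFrame:
    rows = []
    for t in horizons:
        try:
            res = time_dependent_roc(scores, times, events, t)
            rows.append((t, res.auc, ""))
        except ValueError as exc:
            rows.append((t, np.nan, str(exc)))
    return pd.DataFrame(rows, columns=["horizon_months", "auc", "note"])


# ---------------------------------------------------------------------------
# horizon classification
# ---------------------------------------------------------------------------


def horizon_classification(scores: np.ndarray, times: np.ndarray,
                           events: np.ndarray,
                           cutoff: float,
                           horizons: tuple[float, ...] = (6.0, 12.0, 24.0),
                           risk_oriented: bool = True) -> pd.DataFrame:
    """Confusion tables of predicted-vs-actual survival status per horizon.

    "Positive" means predicted alive — a score *below* the cutoff for
    risk-oriented scores.  Samples censored before a horizon are excluded
    at that horizon; a horizon with no evaluable samples is skipped.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    pred_alive = scores < cutoff if risk_oriented else scores >= cutoff
    rows = []
    for t in horizons:
        evaluable = (times > t) | (events == 1)
        if not evaluable.any():
            continue
        alive = times[evaluable] > t
        pred = pred_alive[evaluable]
        tp = int((pred & alive).sum())
        fp = int((pred & ~alive).sum())
        tn = int((~pred & ~alive).sum())
        fn = int((~pred & alive).sum())
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows.append((t, int(evaluable.sum()), tp, fp, tn, fn, sens, spec))
    return pd.DataFrame(rows, columns=["horizon_months", "n_evaluable",
                                       "tp", "fp", "tn", "fn",
                                       "sensitivity", "specificity"])


# ---------------------------------------------------------------------------
# cutpoints
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    method: str               # "median" or "maxstat"
    cutoff: float
    statistic: float          # standardized logrank z at the cutoff
    n_low: int
    n_high: int
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    p_selection_biased: bool = field(default=False)


def _logrank_z(times: np.ndarray, events: np.ndarray,
               high: np.ndarray) -> float:
    """Standardized logrank statistic (O-E)/sqrt(V) for the 'high' group,
    hypergeometric variance, computed in one pass over event times."""
    order = np.argsort(times, kind="stable")
    ts, ev, hi = times[order], events[order], high[order]
    n = len(ts)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    n_at = n
    n1_at = int(hi.sum())
    while i < n:
        j = i
        d = 0
        d1 = 0
        removed1 = 0
        while j < n and ts[j] == ts[i]:
            d += ev[j]
            d1 += int(ev[j] and hi[j])
            removed1 += int(hi[j])
            j += 1
        if d and n_at > 1:
            e1 = d * n1_at / n_at
            v1 = (d * (n1_at / n_at) * (1 - n1_at / n_at)
                  * (n_at - d) / (n_at - 1))
            o_minus_e += d1 - e1
            var += v1
        n_at -= j - i
        n1_at -= removed1
        i = j
    return o_minus_e / np.sqrt(var) if var > 0 else 0.0


def _cutpoint_summary(method: str, times, events, scores, cutoff,
                      biased: bool) -> CutpointResult:
    high = scores > cutoff
    z = _logrank_z(times, events, high)
    _, p = logrank_test(times, events, high.astype(int))
    df = pd.DataFrame({"high": high.astype(float), "_t": times, "_e": events})
    cph = CoxPHFitter().fit(df, "_t", "_e")
    coef = float(cph.summary.loc["high", "coef"])
    lo = float(cph.summary.loc["high", "coef lower 95%"])
    hi_ = float(cph.summary.loc["high", "coef upper 95%"])
    return CutpointResult(method, float(cutoff), float(z),
                          int((~high).sum()), int(high.sum()), p,
                          float(np.exp(coef)),
                          (float(np.exp(lo)), float(np.exp(hi_))), biased)


def median_cutpoint(scores: np.ndarray, times: np.ndarray,
                    events: np.ndarray) -> CutpointResult:
    """Median risk-score split; ties at the median go to the low group."""
    scores = np.asarray(scores, float)
    return _cutpoint_summary("median", np.asarray(times, float),
                             np.asarray(events, int), scores,
                             float(np.median(scores)), biased=False)


def best_cutpoint_maxstat(scores: np.ndarray, times: np.ndarray,
                          events: np.ndarray,
                          bounds: tuple[float, float] = (0.1, 0.9)
                          ) -> CutpointResult:
    """Maximally selected logrank cutpoint within score-quantile bounds.

    Every midpoint of adjacent distinct scores inside the bounds is scanned
    and the cutoff maximizing |standardized logrank| is returned.  The
    reported logrank p is the naive one and is flagged selection-biased (no
    Lausen-Schumacher correction is applied).
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    lo, hi = np.quantile(scores, bounds)
    inside = (scores >= lo) & (scores <= hi)
    if inside.sum() < 10:
        raise ValueError("fewer than 10 samples between the quantile bounds")
    distinct = np.unique(scores[inside])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    if len(candidates) < 2:
        raise ValueError("fewer than 2 candidate cutoffs")
    zs = np.array([abs(_logrank_z(times, events, scores > c))
                   for c in candidates])
    best = candidates[int(np.argmax(zs))]
    res = _cutpoint_summary("maxstat", times, events, scores, best,
                            biased=True)
    return res


# ---------------------------------------------------------------------------
# per-marker KM screen
# ---------------------------------------------------------------------------


def per_marker_km_screen(cohort: CohortTable,
                         subgroup: np.ndarray | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Median-NPX split per marker with logrank p and HR, within a subgroup.

    Ties at the median are assigned to the low (< median) group and the
    marker is flagged when they exceed half the subgroup.
    """
    sub = cohort if subgroup is None else \
        cohort.subset(cohort.sample_ids[np.asarray(subgroup, bool)])
    if sub.n_samples < 10:
        raise ValueError("subgroup must have >= 10 samples")
    times = sub.clinical["os_months"].to_numpy(float)
    events = sub.clinical["event"].to_numpy(int)
    rows = []
    for marker in sub.markers:
        v = sub.npx[marker].to_numpy(float)
        med = float(np.median(v))
        high = v > med  # ties go low
        tie_heavy = (v == med).mean() > 0.5
        if high.sum() == 0 or (~high).sum() == 0:
            rows.append((marker, med, np.nan, np.nan, False, True))
            continue
        _, p = logrank_test(times, events, high.astype(int))
        df = pd.DataFrame({"high": high.astype(float), "_t": times,
                           "_e": events})
        cph = CoxPHFitter().fit(df, "_t", "_e")
        hr = float(np.exp(cph.summary.loc["high", "coef"]))
        rows.append((marker, med, p, hr, p < alpha, tie_heavy))
    return pd.DataFrame(rows, columns=["marker", "median_npx", "logrank_p",
                                       "hr_high_vs_low", "flagged",
                                       "tie_warning"])
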
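"""Stability selection of marker signatures via resampled logistic LASSO.

Approach 1 of the pipeline, in two steps.  Step one: the cohort is split
into discovery and replication parts; the discovery part is repeatedly
(default 500 times) halved into a training and a test set, a logistic LASSO
with 10-fold cross-validated penalty is fitted on each training half, and
every marker's *proportion score* is the fraction of the resampled models
that kept it with a nonzero coefficient.  Step two: candidate signatures
are the nested marker sets obtained by thresholding the proportion scores
at 0, 0.05, ..., 1.0 (duplicate sets keep only the highest threshold);
each signature is evaluated with a Ridge logistic model — fitted on one
half of discovery and scored on the other, then fitted on all of discovery
and scored on replication — reporting AUC, the Youden best point,
sensitivity/specificity/PPV/NPV, and 2000-replicate stratified bootstrap
95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _solvers
from .cohort_io import PipelineConfig
from .penalized_models import (NONZERO_TOL, cv_lambda_logistic,
                               fit_ridge_logistic_cv, lambda_grid,
                               predict_score, standardize)
from .survival_metrics import bootstrap_ci, roc_auc, youden_best_point

# ---------------------------------------------------------------------------
# split plan
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Frozen discovery/replication split plus the per-iteration halves."""

    seed: int
    discovery_ids: list
    replication_ids: list
    half_splits: list  # list of (train_ids, test_ids) partitioning discovery

    def __post_init__(self) -> None:
        if set(self.discovery_ids) & set(self.replication_ids):
            raise ValueError("discovery and replication overlap")
        disc = set(self.discovery_ids)
        for tr, te in self.half_splits:
            if set(tr) | set(te) != disc or set(tr) & set(te):
                raise ValueError("half split does not partition discovery")
            if abs(len(tr) - len(te)) > 1:
                raise ValueError("halves differ by more than one sample")


def _stratified_take(ids_by_class: dict, fractions: dict,
                     rng: np.random.Generator) -> tuple[list, list]:
    # cascade rounding keeps the overall first-part size within one sample
    # of the target even when several classes have fractional shares
    first, second = [], []
    carry = 0.0
    for cls, ids in ids_by_class.items():
        ids = list(ids)
        rng.shuffle(ids)
        ideal = fractions[cls] * len(ids)
        k = int(np.floor(ideal + carry + 1e-9))
        carry += ideal - k
        first.extend(ids[:k])
        second.extend(ids[k:])
    return first, second


def make_split_plan(labels: pd.Series, cfg: PipelineConfig | None = None,
                    seed: int | None = None) -> SplitPlan:
    """Stratified discovery/replication split and 500 half-splits of
    discovery, all drawn from one seeded stream."""
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 101])
    counts = labels.value_counts()
    if len(counts) != 2 or counts.min() < 4:
        raise ValueError("both classes need >= 4 members")
    by_class = {cls: labels.index[labels == cls].tolist()
                for cls in sorted(counts.index, key=str)}
    discovery, replication = _stratified_take(
        by_class, {c: cfg.discovery_fraction for c in by_class}, rng)
    disc_by_class = {cls: [i for i in ids if i in set(discovery)]
                     for cls, ids in by_class.items()}
    halves = []
    for _ in range(cfg.n_stability_iter):
        halves.append(_stratified_take(
            disc_by_class, {c: 0.5 for c in disc_by_class}, rng))
    return SplitPlan(seed, discovery, replication, halves)


# ---------------------------------------------------------------------------
# proportion scores
# ---------------------------------------------------------------------------


@dataclass
class ProportionScoreTable:
    counts: pd.Series   # per-marker number of models with nonzero weight
    n_models: int
    n_redraws: int = 0

    @property
    def proportions(self) -> pd.Series:
        return (self.counts / self.n_models).rename("proportion")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts,
                             "proportion": self.proportions})


def _fit_half(Xh: pd.DataFrame, yh: np.ndarray, cfg: PipelineConfig,
              rng: np.random.Generator) -> np.ndarray:
    """One resampled model: CV-tuned L1 logistic on a training half."""
    Xz, _, _ = standardize(Xh)
    lam_max = _solvers.logistic_lambda_max(Xz, yh)
    grid = lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)
    k = min(cfg.cv_folds, int(np.bincount(yh.astype(int)).min()))
    li = cv_lambda_logistic(Xz, yh, grid, max(k, 2), rng)
    coefs, _ = _solvers.logistic_lasso_path(Xz, yh, grid[:li + 1])
    return coefs[-1]


def run_stability(X: pd.DataFrame, y: np.ndarray, plan: SplitPlan,
                  cfg: PipelineConfig | None = None) -> ProportionScoreTable:
    """Proportion scores over the plan's resampled LASSO models.

    An iteration whose training half lacks a class (possible only with
    degenerate inputs) is redrawn from the seeded stream and counted.
    """
    cfg = cfg or PipelineConfig()
    y = pd.Series(np.asarray(y, int), index=X.index)
    rng = np.random.default_rng([plan.seed, 202])
    counts = np.zeros(X.shape[1])
    redraws = 0
    for tr_ids, _te_ids in plan.half_splits:
        yh = y.loc[tr_ids].to_numpy()
        while len(np.unique(yh)) < 2:  # pragma: no cover - degenerate plans
            redraws += 1
            ids = list(tr_ids) + list(_te_ids)
            rng.shuffle(ids)
            tr_ids = ids[:len(tr_ids)]
            yh = y.loc[tr_ids].to_numpy()
        beta = _fit_half(X.loc[tr_ids], yh.astype(float), cfg, rng)
        counts += np.abs(beta) > NONZERO_TOL
    return ProportionScoreTable(
        pd.Series(counts, index=X.columns, name="count"),
        n_models=len(plan.half_splits), n_redraws=redraws)


# ---------------------------------------------------------------------------
# signature sets
# ---------------------------------------------------------------------------


@dataclass
class SignatureSet:
    threshold: float
    markers: list


def build_signature_sets(proportions: ProportionScoreTable | pd.Series,
                         step: float = 0.05) -> list[SignatureSet]:
    """Nested signature sets at proportion-score thresholds 0, step, ..., 1.

    Identical marker lists keep only the highest-threshold copy; empty sets
    are dropped.  Output is ordered by increasing threshold, so sizes are
    strictly decreasing.
    """
    prop = proportions.proportions if isinstance(
        proportions, ProportionScoreTable) else proportions
    n_steps = int(round(1.0 / step))
    sets: list[SignatureSet] = []
    for i in range(n_steps + 1):
        thr = round(i * step, 10)
        members = prop.index[prop >= thr - 1e-12].tolist()
        if not members:
            continue
        if sets and sets[-1].markers == members:
            sets[-1] = SignatureSet(thr, members)
        else:
            sets.append(SignatureSet(thr, members))
    return sets


# ---------------------------------------------------------------------------
# signature evaluation
# ---------------------------------------------------------------------------


@dataclass
class SignatureEvaluation:
    signature: SignatureSet
    cohort_label: str   # "discovery_half" or "replication"
    n: int
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def _confusion_metrics(scores, labels, cutoff):
    pred = scores >= cutoff
    labels = np.asarray(labels, bool)
    tp = float((pred & labels).sum())
    fp = float((pred & ~labels).sum())
    tn = float((~pred & ~labels).sum())
    fn = float((~pred & labels).sum())
    safe = lambda a, b: a / b if b > 0 else float("nan")
    return {"sensitivity": safe(tp, tp + fn), "specificity": safe(tn, tn + fp),
            "ppv": safe(tp, tp + fp), "npv": safe(tn, tn + fn)}


def evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                    cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    """ROC/Youden metrics with stratified percentile bootstrap CIs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    roc = roc_auc(scores, labels)
    bp = youden_best_point(roc, n_pos=int(labels.sum()),
                           n_neg=int((1 - labels).sum()))
    point = _confusion_metrics(scores, labels, bp.cutoff)
    out = {"auc": roc.auc, "cutoff": bp.cutoff, **point}
    metrics = {"auc": lambda s, l: roc_auc(s, l).auc}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        metrics[name] = (lambda s, l, _n=name:
                         _confusion_metrics(s, l, bp.cutoff)[_n])
    for name, fn in metrics.items():
        out[f"{name}_ci"] = bootstrap_ci(fn, scores, labels,
                                         n=cfg.n_bootstrap, stratified=True,
                                         seed=rng)
    return out


def evaluate_signature(signature: SignatureSet, X: pd.DataFrame,
                       y: np.ndarray, plan: SplitPlan,
                       cfg: PipelineConfig | None = None
                       ) -> tuple[SignatureEvaluation, SignatureEvaluation]:
    """Ridge evaluation of one signature: within-discovery and replication.

    (i) fit on the plan's first discovery half, score the other half;
    (ii) fit on all of discovery, score the replication cohort.
    """
    cfg = cfg or PipelineConfig()
    if not signature.markers:
        raise ValueError("signature is empty")
    y = pd.Series(np.asarray(y, int), index=X.index)
    Xs = X[signature.markers]
    rng = np.random.default_rng([plan.seed, 303])
    evals = []
    splits = [("discovery_half", plan.half_splits[0][0], plan.half_splits[0][1]),
              ("replication", plan.discovery_ids, plan.replication_ids)]
    for label, train_ids, test_ids in splits:
        model = fit_ridge_logistic_cv(Xs.loc[train_ids],
                                      y.loc[train_ids].to_numpy(),
                                      cfg, seed=int(rng.integers(2**31)))
        scores = predict_score(model, Xs.loc[test_ids]).to_numpy()
        labels = y.loc[test_ids].to_numpy()
        if len(np.unique(labels)) < 2:
            raise ValueError(f"evaluation set {label!r} has one class")
        m = evaluate_scores(scores, labels, cfg, rng)
        evals.append(SignatureEvaluation(
            signature, label, len(labels), m["auc"], m["auc_ci"], m["cutoff"],
            m["sensitivity"], m["sensitivity_ci"],
            m["specificity"], m["specificity_ci"],
            m["ppv"], m["ppv_ci"], m["npv"], m["npv_ci"]))
    return evals[0], evals[1]


def evaluations_to_frame(evals: list[SignatureEvaluation]) -> pd.DataFrame:
    rows = []
    for e in evals:
        rows.append({
            "threshold": e.signature.threshold,
            "n_markers": len(e.signature.markers),
            "cohort": e.cohort_label, "n": e.n,
            "auc": e.auc, "auc_lo": e.auc_ci[0], "auc_hi": e.auc_ci[1],
            "cutoff": e.cutoff,
            "sensitivity": e.sensitivity,
            "sens_lo": e.sensitivity_ci[0], "sens_hi": e.sensitivity_ci[1],
            "specificity": e.specificity,
            "spec_lo": e.specificity_ci[0], "spec_hi": e.specificity_ci[1],
            "ppv": e.ppv, "ppv_lo": e.ppv_ci[0], "ppv_hi": e.ppv_ci[1],
            "npv": e.npv, "npv_lo": e.npv_ci[0], "npv_hi": e.npv_ci[1],
        })
    return pd.DataFrame(rows)
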
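"""Median-lambda penalized classifiers and Cox risk models (approach 2).

The penalty is chosen by repeating 10-fold cross-validation many times
(default 500) with fresh fold assignments, taking each repetition's
deviance-minimizing lambda on a shared 100-point log-spaced grid from
lambda_max down to ``1e-3 * lambda_max``, and selecting the **median** of
the repeated lambdas.  The final weights come from a single fit at that
median penalty on all data; the spread of the per-repetition weights is
retained as a robustness summary.

Families: L1 logistic (resectable-vs-unresectable and short-vs-long
classifiers), Ridge logistic (signature evaluation), and L1 Cox for overall
survival with an optional non-negativity constraint on the weights.
Features are standardized internally (sample-SD convention) and the
standardization parameters are stored on the model so new samples can be
scored.  Cox risk scores are oriented so that higher means higher hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import _solvers
from ._solvers import CoxData
from .cohort_io import PipelineConfig

NONZERO_TOL = 1e-10


@dataclass
class FittedLinearModel:
    """Marker weights + standardization, with the lambda-selection trace."""

    family: str  # logistic_l1 | logistic_ridge | cox_l1 | cox_l1_nonneg
    markers: list[str]
    weights: np.ndarray
    intercept: float | None
    lambda_selected: float
    means: np.ndarray
    sds: np.ndarray
    #: per-repetition CV-optimal lambdas (empty if CV was not repeated)
    lambda_repeats: np.ndarray = field(default_factory=lambda: np.array([]))
    #: per-marker robustness summary of weights across the repetitions
    weight_distribution: pd.DataFrame | None = None
    #: "risk" (higher = worse outcome) or "probability" of the positive class
    orientation: str = "probability"

    def __post_init__(self) -> None:
        if self.family.startswith("cox") and self.intercept is not None:
            raise ValueError("Cox families carry no intercept")
        if self.family == "cox_l1_nonneg" and np.any(self.weights < -NONZERO_TOL):
            raise ValueError("non-negative Cox model has a negative weight")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def nonzero_markers(self) -> list[str]:
        return [m for m, w in zip(self.markers, self.weights)
                if abs(w) > NONZERO_TOL]

    def weights_table(self) -> pd.DataFrame:
        """Weight table in the published layout: marker, weight, intercept."""
        rows = [(m, w) for m, w in zip(self.markers, self.weights)
                if abs(w) > NONZERO_TOL]
        df = pd.DataFrame(rows, columns=["marker", "weight"])
        if self.intercept is not None:
            df = pd.concat(
                [df, pd.DataFrame([("intercept", self.intercept)],
                                  columns=["marker", "weight"])],
                ignore_index=True)
        return df


def standardize(X: pd.DataFrame | np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center to mean 0 and scale to sample SD 1 (ddof=1), per column."""
    arr = np.asarray(X, float)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [str(i) for i in range(arr.shape[1])]
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    zero = [c for c, s in zip(cols, sds) if s == 0]
    if zero:
        raise ValueError(f"zero-variance markers cannot be standardized: {zero}")
    return (arr - means) / sds, means, sds


def lambda_grid(lam_max: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Fold assignment balanced by class; redraws cannot be needed because
    every fold's *training* side holds all but one fold."""
    fold = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _cv_deviance_logistic(Xz: np.ndarray, y: np.ndarray, grid: np.ndarray,
                          folds: np.ndarray) -> np.ndarray:
    k = folds.max() + 1
    dev = np.zeros(len(grid))
    for f in range(k):
        tr, va = folds != f, folds == f
        coefs, b0s = _solvers.logistic_lasso_path(Xz[tr], y[tr], grid)
        for li in range(len(grid)):
            dev[li] += _solvers.logistic_deviance(Xz[va], y[va],
                                                  coefs[li], b0s[li]) * va.sum()
    return dev / len(y)


def cv_lambda_logistic(Xz: np.ndarray, y: np.ndarray, grid: np.ndarray,
                       cv_folds: int, rng: np.random.Generator) -> int:
    """Index of the deviance-minimizing penalty for one fold assignment."""
    folds = _stratified_folds(y, cv_folds, rng)
    dev = _cv_deviance_logistic(Xz, y, grid, folds)
    return int(np.argmin(dev))


def fit_median_lambda_logistic(X: pd.DataFrame, y: np.ndarray,
                               cfg: PipelineConfig | None = None,
                               seed: int | None = None) -> FittedLinearModel:
    """L1 logistic classifier with the median-of-repeated-CV penalty."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    y = np.asarray(y, float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    for cls in classes:
        if (y == cls).sum() < cfg.cv_folds:
            raise ValueError("each class needs >= cv_folds members")
    markers = list(X.columns)
    Xz, means, sds = standardize(X)

    lam_max = _solvers.logistic_lambda_max(Xz, y)
    grid = lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)
    full_coefs, full_b0s = _solvers.logistic_lasso_path(Xz, y, grid)

    picks = np.array([cv_lambda_logistic(Xz, y, grid, cfg.cv_folds, rng)
                      for _ in range(cfg.n_lambda_repeats)])
    lam_repeats = grid[picks]
    lam_final = float(np.median(lam_repeats))
    coef_final, b0_final = _solvers.logistic_lasso_path(
        Xz, y, np.array([lam_final]))
    wdist = _weight_distribution(markers, full_coefs[picks])
    return FittedLinearModel("logistic_l1", markers, coef_final[0],
                             float(b0_final[0]), lam_final, means, sds,
                             lam_repeats, wdist, orientation="probability")


def _weight_distribution(markers: list[str], W: np.ndarray) -> pd.DataFrame:
    q25, med, q75 = np.percentile(W, [25, 50, 75], axis=0)
    return pd.DataFrame(
        {"median": med, "q25": q25, "q75": q75,
         "selection_fraction": (np.abs(W) > NONZERO_TOL).mean(axis=0)},
        index=pd.Index(markers, name="marker"))


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


def _cv_deviance_cox(data: CoxData, Xz: np.ndarray, times: np.ndarray,
                     events: np.ndarray, grid: np.ndarray, folds: np.ndarray,
                     nonneg: bool) -> np.ndarray:
    """Verweij-Van Houwelingen cross-validated partial-likelihood deviance:
    for each fold, -2 * (loglik on all data minus loglik on the training
    part), evaluated at the training-fold solution."""
    k = folds.max() + 1
    n = len(times)
    dev = np.zeros(len(grid))
    for f in range(k):
        tr = folds != f
        data_tr = CoxData(Xz[tr], times[tr], events[tr])
        path = _solvers.cox_lasso_path(data_tr, grid, nonneg=nonneg)
        for li, beta in enumerate(path):
            l_full = -data.neg_loglik(beta) * n
            l_tr = -data_tr.neg_loglik(beta) * tr.sum()
            dev[li] += -2.0 * (l_full - l_tr)
    return dev


def _event_stratified_folds(events: np.ndarray, k: int,
                            rng: np.random.Generator) -> np.ndarray:
    fold = _stratified_folds(events, k, rng)
    # every training part must retain at least one event
    for f in range(k):
        if events[fold != f].sum() == 0:
            raise ValueError("cv_folds too large for the number of events")
    return fold


def fit_median_lambda_cox(X: pd.DataFrame, times: np.ndarray,
                          events: np.ndarray, nonneg: bool = False,
                          cfg: PipelineConfig | None = None,
                          seed: int | None = None) -> FittedLinearModel:
    """L1 Cox risk model with the median-of-repeated-CV penalty.

    With ``nonneg=True`` weights are constrained to be >= 0 (a marker whose
    true effect is protective is pushed to exactly zero).  Ties are handled
    with the Breslow approximation.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() < 10:
        raise ValueError("need >= 10 observed events for a Cox fit")
    markers = list(X.columns)
    Xz, means, sds = standardize(X)
    data = CoxData(Xz, times, events)

    lam_max = _solvers.cox_lambda_max(data, nonneg=nonneg)
    grid = lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)
    full_path = _solvers.cox_lasso_path(data, grid, nonneg=nonneg)

    picks = np.empty(cfg.n_lambda_repeats, dtype=int)
    for r in range(cfg.n_lambda_repeats):
        folds = _event_stratified_folds(events, cfg.cv_folds, rng)
        dev = _cv_deviance_cox(data, Xz, times, events, grid, folds, nonneg)
        picks[r] = int(np.argmin(dev))
    lam_repeats = grid[picks]
    lam_final = float(np.median(lam_repeats))
    beta = _solvers.cox_lasso_fit(data, lam_final, nonneg=nonneg)
    wdist = _weight_distribution(markers, full_path[picks])
    family = "cox_l1_nonneg" if nonneg else "cox_l1"
    return FittedLinearModel(family, markers, beta, None, lam_final,
                             means, sds, lam_repeats, wdist,
                             orientation="risk")


# ---------------------------------------------------------------------------
# ridge logistic (signature evaluation)
# ---------------------------------------------------------------------------


def fit_ridge_logistic_cv(X: pd.DataFrame, y: np.ndarray,
                          cfg: PipelineConfig | None = None,
                          seed: int | None = None,
                          n_lambda: int = 50) -> FittedLinearModel:
    """L2 logistic fit with the penalty chosen by 10-fold CV deviance."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    y = np.asarray(y, float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    markers = list(X.columns)
    Xz, means, sds = standardize(X)
    n = len(y)
    grid = np.geomspace(1e2, 1e-5, n_lambda)
    k = min(cfg.cv_folds, int(min(np.bincount(y.astype(int)))))
    folds = _stratified_folds(y, max(k, 2), rng)
    dev = np.zeros(len(grid))
    for f in range(folds.max() + 1):
        tr, va = folds != f, folds == f
        for li, lam in enumerate(grid):
            clf = LogisticRegression(C=1.0 / (tr.sum() * lam), solver="lbfgs",
                                     max_iter=2000)
            clf.fit(Xz[tr], y[tr])
            dev[li] += _solvers.logistic_deviance(
                Xz[va], y[va], clf.coef_[0], float(clf.intercept_[0])) * va.sum()
    lam_final = float(grid[int(np.argmin(dev / n))])
    clf = LogisticRegression(C=1.0 / (n * lam_final), solver="lbfgs",
                             max_iter=5000)
    clf.fit(Xz, y)
    return FittedLinearModel("logistic_ridge", markers, clf.coef_[0],
                             float(clf.intercept_[0]), lam_final, means, sds,
                             orientation="probability")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def predict_score(model: FittedLinearModel, X: pd.DataFrame) -> pd.Series:
    """Linear prediction score: sum of standardized levels times weights.

    Logistic families add the intercept (the score is the logit of the
    positive class); Cox families return the log-relative-hazard, higher
    meaning higher predicted risk.
    """
    missing = [m for m in model.markers if m not in X.columns]
    if missing:
        raise ValueError(f"input lacks model markers: {missing}")
    arr = X[model.markers].to_numpy(float)
    z = (arr - model.means) / model.sds
    score = z @ model.weights
    if model.intercept is not None:
        score = score + model.intercept
    return pd.Series(score, index=X.index, name="prediction_score")
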
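"""Synthetic pre-surgery PDAC cohorts with exported ground truth.

The study data (273 patients, 92 Olink immuno-oncology proteins + CA19-9,
overall survival with right-censoring) are not publicly deposited, so every
downstream stage is exercised on simulated cohorts that reproduce the data's
statistical structure:

* correlated log2 marker levels — a small number of shared latent factors
  plus independent per-marker noise, emulating the co-regulation of
  circulating inflammatory proteins;
* additive NPX mean shifts on selected markers between the resectable and
  unresectable groups;
* overall survival from a proportional-hazards model with constant baseline
  hazard per group, calibrated so the uncensored median OS matches the
  study's 22.6 months (resectable) and 8.2 months (unresectable);
* administrative censoring at a follow-up horizon plus an independent
  uniform early-censoring mechanism.

What the generator deliberately does **not** emulate: the empirical Olink
panel correlation matrix, assay noise floors/LOD, or the joint distribution
of clinical covariates beyond group sizes and survival medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import CA199, CohortTable

#: default survival effects: four hazardous markers and one protective one,
#: |beta| = 0.5 per NPX unit
_DEFAULT_SURVIVAL_BETAS = {
    "P006": 0.5, "P007": 0.5, "P008": 0.5, "P009": 0.5, "P010": -0.5,
}
_DEFAULT_RESECT_SHIFTS = {f"P{i:03d}": 1.0 for i in range(1, 6)}


def default_marker_names(n_markers: int = 93) -> list[str]:
    """n_markers-1 generic protein channels plus the CA19-9 channel."""
    return [f"P{i:03d}" for i in range(1, n_markers)] + [CA199]


@dataclass
class SimulationConfig:
    """Cohort-generator parameters; defaults are the study conditions."""

    n_resectable: int = 193
    n_unresectable: int = 80
    n_markers: int = 93
    n_latent_factors: int = 3
    factor_loading_sd: float = 0.5
    marker_noise_sd: float = 1.0  # NPX units
    #: marker -> mean NPX shift (unresectable minus resectable)
    resectability_effects: dict = field(default_factory=dict)
    #: marker -> Cox log-hazard per NPX unit (positive = hazardous)
    survival_betas: dict = field(default_factory=dict)
    median_os_resectable: float = 22.6   # months
    median_os_unresectable: float = 8.2  # months
    censoring_horizon_months: float = 150.0
    uniform_censoring_fraction: float = 0.08
    seed: int = 0
    #: optional fixed loading matrix (n_markers x n_latent_factors);
    #: when None loadings are drawn N(0, factor_loading_sd^2)
    factor_loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_resectable < 2 or self.n_unresectable < 2:
            raise ValueError("group counts must be >= 2")
        if self.factor_loading_sd <= 0 or self.marker_noise_sd <= 0:
            raise ValueError("loading and noise SDs must be positive")
        if self.median_os_resectable <= 0 or self.median_os_unresectable <= 0:
            raise ValueError("baseline median OS must be positive")
        if not 0.0 <= self.uniform_censoring_fraction < 1.0:
            raise ValueError("censoring fraction must lie in [0, 1)")

    @classmethod
    def default_scenario(cls, **overrides) -> "SimulationConfig":
        """The reference test scenario: 5 resectability-informative markers
        (shift 1.0 NPX) and 5 survival-informative markers (|beta| = 0.5)."""
        kw = dict(resectability_effects=dict(_DEFAULT_RESECT_SHIFTS),
                  survival_betas=dict(_DEFAULT_SURVIVAL_BETAS))
        kw.update(overrides)
        return cls(**kw)

    @property
    def marker_names(self) -> list[str]:
        return default_marker_names(self.n_markers)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    resectability_markers: list[str]
    survival_betas: dict
    latent_event_times: pd.Series  # months, before censoring


def _check_known(effects: dict, names: list[str], what: str) -> None:
    unknown = set(effects) - set(names)
    if unknown:
        raise ValueError(f"{what} reference unknown markers: {sorted(unknown)}")


def simulate_cohort(cfg: SimulationConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort; the same config and seed give bit-identical output."""
    names = cfg.marker_names
    _check_known(cfg.resectability_effects, names, "resectability_effects")
    _check_known(cfg.survival_betas, names, "survival_betas")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_resectable + cfg.n_unresectable
    p = cfg.n_markers
    resectable = np.r_[np.ones(cfg.n_resectable, bool),
                       np.zeros(cfg.n_unresectable, bool)]

    # --- marker matrix: latent factors + noise + group shift ---------------
    baseline = rng.uniform(2.0, 8.0, size=p)
    baseline[-1] = np.log2(200.0)  # CA19-9 channel near the cohort median U/ml
    if cfg.factor_loadings is not None:
        loadings = np.asarray(cfg.factor_loadings, float)
        if loadings.shape != (p, cfg.n_latent_factors):
            raise ValueError("factor_loadings shape mismatch")
    else:
        loadings = rng.normal(0.0, cfg.factor_loading_sd,
                              size=(p, cfg.n_latent_factors))
    factors = rng.normal(size=(n, cfg.n_latent_factors))
    noise = rng.normal(0.0, cfg.marker_noise_sd, size=(n, p))
    X = baseline + factors @ loadings.T + noise
    shift = np.zeros(p)
    for marker, delta in cfg.resectability_effects.items():
        shift[names.index(marker)] = delta
    X[~resectable] += shift  # unresectable group carries the + shift

    # --- survival: exponential PH calibrated to the group medians ----------
    eta = np.zeros(n)
    if cfg.survival_betas:
        centered = X - X.mean(axis=0)
        for marker, beta in cfg.survival_betas.items():
            eta += beta * centered[:, names.index(marker)]
    base_median = np.where(resectable, cfg.median_os_resectable,
                           cfg.median_os_unresectable)
    rate = np.log(2.0) / base_median * np.exp(eta)
    latent_t = rng.exponential(1.0, size=n) / rate

    censor = np.full(n, cfg.censoring_horizon_months)
    early = rng.random(n) < cfg.uniform_censoring_fraction
    u = rng.uniform(0.0, cfg.censoring_horizon_months, size=n)
    censor[early] = np.minimum(censor[early], u[early])
    os_months = np.minimum(latent_t, censor)
    event = (latent_t <= censor).astype(int)
    os_months = np.maximum(os_months, 1e-6)

    # --- clinical covariates (null with respect to survival) ---------------
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    age = np.clip(rng.normal(67.0, 9.0, size=n).round(1), 37.0, 86.0)
    stage = np.where(
        resectable,
        rng.choice([1, 2, 3, 4], size=n, p=[0.06, 0.51, 0.42, 0.01]),
        rng.choice([1, 2, 3, 4], size=n, p=[0.0, 0.0, 0.28, 0.72]),
    )
    asa = rng.choice([1, 2, 3, 4], size=n, p=[0.27, 0.49, 0.23, 0.01])
    chemo = rng.choice(["none", "gemcitabine", "folfirinox"], size=n,
                       p=[0.45, 0.35, 0.20])

    npx = pd.DataFrame(X, index=pd.Index(ids, name="sample_id"), columns=names)
    clinical = pd.DataFrame(
        {
            "resectable": resectable,
            "os_months": os_months,
            "event": event,
            "age_years": age,
            "stage": stage,
            "asa": asa,
            "adjuvant_chemo": chemo,
            "ca199_uml": np.exp2(npx[CA199].to_numpy()),
        },
        index=npx.index,
    )
    cohort = CohortTable(npx, clinical)
    truth = GroundTruth(
        resectability_markers=sorted(cfg.resectability_effects),
        survival_betas=dict(cfg.survival_betas),
        latent_event_times=pd.Series(latent_t, index=npx.index,
                                     name="latent_event_months"),
    )
    return cohort, truth


def null_cohort(cfg: SimulationConfig) -> CohortTable:
    """Same generator with every effect map emptied: labels carry no signal."""
    cohort, _ = simulate_cohort(replace(cfg, resectability_effects={},
                                        survival_betas={}))
    return cohort
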
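"""Cohort data model, file I/O and the two-group comparison catalog.

The pipeline operates on a cohort of patients sampled before surgery for
suspected pancreatic ductal adenocarcinoma (PDAC).  Each patient carries a
vector of 93 circulating markers — 92 immuno-oncology proteins measured on
the Olink NPX (log2) scale plus the clinical tumor marker CA19-9 — joined to
clinical covariates and a right-censored overall-survival outcome.  All
downstream stages (differential expression, stability selection, penalized
risk models, survival evaluation) consume the :class:`CohortTable` built
here.

CA19-9 is reported by the clinical assay in U/ml; on ingest it is placed on
the same log2 scale as the NPX proteins (``log2(U/ml)``) so that penalized
regression weights are comparable across all 93 markers.  The raw U/ml value
is kept in the clinical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

CA199 = "CA19-9"

CLINICAL_COLUMNS = [
    "resectable",
    "os_months",
    "event",
    "age_years",
    "stage",
    "asa",
    "adjuvant_chemo",
    "ca199_uml",
]


class CohortError(ValueError):
    """Raised when an input file or cohort violates the data contract."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Run-wide knobs shared by every pipeline stage.

    Defaults mirror the study conditions: 500 resampled LASSO fits, 10-fold
    cross-validation, 2000 stratified bootstrap replicates, a 0.05 proportion
    step for signature sets, and survival horizons at 6/12/24 months.
    """

    seed: int = 0
    n_stability_iter: int = 500
    cv_folds: int = 10
    n_bootstrap: int = 2000
    proportion_step: float = 0.05
    discovery_fraction: float = 2.0 / 3.0
    evaluation_horizons_months: tuple[float, ...] = (6.0, 12.0, 24.0)
    #: number of penalty values on the log-spaced grid from lambda_max down
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    #: repetitions of the 10-fold CV whose lambdas are pooled by the median
    n_lambda_repeats: int = 500
    simulator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_stability_iter", "cv_folds", "n_bootstrap", "n_lambda",
                     "n_lambda_repeats"):
            if int(getattr(self, name)) < 1:
                raise CohortError(f"{name} must be >= 1")
        n_steps = 1.0 / self.proportion_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise CohortError("proportion_step must divide 1 evenly")
        if not 0.0 < self.discovery_fraction < 1.0:
            raise CohortError("discovery_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise CohortError(f"unknown config keys: {sorted(unknown)}")
        if "evaluation_horizons_months" in raw:
            raw["evaluation_horizons_months"] = tuple(raw["evaluation_horizons_months"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["evaluation_horizons_months"] = list(self.evaluation_horizons_months)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Samples x markers log2 matrix joined to clinical covariates.

    ``npx`` holds the 92 proteins in NPX units and CA19-9 as log2(U/ml);
    ``clinical`` holds resectability, overall survival (months), the event
    indicator (1 = death observed), age, stage, ASA class, adjuvant
    chemotherapy category and raw CA19-9.  Both frames are indexed by the
    sample id and share the exact same index.
    """

    npx: pd.DataFrame
    clinical: pd.DataFrame
    ca199_marker: str = CA199

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.npx.index.duplicated().any():
            dups = self.npx.index[self.npx.index.duplicated()].tolist()
            raise CohortError(f"duplicate sample ids: {dups}")
        if self.npx.columns.duplicated().any():
            raise CohortError("duplicate marker names")
        if not self.npx.index.equals(self.clinical.index):
            raise CohortError("npx and clinical tables are keyed differently")
        if self.ca199_marker not in self.npx.columns:
            raise CohortError(f"CA19-9 channel {self.ca199_marker!r} missing")
        os_months = self.clinical["os_months"].to_numpy(float)
        if not np.all(os_months > 0):
            raise CohortError("os_months must be strictly positive")
        ev = self.clinical["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise CohortError("event indicator must be 0 or 1")
        vals = self.npx.to_numpy(float)
        if np.isinf(vals).any():
            raise CohortError("npx values must be finite (NaN marks missing)")

    # -- conveniences -------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.npx.index

    @property
    def markers(self) -> list[str]:
        return list(self.npx.columns)

    @property
    def n_samples(self) -> int:
        return len(self.npx)

    def subset(self, ids: Sequence[str]) -> "CohortTable":
        ids = pd.Index(ids)
        return CohortTable(self.npx.loc[ids], self.clinical.loc[ids],
                           self.ca199_marker)

    def require_complete(self, markers: Sequence[str] | None = None) -> None:
        """Error (naming markers) if any selected NPX entry is missing."""
        cols = list(markers) if markers is not None else self.markers
        bad = [c for c in cols if self.npx[c].isna().any()]
        if bad:
            raise CohortError(f"missing NPX values in markers: {bad}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df


def read_cohort(marker_path: str | Path, clinical_path: str | Path,
                config: PipelineConfig | None = None,
                ca199_marker: str = CA199) -> CohortTable:
    """Read the marker and clinical CSV/TSV pair and join into a cohort.

    The CA19-9 column of the marker file is expected in raw U/ml and is
    log2-transformed on ingest; every other column is already on the log2
    NPX scale.  Sample ids present in only one file are a hard error.
    """
    markers = _read_table(marker_path)
    clinical = _read_table(clinical_path)

    for df, path in ((markers, marker_path), (clinical, clinical_path)):
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample ids in {path}: {dups}")

    if markers.shape[1] < 2:
        raise CohortError("marker file must contain at least 2 markers")

    for col in markers.columns:
        coerced = pd.to_numeric(markers[col], errors="coerce")
        bad = coerced.isna() & markers[col].notna()
        if bad.any():
            row = markers.index[bad][0]
            raise CohortError(
                f"non-numeric marker value at sample {row!r}, marker {col!r}")
        markers[col] = coerced

    only_m = markers.index.difference(clinical.index)
    only_c = clinical.index.difference(markers.index)
    if len(only_m) or len(only_c):
        raise CohortError(
            "sample ids present in only one file: "
            f"markers-only={only_m.tolist()}, clinical-only={only_c.tolist()}")
    clinical = clinical.loc[markers.index]

    missing_cols = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing_cols:
        raise CohortError(f"clinical file lacks columns: {missing_cols}")

    if ca199_marker in markers.columns:
        raw = markers[ca199_marker]
        if (raw <= 0).any():
            raise CohortError("CA19-9 U/ml values must be positive")
        markers[ca199_marker] = np.log2(raw)

    clinical = clinical.copy()
    clinical["resectable"] = clinical["resectable"].astype(bool)
    clinical["event"] = clinical["event"].astype(int)
    return CohortTable(markers, clinical, ca199_marker)


def write_cohort(cohort: CohortTable, marker_path: str | Path,
                 clinical_path: str | Path) -> None:
    """Write the marker/clinical pair; inverse of :func:`read_cohort`.

    CA19-9 is written back in raw U/ml.  Floats are formatted at 6
    significant digits, so read-after-write reproduces the cohort to that
    precision.
    """
    out = cohort.npx.copy()
    out[cohort.ca199_marker] = np.exp2(out[cohort.ca199_marker])
    out.index.name = "sample_id"
    out.to_csv(marker_path, sep=_sep_for(marker_path), float_format="%.6g")
    clin = cohort.clinical.copy()
    clin["resectable"] = clin["resectable"].astype(int)
    clin.index.name = "sample_id"
    clin.to_csv(clinical_path, sep=_sep_for(clinical_path), float_format="%.6g")


# ---------------------------------------------------------------------------
# comparison catalog
# ---------------------------------------------------------------------------


@dataclass
class ComparisonSpec:
    """A named two-group contrast with resolved, disjoint memberships.

    ``group1`` is the clinically positive arm (unresectable, or the
    short-survival arm) and is scored as the ROC positive class.  Samples
    censored before the defining survival threshold are excluded: their arm
    is unknowable.
    """

    name: str
    group1_ids: list[str]
    group2_ids: list[str]
    positive_label: str = "group1"
    usable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if set(self.group1_ids) & set(self.group2_ids):
            raise CohortError(f"comparison {self.name}: arms overlap")

    @property
    def member_ids(self) -> list[str]:
        return list(self.group1_ids) + list(self.group2_ids)


def _survival_arms(sub: pd.DataFrame, threshold: float) -> tuple[list[str], list[str]]:
    """Short arm: died before the threshold.  Long arm: survived past it.

    A sample censored before the threshold is excluded (class unknowable);
    surviving past the threshold counts as long regardless of later
    censoring.  OS exactly at the threshold goes to the long arm.
    """
    os_m = sub["os_months"]
    ev = sub["event"]
    short = sub.index[(os_m < threshold) & (ev == 1)].tolist()
    long = sub.index[os_m >= threshold].tolist()
    return short, long


def _make_comparison(name: str, short: list[str], long: list[str],
                     note: str = "") -> ComparisonSpec:
    usable = len(short) >= 2 and len(long) >= 2
    if not usable:
        note = (note + "; " if note else "") + "fewer than 2 members in an arm"
    return ComparisonSpec(name, short, long, usable=usable, note=note)


def build_comparison_catalog(cohort: CohortTable) -> list[ComparisonSpec]:
    """The study's seven two-group contrasts.

    1. resectable vs unresectable (unresectable positive);
    2-5. resectable short survivors (<1 y, death observed) vs survivors past
    1/3/4/5 years; 6-7. below- vs above-median OS within the unresectable and
    resectable subgroups, the median computed from that subgroup's observed
    OS.  Comparisons with fewer than two members per arm are emitted but
    flagged unusable.
    """
    clin = cohort.clinical
    res = clin[clin["resectable"]]
    unres = clin[~clin["resectable"]]

    catalog = [
        _make_comparison("resectable_vs_unresectable",
                         unres.index.tolist(), res.index.tolist(),
                         note="positive = unresectable"),
    ]
    for years in (1, 3, 4, 5):
        short, _ = _survival_arms(res, 12.0)
        _, long = _survival_arms(res, 12.0 * years)
        catalog.append(_make_comparison(
            f"resectable_os_lt1y_vs_gt{years}y", short, long,
            note="positive = OS < 1 year"))
    for label, sub in (("unresectable", unres), ("resectable", res)):
        if len(sub):
            med = float(sub["os_months"].median())
            short, long = _survival_arms(sub, med)
            # strictly-below-median deaths only; ties at the median go long
            short = [i for i in short if sub.loc[i, "os_months"] < med]
        else:
            med, short, long = float("nan"), [], []
        catalog.append(_make_comparison(
            f"{label}_os_below_vs_above_median", short, long,
            note=f"median OS = {med:.4g} months; positive = below median"))
    return catalog


def get_comparison(cohort: CohortTable, name: str) -> ComparisonSpec:
    for spec in build_comparison_catalog(cohort):
        if spec.name == name:
            return spec
    raise CohortError(f"no comparison named {name!r}")


def extract_design(cohort: CohortTable, spec: ComparisonSpec
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker matrix and 0/1 label vector for a comparison.

    Rows are restricted to the comparison's members in cohort order (stable
    and recorded in the returned frame's index); labels are 1 for the
    positive arm.  Missing NPX entries among the members are a hard error.
    """
    if not spec.usable:
        raise CohortError(f"comparison {spec.name} is flagged unusable")
    members = [s for s in cohort.sample_ids if s in set(spec.member_ids)]
    pos = set(spec.group1_ids if spec.positive_label == "group1"
              else spec.group2_ids)
    sub = cohort.subset(members)
    sub.require_complete()
    X = sub.npx.copy()
    y = np.array([1 if s in pos else 0 for s in members], dtype=int)
    return X, y
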
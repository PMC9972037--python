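import numpy as np
import pandas as pd
import pytest

from protsig import PipelineConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def fast_cfg() -> PipelineConfig:
    """Reduced iteration counts for unit tests; study defaults are exercised
    through the configuration object itself, not re-run at full scale."""
    return PipelineConfig(seed=1, n_stability_iter=8, cv_folds=5,
                          n_bootstrap=200, n_lambda=20, n_lambda_repeats=6)


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample cohort from the default ground-truth scenario."""
    sim = SimulationConfig.default_scenario(n_resectable=80, n_unresectable=40,
                                            seed=11)
    return simulate_cohort(sim)


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    return small_cohort[0]


def toy_cohort_frames(n: int = 8, n_markers: int = 4, seed: int = 0):
    """Tiny hand-sized cohort frames for I/O tests."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n)]
    markers = [f"M{i}" for i in range(n_markers - 1)] + ["CA19-9"]
    npx = pd.DataFrame(rng.normal(5, 1, size=(n, n_markers)),
                       index=pd.Index(ids, name="sample_id"), columns=markers)
    npx["CA19-9"] = np.log2(rng.uniform(10, 500, n))
    clinical = pd.DataFrame({
        "resectable": rng.random(n) < 0.6,
        "os_months": rng.uniform(2, 60, n),
        "event": rng.integers(0, 2, n),
        "age_years": rng.uniform(40, 85, n).round(1),
        "stage": rng.integers(1, 5, n),
        "asa": rng.integers(1, 5, n),
        "adjuvant_chemo": rng.choice(["none", "gemcitabine"], n),
        "ca199_uml": np.exp2(npx["CA19-9"]),
    }, index=npx.index)
    return npx, clinical
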
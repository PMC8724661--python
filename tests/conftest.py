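import numpy as np
import pandas as pd
import pytest

from qlmm import (
    CohortConfig,
    LongitudinalDataset,
    ModelSpec,
    TruthRecord,
    generate_cohort,
)
from qlmm.saem import SAEMConfig


@pytest.fixture(scope="session")
def short_cohort():
    """Small cohort with short follow-up (2-10 monthly visits per subject)."""
    cfg = CohortConfig(
        n_subjects=60, followup_min=2, followup_max=10, followup_mean=6, followup_sd=2.5
    )
    ds, truth = generate_cohort(cfg, TruthRecord(), seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def fixed_only_data():
    """Independent-errors regression data (no random effects), N=400, p=3."""
    rng = np.random.default_rng(5)
    n = 400
    x1 = rng.uniform(0, 3, n)
    x2 = rng.normal(size=n)
    y = 1.0 + 2.0 * x1 - 0.5 * x2 + rng.standard_normal(n)
    frame = pd.DataFrame(
        {"subject": np.arange(n), "time": 0.0, "response": y, "x1": x1, "x2": x2}
    )
    ds = LongitudinalDataset(frame)
    spec = ModelSpec(tau=0.5, fixed_terms=("intercept", "x1", "x2"), random_terms=())
    return ds, spec


@pytest.fixture(scope="session")
def quick_saem_cfg():
    return SAEMConfig(W=60, c=0.4, m=5, burn_in_per_iteration=8, seed=3)


@pytest.fixture(scope="session")
def fitted_short_cohort(short_cohort, quick_saem_cfg):
    """One SAEM fit shared across inference tests."""
    from qlmm import fit_qrlmm

    ds, truth = short_cohort
    res = fit_qrlmm(ds, ModelSpec(tau=0.5), quick_saem_cfg)
    return ds, truth, res
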
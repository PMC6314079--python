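import numpy as np
import pandas as pd
import pytest

from methcordance import SimConfig, simulate_cohorts
from methcordance.data_io import BetaMatrix


def make_beta(values, tissue="BEC", cohort="c", probe_prefix="cg", sample_prefix="s"):
    """Build a BetaMatrix from a 2-D array with generated ids."""
    arr = np.asarray(values, dtype=float)
    return BetaMatrix(
        pd.DataFrame(
            arr,
            index=[f"{probe_prefix}{i:04d}" for i in range(arr.shape[0])],
            columns=[f"{sample_prefix}{j:03d}" for j in range(arr.shape[1])],
        ),
        tissue=tissue,
        cohort=cohort,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Two small cohorts with planted truth, shared across tests (read-only)."""
    cfg = SimConfig(n_cpgs=600, n_snps=120, cohort_sizes=[40, 16], seed=7)
    bundles, truth = simulate_cohorts(cfg)
    return cfg, bundles, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
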
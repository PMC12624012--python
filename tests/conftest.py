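import numpy as np
import pandas as pd
import pytest

import cpsrec
from cpsrec import cohort, partitioning


@pytest.fixture(scope="session")
def cohort_231():
    """Default 231-record synthetic cohort."""
    return cpsrec.generate_cohort(n=231, seed=7)


@pytest.fixture(scope="session")
def cohort_2000():
    """Large cohort for moment/correlation recovery checks."""
    return cpsrec.generate_cohort(n=2000, seed=11)


@pytest.fixture(scope="session")
def split_231(cohort_231):
    return partitioning.stratified_split(cohort_231, 0.20, seed=42)


@pytest.fixture(scope="session")
def dev_table(cohort_231, split_231):
    cols = list(cpsrec.SELECTED_FEATURES) + [cohort.OUTCOME]
    return cohort_231.loc[split_231.development_indices, cols]


@pytest.fixture(scope="session")
def holdout_table(cohort_231, split_231):
    cols = list(cpsrec.SELECTED_FEATURES) + [cohort.OUTCOME]
    return cohort_231.loc[split_231.holdout_indices, cols]


@pytest.fixture(scope="session")
def small_table():
    """A small generic numeric table with a CHO column for clip tests."""
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        {
            "CHO": rng.uniform(0.0, 1.2, 40),
            "a": rng.normal(5, 2, 40),
            "b": rng.normal(-3, 1, 40),
            "Rowing distance": rng.normal(14000, 800, 40),
        }
    )


def toy_gaussian_pair(seed: int, n: int = 400) -> pd.DataFrame:
    """2-column correlated Gaussian toy table (r = 0.8)."""
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=n)
    return pd.DataFrame(
        {"a": 2 + 0.5 * z[:, 0], "Rowing distance": 10 + 2 * z[:, 1]}
    )
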
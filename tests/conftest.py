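import warnings

import numpy as np
import pytest

from mhpheno.cohort import CohortConfig, generate_cohort
from mhpheno.instruments import score_dataframe

warnings.filterwarnings("ignore", category=UserWarning, module="umap")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (n=277), fixed seed."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    return score_dataframe(default_cohort)


@pytest.fixture(scope="session")
def big_cohort():
    """Large exact-count cohort for Monte-Carlo rate checks."""
    return generate_cohort(CohortConfig(n=6000, seed=23, exact_counts=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
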
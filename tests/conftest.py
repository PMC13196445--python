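import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from multimorb import CohortSpec, ConditionClassifier, generate_cohort_frame


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Default synthetic cohort (N = 2333, fixed seed), with truth columns."""
    return generate_cohort_frame(CohortSpec())


@pytest.fixture(scope="session")
def default_panel(default_cohort) -> pd.DataFrame:
    clf = ConditionClassifier()
    return clf.fit(default_cohort).transform(default_cohort)


@pytest.fixture(scope="session")
def big_cohort() -> pd.DataFrame:
    """Larger cohort for calibration / recovery checks."""
    return generate_cohort_frame(CohortSpec(n_participants=10_000, seed=11))


@pytest.fixture()
def designed_complete_panel() -> pd.DataFrame:
    """9 conditions, one participant per unordered pair -> every pair co-occurs."""
    conds = [f"c{i}" for i in range(9)]
    rows = []
    for a, b in itertools.combinations(range(9), 2):
        r = [0.0] * 9
        r[a] = r[b] = 1.0
        rows.append(r)
    return pd.DataFrame(rows, columns=conds)
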
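import numpy as np
import pandas as pd
import pytest

from quitline_ipw import generate_cohort, load_scenario
from quitline_ipw.cohort import Cohort


def make_cohort(a, c, y, **covariates) -> Cohort:
    """Build a small cohort from parallel arrays; Y entries for censored
    subjects are ignored and blanked."""
    a = np.asarray(a, dtype=int)
    c = np.asarray(c, dtype=int)
    yarr = pd.array(np.asarray(y, dtype=float), dtype="Int64")
    yarr[c == 1] = pd.NA
    df = pd.DataFrame({"id": np.arange(len(a)), **covariates, "A": a, "C": c, "Y": yarr})
    return Cohort(df)


def two_by_two_cohort(n1, y1, n0, y0) -> Cohort:
    """Uncensored cohort with y1/n1 events in the high arm, y0/n0 in the low arm."""
    a = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
    y = np.concatenate([np.ones(y1), np.zeros(n1 - y1), np.ones(y0), np.zeros(n0 - y0)])
    return make_cohort(a, np.zeros_like(a), y)


@pytest.fixture(scope="session")
def confounded_50k():
    """One large confounded cohort shared across test modules."""
    return generate_cohort(load_scenario("confounded", n=50_000, seed=424242))
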
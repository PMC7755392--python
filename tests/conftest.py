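import warnings

import numpy as np
import pandas as pd
import pytest

import volatility_learner as vl
from volatility_learner.task import TrialSchedule

warnings.filterwarnings("ignore", message=".*ArviZ.*")


def tiny_schedule(task_version: str = "gain", m1=None, m2=None,
                  event_shape=None, p=0.75, n: int = 5) -> TrialSchedule:
    """Hand-built miniature schedule for unrolled-arithmetic oracles."""
    m1 = m1 if m1 is not None else [40, 60, 10, 99, 50][:n]
    m2 = m2 if m2 is not None else [60, 40, 90, 1, 50][:n]
    event_shape = event_shape if event_shape is not None else [1, 2, 1, 1, 2][:n]
    trials = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "block_type": ["stable"] * n,
            "p_shape1_event": [p] * n,
            "M1": m1,
            "M2": m2,
            "event_shape": event_shape,
        }
    )
    return TrialSchedule(task_version, "stable_first", -1, trials)


@pytest.fixture(scope="session")
def m11_spec():
    return vl.get_model_spec("m11")


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic two-version cohort from the winning model."""
    spec = vl.get_model_spec("m11")
    cohort = vl.CohortSpec(
        n_subjects=12, population=vl.default_population(spec), seed=321
    )
    return vl.simulate_cohort(cohort)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A fitted winning model on the small cohort (shared across tests)."""
    spec = vl.get_model_spec("m11")
    model = vl.build_model(spec, small_cohort.datasets, small_cohort.scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return vl.fit(model, chains=2, tune=500, draws=600, seed=2024)
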
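import numpy as np
import pandas as pd
import pytest

import chronomeal as cm


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but structurally complete cohort: 3 participants x 3 days."""
    params = cm.CohortParams(n_participants=3, n_days=3, seed=7)
    return params, cm.simulate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort():
    """One full study-sized cohort (20 x 7 days)."""
    params = cm.CohortParams(seed=1)
    return params, cm.simulate_cohort(params)


@pytest.fixture
def flat_trace():
    """One constant-glucose day at 5-min epochs."""
    times = pd.date_range("2024-03-04", periods=288, freq="300s")
    return cm.GlucoseTrace(
        participant_id="P01",
        times=times,
        values=np.full(288, 100.0),
        epoch_seconds=300,
    )


def make_event(ts, pid="P01", source="KE", meal_type="lunch", entry_mode="prospective"):
    if source == "KW":
        meal_type, entry_mode = "unknown", "na"
    return cm.MealEvent(
        participant_id=pid,
        timestamp=pd.Timestamp(ts),
        source=source,
        meal_type=meal_type,
        entry_mode=entry_mode,
    )
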
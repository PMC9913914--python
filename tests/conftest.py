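import numpy as np
import pandas as pd
import pytest

from glucoforecast import (
    CarbKineticsParams,
    EventSeries,
    InsulinKineticsParams,
    SimulationConfig,
    impute_series,
    simulate_patient,
)


@pytest.fixture(scope="session")
def carb_params():
    return CarbKineticsParams()


@pytest.fixture(scope="session")
def insulin_adult():
    return InsulinKineticsParams.adult()


@pytest.fixture(scope="session")
def small_record():
    """A 7-day synthetic patient, reused read-only across tests."""
    return simulate_patient(SimulationConfig(seed=3, days=7))


@pytest.fixture(scope="session")
def clean_record(small_record):
    """The same patient with both CGM parts gap-imputed."""
    return small_record.with_(
        train_cgm=impute_series(small_record.train_cgm),
        test_cgm=impute_series(small_record.test_cgm),
    )


def make_events(kind, times_min, magnitudes, start="2025-01-01"):
    """Events at minute offsets from a common origin."""
    t0 = pd.Timestamp(start)
    times = pd.DatetimeIndex([t0 + pd.Timedelta(minutes=m) for m in times_min])
    return EventSeries(kind, times, np.asarray(magnitudes, dtype=float))
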
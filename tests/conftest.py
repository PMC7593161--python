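import numpy as np
import pandas as pd
import pytest

from nestsurv.recess import build_exposure_table
from nestsurv.simulate import FIX_HOURS, NIGHT_FIX, SimParams, make_dataset


@pytest.fixture(scope="session")
def small_params():
    return SimParams(n_birds=24, n_sites=2, years=(2016, 2017), seed=101)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return make_dataset(small_params)


@pytest.fixture(scope="session")
def small_exposure(small_dataset):
    cov, period = build_exposure_table(small_dataset.nests, small_dataset.fixes)
    return cov, period


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def day_times(day="2016-04-05", n=17):
    """The study fix schedule: hourly 05:00-20:00 plus 23:59."""
    day = pd.Timestamp(day)
    stamps = [day + pd.Timedelta(hours=h) for h in FIX_HOURS]
    stamps.append(day + pd.Timedelta(hours=NIGHT_FIX[0], minutes=NIGHT_FIX[1]))
    return pd.DatetimeIndex(stamps[:n])
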
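import numpy as np
import pandas as pd
import pytest

from avert import synthetic


@pytest.fixture(scope="session")
def small_config():
    """A 40-district simulated survey, small enough for fast unit tests."""
    return synthetic.SimConfig(
        n_states=4, districts_per_state=10, women_per_district=400, seed=20160101
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truths, women, births = synthetic.simulate(small_config)
    return truths, women, births


def make_woman(
    woman_id=1,
    district_id=1,
    state_id=1,
    age_years=30,
    age_extra_months=0,
    interview_cmc=1393,
    currently_married=True,
    using_any_method=False,
    weight=1.0,
):
    """A single woman row with age given in completed years at interview."""
    return {
        "woman_id": woman_id,
        "state_id": state_id,
        "district_id": district_id,
        "dob_cmc": interview_cmc - (12 * age_years + age_extra_months),
        "interview_cmc": interview_cmc,
        "currently_married": currently_married,
        "using_any_method": using_any_method,
        "weight": weight,
    }


def women_frame(rows):
    return pd.DataFrame(rows)


def births_frame(rows=None):
    if not rows:
        return pd.DataFrame(
            {"woman_id": pd.Series(dtype=np.int64), "birth_cmc": pd.Series(dtype=np.int64)}
        )
    return pd.DataFrame(rows)


@pytest.fixture
def clean_line_districts():
    """100 districts exactly on log TFR = 1.2 - 0.0083 CPR plus mild noise."""
    rng = np.random.default_rng(42)
    cpr = np.linspace(5, 85, 100)
    log_tfr = 1.2 - 0.0083 * cpr + rng.normal(0, 0.05, 100)
    return pd.DataFrame(
        {
            "district_id": np.arange(1, 101),
            "state_id": 1,
            "tfr": np.exp(log_tfr),
            "cpr": cpr,
            "total_births_window": 1000.0,
        }
    )
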
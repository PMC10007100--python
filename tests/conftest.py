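from datetime import date

import numpy as np
import pandas as pd
import pytest

from etcmp import presets
from etcmp.fao56 import CropCalendar
from etcmp.soil import simulate_season
from etcmp.soil.simulate import water_balance
from etcmp.synthetic import gen_forcing_fixtures


@pytest.fixture(scope="session")
def profile():
    return presets.load_profile("oued_souhil")


@pytest.fixture(scope="session")
def potato():
    return presets.load_crop_params("potato")


@pytest.fixture(scope="session")
def barley():
    return presets.load_crop_params("barley")


@pytest.fixture(scope="session")
def potato_calendar():
    return presets.load_crop_calendar(1)


@pytest.fixture(scope="session")
def mini_calendar():
    """A 30-day potato-like season for fast solver tests."""
    return CropCalendar(
        crop="potato", planting=date(2015, 3, 11), harvest=date(2015, 4, 9),
        kc_ini=0.5, kc_mid=1.15, kc_end=0.75,
        lai_points=[(0.0, 1.0), (0.42, 3.5), (0.77, 3.5), (1.0, 1.0)],
    )


@pytest.fixture(scope="session")
def mini_forcing(mini_calendar):
    dates = mini_calendar.dates()
    n = len(dates)
    irrigation = np.zeros(n)
    irrigation[[5, 15, 25]] = 20.0
    return pd.DataFrame({
        "date": dates,
        "precipitation": 0.0,
        "irrigation": irrigation,
        "irrigation_EC": np.where(irrigation > 0, 3.5, 0.0),
        "ET0": 4.0,
    })


@pytest.fixture(scope="session")
def season1_forcing():
    return gen_forcing_fixtures(seed=1)[1]


@pytest.fixture(scope="session")
def potato_season(profile, potato, potato_calendar, season1_forcing):
    """Full saline (3.5 dS/m irrigation water) potato season - shared by
    the closure, stress and convergence tests."""
    return simulate_season(profile, potato, potato_calendar, season1_forcing)


@pytest.fixture(scope="session")
def potato_season_fresh(profile, potato, potato_calendar, season1_forcing):
    fresh = season1_forcing.copy()
    fresh["irrigation_EC"] = 0.0
    return simulate_season(profile, potato, potato_calendar, fresh)


@pytest.fixture(scope="session")
def potato_balance(potato_season):
    return water_balance(potato_season)
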
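import numpy as np
import pytest

from paddywf.climate import et0_series, generate_daily_weather
from paddywf.hydrology import IDUGeometry, ManagementStyle, default_scheme
from paddywf.presets import CLIMATE_PRESETS
from paddywf.simulate import IDUConfig, default_fertilization


@pytest.fixture(scope="session")
def cj_climate():
    return CLIMATE_PRESETS["CJ"]


@pytest.fixture(scope="session")
def cj_weather(cj_climate):
    """Five years of Changjiang-archetype synthetic weather plus ET0."""
    weather = generate_daily_weather(cj_climate, 5, seed=42)
    et0 = et0_series(weather, cj_climate.latitude_deg, cj_climate.elevation_m)
    return weather, et0


@pytest.fixture(scope="session")
def cj_season(cj_climate, cj_weather):
    """Season slice (weather rows, et0) for year 1 of the CJ archetype."""
    weather, et0 = cj_weather
    mask = ((weather["year"] == 1)
            & (weather["doy"] >= cj_climate.season_start_doy)
            & (weather["doy"] <= cj_climate.season_end_doy))
    return weather.loc[mask].reset_index(drop=True), et0[mask.to_numpy()]


def make_config(style=ManagementStyle.QD, *, idu_area_m2=2e5, ditch_frac=0.04,
                pond_frac=0.02, season_length=120, percolation=2.0):
    geom = IDUGeometry(
        field_area_m2=idu_area_m2 * (1 - ditch_frac - pond_frac),
        ditch_area_m2=idu_area_m2 * ditch_frac,
        pond_area_m2=idu_area_m2 * pond_frac if style.pond_in_drainage_path else 0.0,
        percolation_mm_day=percolation,
    )
    return IDUConfig(geometry=geom, style=style, scheme=default_scheme(season_length),
                     fert_events=default_fertilization())


@pytest.fixture(scope="session")
def qd_config():
    return make_config(ManagementStyle.QD)


@pytest.fixture(scope="session")
def tc_config():
    return make_config(ManagementStyle.TC, pond_frac=0.0)
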
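"""Reference/crop evapotranspiration and stage-wise yield response.

Implements the FAO-56 Penman-Monteith daily reference evapotranspiration
(radiation estimated from sunshine hours via the Angstrom formula), the
CROPWAT-style soil-water stress coefficient Ks, and the stage-wise yield
response to evapotranspiration deficit with yield response factors Ky.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StageYieldFactors",
    "saturation_vapour_pressure",
    "extraterrestrial_radiation",
    "daylight_hours",
    "reference_et0",
    "water_stress_coefficient",
    "yield_loss",
]

#: Solar constant, MJ m-2 min-1.
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1.
STEFAN_BOLTZMANN = 4.903e-9


@dataclass(frozen=True)
class StageYieldFactors:
    """Per-stage crop coefficients and yield response factors for paddy rice.

    Stage order is (initial, development, mid-season, late-season).  Default
    Ky values are the standard rice yield-response factors (1.0, 1.09, 1.32,
    0.5); default Kc values are the FAO-56 paddy rice crop coefficients.
    """

    ky: tuple[float, float, float, float] = (1.0, 1.09, 1.32, 0.5)
    kc: tuple[float, float, float, float] = (1.05, 1.10, 1.20, 0.90)

    def __post_init__(self) -> None:
        if len(self.ky) != 4 or len(self.kc) != 4:
            raise ValueError("ky and kc must have one value per growth stage")
        if any(k <= 0 for k in self.ky) or any(k <= 0 for k in self.kc):
            raise ValueError("ky and kc must be positive")


def saturation_vapour_pressure(temp_c: float) -> float:
    """Saturation vapour pressure e0(T) in kPa at air temperature ``temp_c``."""
    return 0.6108 * math.exp(17.27 * temp_c / (temp_c + 237.3))


def _solar_geometry(latitude_deg: float, doy: int) -> tuple[float, float]:
    """Return (sunset hour angle ws [rad], extraterrestrial radiation Ra)."""
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    return ws, ra


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1."""
    return _solar_geometry(latitude_deg, doy)[1]


def daylight_hours(latitude_deg: float, doy: int) -> float:
    """Maximum possible sunshine duration N in hours."""
    ws, _ = _solar_geometry(latitude_deg, doy)
    return 24.0 / math.pi * ws


def reference_et0(
    tmin_c: float,
    tmax_c: float,
    rh_mean_pct: float,
    wind_2m_ms: float,
    sunshine_h: float,
    doy: int,
    latitude_deg: float,
    elevation_m: float,
    *,
    albedo: float = 0.23,
    angstrom_a: float = 0.25,
    angstrom_b: float = 0.50,
) -> float:
    """FAO-56 Penman-Monteith daily grass reference evapotranspiration, mm/day.

    Shortwave radiation is estimated from relative sunshine duration with the
    Angstrom formula; actual vapour pressure from mean relative humidity; soil
    heat flux is taken as zero at the daily step.

    Parameters
    ----------
    tmin_c, tmax_c:
        Daily minimum/maximum air temperature, degC.
    rh_mean_pct:
        Daily mean relative humidity, %.
    wind_2m_ms:
        Wind speed at 2 m, m/s.
    sunshine_h:
        Bright sunshine duration, hours.
    doy:
        Day of year (1-365).
    latitude_deg, elevation_m:
        Station latitude (degrees, positive north) and elevation (m a.s.l.).
    """
    if not 0.0 <= rh_mean_pct <= 100.0:
        raise ValueError(f"relative humidity must be in [0, 100], got {rh_mean_pct}")
    if tmax_c < tmin_c:
        raise ValueError("tmax must be >= tmin")

    tmean = 0.5 * (tmax_c + tmin_c)
    # Atmospheric pressure and psychrometric constant at elevation.
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.665e-3 * pressure
    # Vapour pressures.
    es = 0.5 * (saturation_vapour_pressure(tmax_c) + saturation_vapour_pressure(tmin_c))
    ea = rh_mean_pct / 100.0 * es
    delta = 4098.0 * saturation_vapour_pressure(tmean) / (tmean + 237.3) ** 2
    # Radiation balance.
    ws, ra = _solar_geometry(latitude_deg, doy)
    n_max = 24.0 / math.pi * ws
    rel_sun = 0.0 if n_max <= 0 else min(1.0, sunshine_h / n_max)
    rs = (angstrom_a + angstrom_b * rel_sun) * ra
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = (1.0 - albedo) * rs
    rel_rs = 1.0 if rso <= 0 else min(1.0, rs / rso)
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * ((tmax_c + 273.16) ** 4 + (tmin_c + 273.16) ** 4)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel_rs - 0.35)
    )
    rn = rns - rnl
    num = 0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * wind_2m_ms * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * wind_2m_ms)
    return max(0.0, num / den)


def water_stress_coefficient(
    field_depth_mm: float,
    root_zone_depletion_mm: float,
    taw_mm: float = 60.0,
    p: float = 0.2,
) -> float:
    """CROPWAT water-stress coefficient Ks in [0, 1].

    Ks = 1 while the field is ponded or the root-zone depletion Dr is below
    the readily-available fraction p*TAW; it then declines linearly to 0 at
    Dr = TAW.
    """
    if taw_mm <= 0:
        raise ValueError("TAW must be positive")
    if field_depth_mm > 0 or root_zone_depletion_mm <= p * taw_mm:
        return 1.0
    if root_zone_depletion_mm >= taw_mm:
        return 0.0
    return (taw_mm - root_zone_depletion_mm) / ((1.0 - p) * taw_mm)


def yield_loss(
    eta_by_stage: Sequence[float],
    etc_by_stage: Sequence[float],
    ky: Sequence[float] = StageYieldFactors().ky,
) -> float:
    """Seasonal relative yield loss (%) from stage-wise ET deficits.

    Per stage i the relative loss is Ky_i * (1 - ETa_i / ETc_i), clipped to
    [0, 1]; stages combine multiplicatively (CROPWAT convention):
    Ya/Yx = prod_i (1 - loss_i) and YL = (1 - Ya/Yx) * 100.
    """
    eta = np.asarray(eta_by_stage, dtype=float)
    etc = np.asarray(etc_by_stage, dtype=float)
    kyv = np.asarray(ky, dtype=float)
    if eta.shape != etc.shape or eta.shape != kyv.shape:
        raise ValueError("eta, etc and ky must have one entry per stage")
    if np.any(etc <= 0):
        raise ValueError("ETc must be positive in every stage")
    stage_loss = np.clip(kyv * (1.0 - eta / etc), 0.0, 1.0)
    relative_yield = float(np.prod(1.0 - stage_loss))
    return (1.0 - relative_yield) * 100.0
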
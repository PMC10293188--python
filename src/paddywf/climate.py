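"""Synthetic monsoonal daily weather and growing-season dryness classification.

A standard stochastic weather generator: wet/dry day occurrence follows a
first-order two-state Markov chain with month-specific transition
probabilities, wet-day rainfall amounts follow a month-specific gamma
distribution, and temperature / humidity / wind / sunshine are drawn around
month-specific means.  Years are 365 days (leap days are not generated).

Growing seasons are classified by the aridity index (season reference
evapotranspiration divided by season precipitation): index > 1 marks the
~25% dry class and index > 1.6 the ~5% extreme-dry class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cropwater import daylight_hours, reference_et0

__all__ = [
    "ClimateParams",
    "ClimateYearLabel",
    "MONTH_LENGTHS",
    "generate_daily_weather",
    "weather_to_csv",
    "weather_from_csv",
    "et0_series",
    "aridity_index",
    "seasonal_aridity_index",
    "classify_years",
    "no_rain_run",
    "NO_RAIN_THRESHOLD_MM",
]

#: Month lengths of the 365-day model year (no leap days).
MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
#: Month index (0-based) for each day-of-year 1..365.
_DOY_MONTH = np.repeat(np.arange(12), MONTH_LENGTHS)

#: Days with precipitation below this depth count as no-rain days (trace cutoff).
NO_RAIN_THRESHOLD_MM = 1.0

WEATHER_COLUMNS = ["date", "year", "doy", "precip_mm", "tmin_c", "tmax_c", "rh_pct", "wind_ms", "sunshine_h"]


def _check12(name: str, values: Sequence[float]) -> tuple[float, ...]:
    values = tuple(float(v) for v in values)
    if len(values) != 12:
        raise ValueError(f"{name} must have 12 monthly values")
    return values


@dataclass(frozen=True)
class ClimateParams:
    """Monthly climate normals and site constants driving the generator.

    All sequences hold one value per calendar month, January first.

    Parameters
    ----------
    monthly_rain_mm:
        Mean monthly rainfall totals, mm.
    wet_day_prob:
        Unconditional (stationary) probability that a day is wet, per month.
    wet_after_wet:
        Markov persistence p(wet | previous day wet), per month.
    tmin_c, tmax_c:
        Mean daily minimum / maximum temperature, degC.
    rh_pct, wind_ms, sunshine_h:
        Mean relative humidity (%), 2-m wind (m/s), bright sunshine (h/day).
    latitude_deg, elevation_m:
        Site coordinates for solar geometry and the psychrometric constant.
    season_start_doy, season_end_doy:
        Growing-season window (inclusive day-of-year bounds).
    gamma_shape:
        Shape parameter of the wet-day rainfall gamma distribution.
    """

    monthly_rain_mm: tuple[float, ...]
    wet_day_prob: tuple[float, ...]
    wet_after_wet: tuple[float, ...]
    tmin_c: tuple[float, ...]
    tmax_c: tuple[float, ...]
    rh_pct: tuple[float, ...]
    wind_ms: tuple[float, ...]
    sunshine_h: tuple[float, ...]
    latitude_deg: float
    elevation_m: float
    season_start_doy: int
    season_end_doy: int
    gamma_shape: float = 0.75

    def __post_init__(self) -> None:
        for name in ("monthly_rain_mm", "wet_day_prob", "wet_after_wet", "tmin_c",
                     "tmax_c", "rh_pct", "wind_ms", "sunshine_h"):
            object.__setattr__(self, name, _check12(name, getattr(self, name)))
        if any(p < 0 or p > 1 for p in self.wet_day_prob + self.wet_after_wet):
            raise ValueError("probabilities must be in [0, 1]")
        if any(r < 0 for r in self.monthly_rain_mm):
            raise ValueError("monthly rainfall must be >= 0")
        if any(hi < lo for lo, hi in zip(self.tmin_c, self.tmax_c)):
            raise ValueError("tmax must be >= tmin each month")
        if not 1 <= self.season_start_doy < self.season_end_doy <= 365:
            raise ValueError("growing-season window must satisfy 1 <= start < end <= 365")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    @property
    def season_length(self) -> int:
        return self.season_end_doy - self.season_start_doy + 1

    def wet_after_dry(self, month: int) -> float:
        """p(wet | previous day dry) consistent with the stationary wet prob."""
        pi = self.wet_day_prob[month]
        p11 = self.wet_after_wet[month]
        if pi >= 1.0:
            return 1.0
        return min(1.0, max(0.0, pi * (1.0 - p11) / (1.0 - pi)))


@dataclass(frozen=True)
class ClimateYearLabel:
    """Dryness class of one growing season."""

    aridity_index: float
    label: str  # "normal" | "dry25" | "extreme5"


def _classify_one(index: float) -> str:
    if index > 1.6:
        return "extreme5"
    if index > 1.0:
        return "dry25"
    return "normal"


def generate_daily_weather(params: ClimateParams, n_years: int, seed: int) -> pd.DataFrame:
    """Generate ``n_years`` of daily weather as a DataFrame.

    Columns: date (ISO-8601, synthetic calendar starting 2001), year (1-based),
    doy, precip_mm, tmin_c, tmax_c, rh_pct, wind_ms, sunshine_h.  The series
    is bit-identical for identical seed and parameters.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n_days = 365 * n_years
    month = np.tile(_DOY_MONTH, n_years)
    doy = np.tile(np.arange(1, 366), n_years)
    year = np.repeat(np.arange(1, n_years + 1), 365)

    # Wet/dry occurrence: first-order Markov chain (sequential by necessity).
    u = rng.random(n_days)
    wet = np.zeros(n_days, dtype=bool)
    prev = False
    p01 = [params.wet_after_dry(m) for m in range(12)]
    p11 = params.wet_after_wet
    wet_prob = params.wet_day_prob
    for i in range(n_days):
        m = month[i]
        p = p11[m] if prev else p01[m]
        if i % 365 == 0:
            p = wet_prob[m]  # reset at year boundaries keeps years exchangeable
        wet[i] = u[i] < p
        prev = wet[i]

    # Wet-day amounts: gamma with month-specific mean preserving monthly totals.
    mdays = np.array(MONTH_LENGTHS, dtype=float)
    mean_wet = np.array([
        params.monthly_rain_mm[m] / (wet_prob[m] * mdays[m]) if wet_prob[m] > 0 else 0.0
        for m in range(12)
    ])
    shape = params.gamma_shape
    scale = np.where(mean_wet > 0, mean_wet / shape, 0.0)
    amounts = rng.gamma(shape, 1.0, size=n_days) * scale[month]
    precip = np.where(wet, amounts, 0.0)

    # Temperature: shared daily anomaly plus independent jitter.
    anom = rng.normal(0.0, 1.5, n_days)
    tmin = np.array(params.tmin_c)[month] + anom + rng.normal(0.0, 0.8, n_days)
    tmax = np.array(params.tmax_c)[month] + anom + rng.normal(0.0, 0.8, n_days)
    tmax = np.maximum(tmax, tmin + 0.5)

    # Humidity is slightly higher on wet days.
    rh = np.array(params.rh_pct)[month] + np.where(wet, 4.0, -1.0) + rng.normal(0.0, 4.0, n_days)
    rh = np.clip(rh, 20.0, 100.0)

    wind = np.maximum(0.2, rng.normal(np.array(params.wind_ms)[month], 0.25 * np.array(params.wind_ms)[month]))

    # Sunshine: wet days are overcast; dry-day mean compensates so the
    # monthly mean is approximately preserved.
    sun_m = np.array(params.sunshine_h)[month]
    pi_m = np.array(wet_prob)[month]
    dry_mean = np.where(pi_m < 1.0, sun_m * (1.0 - 0.35 * pi_m) / (1.0 - pi_m + 1e-12), sun_m)
    sun = np.where(wet, 0.35 * sun_m, dry_mean) + rng.normal(0.0, 1.0, n_days)
    n_max = np.array([daylight_hours(params.latitude_deg, d) for d in range(1, 366)])
    sun = np.clip(sun, 0.0, np.tile(n_max, n_years))

    dates = _synthetic_dates(n_years)
    return pd.DataFrame({
        "date": dates,
        "year": year,
        "doy": doy,
        "precip_mm": precip,
        "tmin_c": np.round(tmin, 2),
        "tmax_c": np.round(tmax, 2),
        "rh_pct": np.round(rh, 1),
        "wind_ms": np.round(wind, 2),
        "sunshine_h": np.round(sun, 2),
    })


def _synthetic_dates(n_years: int, base_year: int = 2001) -> list[str]:
    dates = []
    for y in range(n_years):
        yy = base_year + y
        for m, ndays in enumerate(MONTH_LENGTHS, start=1):
            for d in range(1, ndays + 1):
                dates.append(f"{yy:04d}-{m:02d}-{d:02d}")
    return dates


def weather_to_csv(weather: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a weather series to CSV (optionally with a leading # comment)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        weather.to_csv(fh, index=False)


def weather_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def et0_series(weather: pd.DataFrame, latitude_deg: float, elevation_m: float) -> np.ndarray:
    """Daily FAO-56 reference evapotranspiration for every row of ``weather``."""
    out = np.empty(len(weather), dtype=float)
    doy = weather["doy"].to_numpy()
    tmin = weather["tmin_c"].to_numpy()
    tmax = weather["tmax_c"].to_numpy()
    rh = weather["rh_pct"].to_numpy()
    wind = weather["wind_ms"].to_numpy()
    sun = weather["sunshine_h"].to_numpy()
    for i in range(len(weather)):
        out[i] = reference_et0(tmin[i], tmax[i], rh[i], wind[i], sun[i],
                               int(doy[i]), latitude_deg, elevation_m)
    return out


def aridity_index(precip_mm: Sequence[float], et0_mm: Sequence[float]) -> float:
    """Aridity index of one window: sum(ET0) / sum(P).

    Returns ``inf`` (with a warning) when the window has zero precipitation.
    """
    p = float(np.sum(np.asarray(precip_mm, dtype=float)))
    e = float(np.sum(np.asarray(et0_mm, dtype=float)))
    if p <= 0:
        warnings.warn("zero precipitation in window: aridity index undefined (inf)",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return e / p


def seasonal_aridity_index(
    weather: pd.DataFrame,
    et0: Sequence[float],
    season: tuple[int, int],
) -> pd.Series:
    """Per-year aridity index over the growing-season window ``(start, end)``."""
    start, end = season
    if not start <= end:
        raise ValueError("season window must be non-empty")
    et0 = np.asarray(et0, dtype=float)
    if len(et0) != len(weather):
        raise ValueError("et0 must align with weather rows")
    mask = (weather["doy"] >= start) & (weather["doy"] <= end)
    sub = weather.loc[mask]
    grouped_p = sub.groupby("year")["precip_mm"].sum()
    grouped_e = pd.Series(et0[mask.to_numpy()], index=sub.index).groupby(sub["year"]).sum()
    out = {}
    for y in grouped_p.index:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[y] = aridity_index([grouped_p[y]], [grouped_e[y]])
    return pd.Series(out, name="aridity_index")


def classify_years(indices: Sequence[float]) -> list[ClimateYearLabel]:
    """Classify growing seasons by dryness.

    Thresholds follow the strict 'greater than' convention: index > 1 is the
    dry (25%) class, index > 1.6 the extreme-dry (5%) class; exact boundary
    values fall into the less-dry class.
    """
    out = []
    for x in indices:
        x = float(x)
        if not np.isfinite(x) and not np.isposinf(x):
            raise ValueError(f"aridity index must be finite or +inf, got {x}")
        out.append(ClimateYearLabel(aridity_index=x, label=_classify_one(x)))
    return out


def no_rain_run(weather: pd.DataFrame, day_index: int,
                threshold_mm: float = NO_RAIN_THRESHOLD_MM) -> int:
    """Consecutive no-rain days ending the day before ``day_index`` (0-based row).

    A day counts as no-rain when its precipitation is below ``threshold_mm``
    (trace cutoff, default 1 mm).
    """
    if not 0 <= day_index < len(weather):
        raise IndexError(f"day index {day_index} outside series of length {len(weather)}")
    precip = weather["precip_mm"].to_numpy()
    run = 0
    i = day_index - 1
    while i >= 0 and precip[i] < threshold_mm:
        run += 1
        i -= 1
    return run
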
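"""Shipped archetype presets: regional climates, province profiles, IDU builder.

Three climate archetypes emulate the monsoonal regimes of China's main rice
regions — NE (northeast, single season, ~41 N), CJ (Changjiang basin,
~30.5 N) and SE (southeast coastal, ~23 N) — with month-specific rainfall,
wet-day statistics and temperature/humidity/wind/sunshine normals chosen as
realistic climatological values for the archetype stations.  Province
profiles carry the ditch/pond area shares, management-style shares, the
probability-of-irrigation guarantee (PI) and statistical rice yields used by
the scenario engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .climate import ClimateParams
from .hydrology import IDUGeometry, ManagementStyle

__all__ = ["CLIMATE_PRESETS", "ProvinceProfile", "PROVINCE_PRESETS", "idu_geometry"]


CLIMATE_PRESETS: dict[str, ClimateParams] = {
    # Northeast (e.g. Liaoning): dry winters, July/August rainfall peak,
    # strong seasonal temperature cycle. Rice season late May - late Sep.
    "NE": ClimateParams(
        monthly_rain_mm=(5, 7, 15, 32, 52, 92, 168, 158, 68, 36, 16, 8),
        wet_day_prob=(0.08, 0.08, 0.12, 0.18, 0.25, 0.33, 0.42, 0.40, 0.28, 0.18, 0.12, 0.08),
        wet_after_wet=(0.30, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.55, 0.45, 0.40, 0.35, 0.30),
        tmin_c=(-15, -12, -4, 4, 11, 17, 21, 20, 13, 5, -4, -12),
        tmax_c=(-4, -1, 7, 16, 23, 27, 29, 28, 23, 15, 5, -2),
        rh_pct=(62, 60, 58, 58, 62, 72, 80, 80, 74, 66, 64, 63),
        wind_ms=(2.8, 3.0, 3.4, 3.8, 3.6, 3.0, 2.6, 2.4, 2.6, 3.0, 3.0, 2.8),
        sunshine_h=(6.5, 7.0, 7.5, 8.0, 8.5, 8.0, 6.5, 7.0, 7.5, 7.0, 6.0, 6.0),
        latitude_deg=41.1, elevation_m=5.0,
        season_start_doy=141, season_end_doy=260,  # late May - mid Sep, 120 d
    ),
    # Changjiang basin (e.g. Hubei): plum-rain early summer peak, hot humid
    # summers. One-season rice roughly mid June - mid Oct.
    "CJ": ClimateParams(
        monthly_rain_mm=(42, 56, 94, 134, 158, 200, 178, 126, 80, 76, 54, 34),
        wet_day_prob=(0.28, 0.30, 0.36, 0.40, 0.40, 0.42, 0.36, 0.30, 0.28, 0.28, 0.26, 0.24),
        wet_after_wet=(0.50, 0.52, 0.55, 0.58, 0.58, 0.60, 0.55, 0.50, 0.48, 0.48, 0.46, 0.45),
        tmin_c=(1, 3, 7, 13, 18, 22, 25, 25, 20, 14, 8, 3),
        tmax_c=(8, 10, 15, 22, 27, 30, 33, 33, 28, 22, 16, 10),
        rh_pct=(76, 76, 76, 76, 76, 78, 78, 78, 76, 76, 76, 75),
        wind_ms=(2.2, 2.4, 2.6, 2.6, 2.5, 2.4, 2.6, 2.4, 2.2, 2.1, 2.1, 2.1),
        sunshine_h=(3.5, 3.5, 4.0, 4.8, 5.5, 5.8, 7.5, 7.5, 5.8, 4.8, 4.2, 3.8),
        latitude_deg=30.5, elevation_m=30.0,
        season_start_doy=166, season_end_doy=285,  # mid Jun - mid Oct, 120 d
    ),
    # Southeast coastal (e.g. Guangdong): early and abundant monsoon, warm
    # year-round. Late-rice season roughly mid July - mid Nov.
    "SE": ClimateParams(
        monthly_rain_mm=(32, 48, 72, 150, 238, 296, 228, 220, 150, 62, 38, 28),
        wet_day_prob=(0.22, 0.28, 0.34, 0.42, 0.48, 0.52, 0.44, 0.46, 0.36, 0.22, 0.18, 0.18),
        wet_after_wet=(0.45, 0.50, 0.55, 0.60, 0.62, 0.65, 0.60, 0.60, 0.55, 0.45, 0.42, 0.42),
        tmin_c=(10, 12, 15, 19, 23, 25, 26, 26, 24, 20, 16, 12),
        tmax_c=(18, 19, 22, 26, 30, 32, 33, 33, 31, 28, 24, 20),
        rh_pct=(72, 78, 82, 84, 84, 84, 82, 82, 78, 72, 70, 68),
        wind_ms=(2.2, 2.2, 2.2, 2.1, 2.0, 2.2, 2.4, 2.2, 2.4, 2.6, 2.4, 2.2),
        sunshine_h=(4.0, 2.8, 2.5, 3.0, 4.5, 5.5, 7.0, 6.2, 5.8, 6.2, 5.5, 4.8),
        latitude_deg=23.1, elevation_m=10.0,
        season_start_doy=196, season_end_doy=315,  # mid Jul - mid Nov, 120 d
    ),
}


@dataclass(frozen=True)
class ProvinceProfile:
    """Province-level system composition used for upscaling.

    ``style_shares`` are the fractions of IDUs under each management style
    (summing to 1).  ``pond_bearing_pd1_frac`` is the fraction of PD1 IDUs
    that possess a (hydrologically isolated) pond and can be converted to QD
    by pond reconnection.  ``pi_pct`` is the probability-of-irrigation
    guarantee: remote freshwater supply is guaranteed up to that climatic
    percentile.  ``yield_t_ha`` is the statistical rice yield (dry matter).
    """

    region: str
    ditch_pct: float
    pond_pct: float
    style_shares: dict[str, float]
    pi_pct: float
    yield_t_ha: float
    pond_bearing_pd1_frac: float = 0.5
    climate: str = "CJ"

    def __post_init__(self) -> None:
        total = sum(self.style_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"style shares must sum to 1, got {total}")
        if any(v < 0 for v in self.style_shares.values()):
            raise ValueError("style shares must be >= 0")
        if self.ditch_pct < 0 or self.pond_pct < 0:
            raise ValueError("area percentages must be >= 0")

    @property
    def area_pct(self) -> float:
        """Ditch + pond area percentage of the system."""
        return self.ditch_pct + self.pond_pct

    def share(self, style: ManagementStyle | str) -> float:
        key = style.value if isinstance(style, ManagementStyle) else style
        return self.style_shares.get(key, 0.0)


#: Current-status archetype profiles: TC dominant (>60% of IDUs), QD marginal
#: (<5%); ditch+pond areas around the national ~6% average; PI per the
#: well-facilitated farmland construction plan (79/83/87%).
PROVINCE_PRESETS: dict[str, ProvinceProfile] = {
    "NE": ProvinceProfile(
        region="NE", ditch_pct=4.0, pond_pct=0.5,
        style_shares={"TC": 0.70, "PD1": 0.17, "PD2": 0.09, "QD": 0.04},
        pi_pct=79.0, yield_t_ha=8.5, climate="NE",
    ),
    "CJ": ProvinceProfile(
        region="CJ", ditch_pct=5.0, pond_pct=1.5,
        style_shares={"TC": 0.62, "PD1": 0.18, "PD2": 0.15, "QD": 0.05},
        pi_pct=87.0, yield_t_ha=8.0, climate="CJ",
    ),
    "SE": ProvinceProfile(
        region="SE", ditch_pct=4.8, pond_pct=1.2,
        style_shares={"TC": 0.64, "PD1": 0.16, "PD2": 0.15, "QD": 0.05},
        pi_pct=83.0, yield_t_ha=7.0, climate="SE",
    ),
}


def idu_geometry(profile: ProvinceProfile, style: ManagementStyle,
                 idu_area_ha: float = 20.0,
                 ditch_depth_m: float = 0.8,
                 pond_depth_m: float = 1.5) -> IDUGeometry:
    """Build a typical IDU geometry for one style from a province profile.

    The province's ditch area share applies to every IDU.  The pond area is
    concentrated in the pond-bearing IDUs (PD2, QD and the pond-bearing part
    of PD1) so that the system-wide pond share matches the profile; TC and
    PD1 geometries carry no pond (PD1 ponds are isolated from the system).
    """
    a_total = idu_area_ha * 1e4
    ditch_frac = profile.ditch_pct / 100.0
    pond_frac = 0.0
    if style.pond_in_drainage_path:
        bearing = (profile.share("PD2") + profile.share("QD")
                   + profile.share("PD1") * profile.pond_bearing_pd1_frac)
        if bearing > 0:
            pond_frac = min(0.12, (profile.pond_pct / 100.0) / bearing)
    field_frac = 1.0 - ditch_frac - pond_frac
    if field_frac <= 0:
        raise ValueError("ditch+pond area shares leave no field area")
    return IDUGeometry(
        field_area_m2=field_frac * a_total,
        ditch_area_m2=ditch_frac * a_total,
        pond_area_m2=pond_frac * a_total,
        ditch_depth_m=ditch_depth_m,
        pond_depth_m=pond_depth_m,
    )
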
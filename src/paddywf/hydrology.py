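"""Daily water balance of one paddy irrigation-drainage unit (IDU).

An IDU is a rice field, a drainage ditch, and (for some management styles)
a small pond, closed off by a weir at the outlet.  Each day the model applies
rainfall, crop evapotranspiration and percolation, irrigation triggered by a
stage-dependent water-level scheme, and surplus drainage routing: field
excess above the stage maximum flows into the ditch, ditch overflow into the
pond when the pond is in the drainage path, and final overflow leaves the
IDU.  Irrigation sourcing depends on the management style:

* TC  (totally centralized): remote freshwater only, no pond.
* PD1 (partly decentralized 1): ditch water prioritized, no pond.
* PD2 (partly decentralized 2): pond in drainage path, remote irrigation.
* QD  (quasi-decentralized): pond in drainage path and ditch+pond water
  prioritized for irrigation.

Field water is tracked with its source composition (rain / remote freshwater
/ local recycled) under perfect volume-weighted mixing, which downstream
modules use to split actual evapotranspiration into green, blue and
recycled components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from enum import Enum

import numpy as np

from .cropwater import water_stress_coefficient

__all__ = [
    "ManagementStyle",
    "IDUGeometry",
    "StageSpec",
    "WaterLevelScheme",
    "default_scheme",
    "HydroState",
    "DailyFluxes",
    "IrrigationLedger",
    "local_storage_volume",
    "irrigation_demand",
    "allocate_irrigation",
    "step_water_balance",
]

SOURCES = ("rain", "remote", "local")


class ManagementStyle(str, Enum):
    """IDU management style (how ditches and ponds are used)."""

    TC = "TC"
    PD1 = "PD1"
    PD2 = "PD2"
    QD = "QD"

    @property
    def pond_in_drainage_path(self) -> bool:
        return self in (ManagementStyle.PD2, ManagementStyle.QD)

    @property
    def local_irrigation_priority(self) -> bool:
        return self in (ManagementStyle.PD1, ManagementStyle.QD)


@dataclass(frozen=True)
class IDUGeometry:
    """Areas and depths of the IDU compartments.

    Ditch and pond percolation are zero by default (puddled/lined bottoms);
    field percolation is a constant daily rate while ponded.
    """

    field_area_m2: float
    ditch_area_m2: float
    pond_area_m2: float = 0.0
    ditch_depth_m: float = 0.8
    pond_depth_m: float = 1.5
    percolation_mm_day: float = 2.0

    def __post_init__(self) -> None:
        for name in ("field_area_m2", "ditch_area_m2", "pond_area_m2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.percolation_mm_day < 0:
            raise ValueError("percolation must be >= 0")

    @property
    def ditch_capacity_m3(self) -> float:
        return self.ditch_area_m2 * self.ditch_depth_m

    @property
    def pond_capacity_m3(self) -> float:
        return self.pond_area_m2 * self.pond_depth_m

    @property
    def storage_capacity_m3(self) -> float:
        """Combined ditch + pond storage capacity V_DP, m3."""
        return self.ditch_capacity_m3 + self.pond_capacity_m3


def local_storage_volume(geom: IDUGeometry) -> float:
    """Local storage volume LSV = V_DP * 1000 / A_F, in mm of field water.

    Expresses the ditch+pond capacity as an equivalent ponding depth over the
    field; the 35 mm and 55 mm marks separate low / medium / high storage
    classes.
    """
    if geom.field_area_m2 <= 0:
        raise ValueError("field area must be positive")
    return geom.storage_capacity_m3 * 1000.0 / geom.field_area_m2


@dataclass(frozen=True)
class StageSpec:
    """Water-level rules for one growth stage."""

    name: str
    length_days: int
    trigger_mm: float   # irrigate when ponding falls below this depth
    target_mm: float    # refill ponding to this depth
    max_mm: float       # drain ponding above this depth

    def __post_init__(self) -> None:
        if not (0 <= self.trigger_mm <= self.target_mm <= self.max_mm):
            raise ValueError("stage depths must satisfy trigger <= target <= max")
        if self.length_days <= 0:
            raise ValueError("stage length must be positive")


@dataclass(frozen=True)
class WaterLevelScheme:
    """Ordered growth stages plus scheduled drainage (field-drying) windows.

    Day-of-season (dos) is 0-based from transplanting.  During a drying
    window no irrigation is applied and any ponded water is drained.
    """

    stages: tuple[StageSpec, ...]
    drying_windows: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("at least one stage required")
        for a, b in self.drying_windows:
            if a > b:
                raise ValueError("drying window start must be <= end")

    @property
    def season_length(self) -> int:
        return sum(s.length_days for s in self.stages)

    def stage_index(self, dos: int) -> int:
        if dos < 0:
            raise ValueError("day of season must be >= 0")
        acc = 0
        for i, s in enumerate(self.stages):
            acc += s.length_days
            if dos < acc:
                return i
        return len(self.stages) - 1

    def stage(self, dos: int) -> StageSpec:
        return self.stages[self.stage_index(dos)]

    def in_drying_window(self, dos: int) -> bool:
        return any(a <= dos <= b for a, b in self.drying_windows)


def default_scheme(season_length: int = 120) -> WaterLevelScheme:
    """Shallow-ponding scheme representing normal farmer management.

    Stage lengths scale the canonical 20/30/40/30-day rice season; ponding is
    kept between a 10 mm trigger and a 40 mm target with drainage above
    60 mm; a ~7-day midseason drying spell ends the development stage, and
    the field is drained over the final week before harvest.
    """
    l = [round(season_length * f) for f in (20 / 120, 30 / 120, 40 / 120)]
    l.append(season_length - sum(l))
    stages = (
        StageSpec("initial", l[0], 10.0, 40.0, 60.0),
        StageSpec("development", l[1], 10.0, 40.0, 60.0),
        StageSpec("mid-season", l[2], 10.0, 40.0, 60.0),
        StageSpec("late-season", l[3], 5.0, 30.0, 60.0),
    )
    dry_start = l[0] + l[1] - 7
    drain_start = season_length - 7
    return WaterLevelScheme(
        stages=stages,
        drying_windows=((dry_start, dry_start + 6), (drain_start, season_length - 1)),
    )


@dataclass
class HydroState:
    """Mutable daily state of the IDU water stores.

    ``depth_mm`` is ponded water on the field; ``soil_deficit_mm`` is the
    root-zone depletion Dr (0 when saturated).  ``fractions`` partitions all
    field water (ponded + soil storage) by source (rain, remote, local).
    """

    depth_mm: float = 0.0
    soil_deficit_mm: float = 0.0
    ditch_m3: float = 0.0
    pond_m3: float = 0.0
    fractions: np.ndarray = dc_field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def copy(self) -> "HydroState":
        return HydroState(self.depth_mm, self.soil_deficit_mm, self.ditch_m3,
                          self.pond_m3, self.fractions.copy())


@dataclass
class IrrigationLedger:
    """Cumulative irrigation by source, mm over the field area."""

    i_local_mm: float = 0.0
    i_remote_mm: float = 0.0

    @property
    def i_all_mm(self) -> float:
        return self.i_local_mm + self.i_remote_mm


@dataclass
class DailyFluxes:
    """All water fluxes of one day plus sub-step volumes for mass tracking.

    Field fluxes are in mm over the field area; ditch/pond fluxes in m3.
    ``depth_*`` record the ponded depth after each sub-step so that the
    nutrient module can replay the day with consistent volumes.
    """

    et0_mm: float = 0.0
    etc_mm: float = 0.0
    eta_mm: float = 0.0
    eta_sources_mm: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    rain_mm: float = 0.0
    perc_mm: float = 0.0
    irr_demand_mm: float = 0.0
    irr_local_mm: float = 0.0
    irr_remote_mm: float = 0.0
    irr_unmet_mm: float = 0.0
    irr_from_ditch_m3: float = 0.0
    irr_from_pond_m3: float = 0.0
    field_to_ditch_m3: float = 0.0
    ditch_to_pond_m3: float = 0.0
    outflow_ditch_m3: float = 0.0
    outflow_pond_m3: float = 0.0
    rain_ditch_m3: float = 0.0
    rain_pond_m3: float = 0.0
    evap_ditch_m3: float = 0.0
    evap_pond_m3: float = 0.0
    # ponded depth (mm) after each sub-step
    depth_start_mm: float = 0.0
    depth_after_rain_mm: float = 0.0
    depth_after_et_mm: float = 0.0
    depth_after_perc_mm: float = 0.0
    depth_after_irr_mm: float = 0.0
    depth_end_mm: float = 0.0
    # ditch/pond volume (m3) at nutrient-relevant points
    ditch_after_evap_m3: float = 0.0
    ditch_before_overflow_m3: float = 0.0
    ditch_end_m3: float = 0.0
    pond_after_evap_m3: float = 0.0
    pond_before_overflow_m3: float = 0.0
    pond_end_m3: float = 0.0

    @property
    def outflow_m3(self) -> float:
        return self.outflow_ditch_m3 + self.outflow_pond_m3


def irrigation_demand(state: HydroState, scheme: WaterLevelScheme, dos: int) -> float:
    """Irrigation demand (mm) under the water-level scheme.

    Demand refills to the stage target when ponding is below the stage
    trigger, and additionally replaces any root-zone deficit; it is zero
    inside scheduled drying windows.
    """
    if scheme.in_drying_window(dos):
        return 0.0
    st = scheme.stage(dos)
    if state.depth_mm < st.trigger_mm:
        return (st.target_mm - state.depth_mm) + state.soil_deficit_mm
    return 0.0


def allocate_irrigation(
    demand_mm: float,
    style: ManagementStyle,
    state: HydroState,
    geom: IDUGeometry,
    freshwater_cap_mm: float = math.inf,
) -> tuple[float, float, float, float]:
    """Split an irrigation demand between local storage and remote freshwater.

    Returns ``(from_ditch_mm, from_pond_mm, from_remote_mm, unmet_mm)``.
    Local-priority styles (PD1, QD) draw the ditch first (QD also the pond);
    TC and PD2 use remote freshwater only.  Remote supply is limited by
    ``freshwater_cap_mm`` (the remaining seasonal allowance).
    """
    if demand_mm < 0:
        raise ValueError("demand must be >= 0")
    from_ditch = from_pond = 0.0
    remaining = demand_mm
    if style.local_irrigation_priority and geom.field_area_m2 > 0:
        ditch_avail_mm = state.ditch_m3 * 1000.0 / geom.field_area_m2
        from_ditch = min(remaining, ditch_avail_mm)
        remaining -= from_ditch
        if style is ManagementStyle.QD and remaining > 0:
            pond_avail_mm = state.pond_m3 * 1000.0 / geom.field_area_m2
            from_pond = min(remaining, pond_avail_mm)
            remaining -= from_pond
    from_remote = min(remaining, freshwater_cap_mm)
    unmet = remaining - from_remote
    return from_ditch, from_pond, from_remote, unmet


def _mix_in(state: HydroState, total_mm: float, add_mm: float, source_idx: int) -> None:
    """Volume-weighted mixing of ``add_mm`` of one source into the field water."""
    if add_mm <= 0:
        return
    new_total = total_mm + add_mm
    e = np.zeros(3)
    e[source_idx] = 1.0
    state.fractions = (state.fractions * total_mm + e * add_mm) / new_total
    s = state.fractions.sum()
    if s > 0:
        state.fractions /= s


def step_water_balance(
    state: HydroState,
    precip_mm: float,
    et0_mm: float,
    dos: int,
    geom: IDUGeometry,
    scheme: WaterLevelScheme,
    style: ManagementStyle,
    kc: float,
    *,
    taw_mm: float = 60.0,
    p_depletion: float = 0.2,
    open_water_kc: float = 1.05,
    freshwater_cap_mm: float = math.inf,
) -> tuple[HydroState, DailyFluxes]:
    """Advance the IDU one day: rain, ET/percolation, irrigation, drainage.

    Returns a new state and the day's fluxes.  ``freshwater_cap_mm`` is the
    remote-freshwater still available this season (infinite in normal years).
    Water is conserved exactly: rain + irrigation - ETa - percolation -
    outflow equals the change of (ponded + soil + ditch + pond) storage.
    """
    if any(map(math.isnan, (precip_mm, et0_mm))):
        raise ValueError("NaN weather inputs")
    s = state.copy()
    f = DailyFluxes(et0_mm=et0_mm, rain_mm=precip_mm, depth_start_mm=s.depth_mm)
    a_f = geom.field_area_m2

    # --- rain ---------------------------------------------------------------
    field_water = s.depth_mm + (taw_mm - s.soil_deficit_mm)
    _mix_in(s, field_water, precip_mm, 0)
    fill = min(s.soil_deficit_mm, precip_mm)
    s.soil_deficit_mm -= fill
    s.depth_mm += precip_mm - fill
    f.depth_after_rain_mm = s.depth_mm
    f.rain_ditch_m3 = precip_mm / 1000.0 * geom.ditch_area_m2
    f.rain_pond_m3 = precip_mm / 1000.0 * geom.pond_area_m2
    s.ditch_m3 += f.rain_ditch_m3
    s.pond_m3 += f.rain_pond_m3

    # --- crop ET and percolation -------------------------------------------
    etc = kc * et0_mm
    f.etc_mm = etc
    from_ponded = min(s.depth_mm, etc)
    s.depth_mm -= from_ponded
    rem = etc - from_ponded
    eta_soil = 0.0
    if rem > 0:
        ks = water_stress_coefficient(s.depth_mm, s.soil_deficit_mm, taw_mm, p_depletion)
        eta_soil = min(ks * rem, taw_mm - s.soil_deficit_mm)
        s.soil_deficit_mm += eta_soil
    f.eta_mm = from_ponded + eta_soil
    f.eta_sources_mm = f.eta_mm * s.fractions.copy()
    f.depth_after_et_mm = s.depth_mm

    if s.depth_mm > 0:
        f.perc_mm = min(s.depth_mm, geom.percolation_mm_day)
        s.depth_mm -= f.perc_mm
    f.depth_after_perc_mm = s.depth_mm

    f.evap_ditch_m3 = min(s.ditch_m3, open_water_kc * et0_mm / 1000.0 * geom.ditch_area_m2)
    s.ditch_m3 -= f.evap_ditch_m3
    f.evap_pond_m3 = min(s.pond_m3, open_water_kc * et0_mm / 1000.0 * geom.pond_area_m2)
    s.pond_m3 -= f.evap_pond_m3
    f.ditch_after_evap_m3 = s.ditch_m3
    f.pond_after_evap_m3 = s.pond_m3

    # --- irrigation ---------------------------------------------------------
    demand = irrigation_demand(s, scheme, dos)
    f.irr_demand_mm = demand
    if demand > 0:
        from_ditch, from_pond, from_remote, unmet = allocate_irrigation(
            demand, style, s, geom, freshwater_cap_mm)
        f.irr_from_ditch_m3 = from_ditch * a_f / 1000.0
        f.irr_from_pond_m3 = from_pond * a_f / 1000.0
        s.ditch_m3 = max(0.0, s.ditch_m3 - f.irr_from_ditch_m3)
        s.pond_m3 = max(0.0, s.pond_m3 - f.irr_from_pond_m3)
        f.irr_local_mm = from_ditch + from_pond
        f.irr_remote_mm = from_remote
        f.irr_unmet_mm = unmet
        applied = f.irr_local_mm + f.irr_remote_mm
        field_water = s.depth_mm + (taw_mm - s.soil_deficit_mm)
        _mix_in(s, field_water, f.irr_local_mm, 2)
        _mix_in(s, field_water + f.irr_local_mm, f.irr_remote_mm, 1)
        fill = min(s.soil_deficit_mm, applied)
        s.soil_deficit_mm -= fill
        s.depth_mm += applied - fill
    f.depth_after_irr_mm = s.depth_mm

    # --- drainage and routing ----------------------------------------------
    if scheme.in_drying_window(dos):
        excess = s.depth_mm
    else:
        excess = max(0.0, s.depth_mm - scheme.stage(dos).max_mm)
    if excess > 0:
        f.field_to_ditch_m3 = excess * a_f / 1000.0
        s.depth_mm -= excess
        s.ditch_m3 += f.field_to_ditch_m3
    f.depth_end_mm = s.depth_mm
    f.ditch_before_overflow_m3 = s.ditch_m3

    over = max(0.0, s.ditch_m3 - geom.ditch_capacity_m3)
    if over > 0:
        s.ditch_m3 = geom.ditch_capacity_m3
        if style.pond_in_drainage_path and geom.pond_capacity_m3 > 0:
            to_pond = min(over, max(0.0, geom.pond_capacity_m3 - s.pond_m3))
            f.ditch_to_pond_m3 = to_pond
            s.pond_m3 += to_pond
            f.outflow_ditch_m3 = over - to_pond
        else:
            f.outflow_ditch_m3 = over
    f.pond_before_overflow_m3 = s.pond_m3
    over_p = max(0.0, s.pond_m3 - geom.pond_capacity_m3)
    if over_p > 0:
        s.pond_m3 = geom.pond_capacity_m3
        f.outflow_pond_m3 = over_p
    f.ditch_end_m3 = s.ditch_m3
    f.pond_end_m3 = s.pond_m3
    return s, f
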
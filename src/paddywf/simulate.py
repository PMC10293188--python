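"""Growing-season simulation of one IDU: hydrology, nutrients, yield response.

The hydrology of a season is independent of the nutrient-retention
parameters, so it is simulated once per (IDU, year) and the nutrient mass
balance is then replayed cheaply for each Monte-Carlo parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accounting import SeasonTotals
from .cropwater import StageYieldFactors, yield_loss
from .hydrology import (DailyFluxes, HydroState, IDUGeometry, IrrigationLedger,
                        ManagementStyle, WaterLevelScheme, default_scheme,
                        local_storage_volume, step_water_balance)
from .nutrients import ConcState, DailyLoads, FertilizationEvent, NutrientParams, step_nutrient

__all__ = ["CropParams", "IDUConfig", "HydroSeason", "NutrientSeason",
           "default_fertilization", "run_hydrology_season", "run_nutrient_season",
           "season_totals", "simulate_season"]


@dataclass(frozen=True)
class CropParams:
    """Crop coefficients, yield-response factors and the paddy soil store."""

    factors: StageYieldFactors = StageYieldFactors()
    taw_mm: float = 60.0     # total available soil water after ponding is gone
    p_depletion: float = 0.2  # readily-available fraction for rice


@dataclass(frozen=True)
class IDUConfig:
    """Full configuration of one IDU simulation."""

    geometry: IDUGeometry
    style: ManagementStyle
    scheme: WaterLevelScheme
    crop: CropParams = CropParams()
    fert_events: tuple[FertilizationEvent, ...] = ()
    field_decay_per_day: float = 0.15
    open_water_kc: float = 1.05


def default_fertilization() -> tuple[FertilizationEvent, ...]:
    """Basal, tillering and panicle dressings with typical floodwater
    concentrations observed after fertilization (mg/L)."""
    return (
        FertilizationEvent(1, 25.0, 1.5),
        FertilizationEvent(30, 15.0, 0.5),
        FertilizationEvent(65, 12.0, 0.3),
    )


@dataclass
class HydroSeason:
    """Hydrology outcome of one simulated growing season."""

    fluxes: list[DailyFluxes]
    ledger: IrrigationLedger
    eta_sources_mm: np.ndarray          # (rain, remote, local) totals
    stage_eta_mm: np.ndarray            # per growth stage
    stage_etc_mm: np.ndarray
    outflow_m3: float = 0.0
    unmet_mm: float = 0.0
    final_state: HydroState | None = None

    @property
    def eta_mm(self) -> float:
        return float(self.eta_sources_mm.sum())

    def yield_loss_pct(self, factors: StageYieldFactors = StageYieldFactors()) -> float:
        return yield_loss(self.stage_eta_mm, self.stage_etc_mm, factors.ky)

    def daily_frame(self) -> pd.DataFrame:
        rows = []
        for dos, f in enumerate(self.fluxes):
            rows.append({
                "dos": dos, "rain_mm": f.rain_mm, "et0_mm": f.et0_mm,
                "etc_mm": f.etc_mm, "eta_mm": f.eta_mm,
                "eta_green_mm": f.eta_sources_mm[0],
                "eta_blue_mm": f.eta_sources_mm[1],
                "eta_recycled_mm": f.eta_sources_mm[2],
                "perc_mm": f.perc_mm, "irr_local_mm": f.irr_local_mm,
                "irr_remote_mm": f.irr_remote_mm, "irr_unmet_mm": f.irr_unmet_mm,
                "field_to_ditch_m3": f.field_to_ditch_m3,
                "ditch_to_pond_m3": f.ditch_to_pond_m3,
                "outflow_m3": f.outflow_m3, "depth_mm": f.depth_end_mm,
                "ditch_m3": f.ditch_end_m3, "pond_m3": f.pond_end_m3,
            })
        return pd.DataFrame(rows)


@dataclass
class NutrientSeason:
    """Nutrient outcome of one season for one parameter set (kg/ha)."""

    runoff_n_kg_ha: float
    runoff_p_kg_ha: float
    leach_n_kg_ha: float
    leach_p_kg_ha: float
    retention_n_kg_ha: float
    retention_p_kg_ha: float
    field_decay_n_kg_ha: float
    field_decay_p_kg_ha: float
    fert_input_n_kg_ha: float
    fert_input_p_kg_ha: float
    storage_delta_n_kg_ha: float
    storage_delta_p_kg_ha: float


def run_hydrology_season(
    season_weather: pd.DataFrame,
    et0: np.ndarray,
    config: IDUConfig,
    freshwater_cap_mm: float = math.inf,
) -> HydroSeason:
    """Simulate the water balance over one growing season.

    ``season_weather`` holds one row per day of the season (column
    ``precip_mm``); ``et0`` is the aligned reference-ET series.  The field
    starts drained and saturated; ditch and pond start empty.
    ``freshwater_cap_mm`` is the seasonal remote-supply allowance.
    """
    n_days = len(season_weather)
    if len(et0) != n_days:
        raise ValueError("et0 must align with the season weather")
    scheme = config.scheme
    n_stages = len(scheme.stages)
    state = HydroState()
    ledger = IrrigationLedger()
    fluxes: list[DailyFluxes] = []
    eta_sources = np.zeros(3)
    stage_eta = np.zeros(n_stages)
    stage_etc = np.zeros(n_stages)
    outflow = 0.0
    unmet = 0.0
    remote_left = freshwater_cap_mm
    precip = season_weather["precip_mm"].to_numpy()
    kc = config.crop.factors.kc
    for dos in range(n_days):
        st = scheme.stage_index(dos)
        state, f = step_water_balance(
            state, float(precip[dos]), float(et0[dos]), dos,
            config.geometry, scheme, config.style, kc[st],
            taw_mm=config.crop.taw_mm, p_depletion=config.crop.p_depletion,
            open_water_kc=config.open_water_kc, freshwater_cap_mm=remote_left,
        )
        remote_left -= f.irr_remote_mm
        ledger.i_local_mm += f.irr_local_mm
        ledger.i_remote_mm += f.irr_remote_mm
        eta_sources += f.eta_sources_mm
        stage_eta[st] += f.eta_mm
        stage_etc[st] += f.etc_mm
        outflow += f.outflow_m3
        unmet += f.irr_unmet_mm
        fluxes.append(f)
    return HydroSeason(fluxes=fluxes, ledger=ledger, eta_sources_mm=eta_sources,
                       stage_eta_mm=stage_eta, stage_etc_mm=stage_etc,
                       outflow_m3=outflow, unmet_mm=unmet, final_state=state)


def run_nutrient_season(
    hydro: HydroSeason,
    params: NutrientParams,
    config: IDUConfig,
) -> NutrientSeason:
    """Replay the season's nutrient mass balance for one parameter set."""
    events = {e.day_of_season: e for e in config.fert_events}
    conc = ConcState()
    start_n, start_p = conc.total_n(), conc.total_p()
    acc = DailyLoads()
    for dos, f in enumerate(hydro.fluxes):
        conc, loads = step_nutrient(
            conc, f, params, config.geometry,
            field_decay_per_day=config.field_decay_per_day,
            fert_event=events.get(dos),
        )
        for name in vars(acc):
            setattr(acc, name, getattr(acc, name) + getattr(loads, name))
    to_kg_ha = 10.0 / config.geometry.field_area_m2  # g -> kg/ha over the field
    return NutrientSeason(
        runoff_n_kg_ha=acc.runoff_n_g * to_kg_ha,
        runoff_p_kg_ha=acc.runoff_p_g * to_kg_ha,
        leach_n_kg_ha=acc.leach_n_g * to_kg_ha,
        leach_p_kg_ha=acc.leach_p_g * to_kg_ha,
        retention_n_kg_ha=acc.retention_n_g * to_kg_ha,
        retention_p_kg_ha=acc.retention_p_g * to_kg_ha,
        field_decay_n_kg_ha=acc.field_decay_n_g * to_kg_ha,
        field_decay_p_kg_ha=acc.field_decay_p_g * to_kg_ha,
        fert_input_n_kg_ha=acc.fert_input_n_g * to_kg_ha,
        fert_input_p_kg_ha=acc.fert_input_p_g * to_kg_ha,
        storage_delta_n_kg_ha=(conc.total_n() - start_n) * to_kg_ha,
        storage_delta_p_kg_ha=(conc.total_p() - start_p) * to_kg_ha,
    )


def season_totals(hydro: HydroSeason, nutr: NutrientSeason, config: IDUConfig,
                  yield_t_ha: float) -> SeasonTotals:
    """Assemble the per-season ledger used by the accounting module."""
    return SeasonTotals(
        yield_t_ha=yield_t_ha,
        l_runoff_n_kg_ha=nutr.runoff_n_kg_ha,
        l_runoff_p_kg_ha=nutr.runoff_p_kg_ha,
        l_leach_n_kg_ha=nutr.leach_n_kg_ha,
        l_leach_p_kg_ha=nutr.leach_p_kg_ha,
        eta_green_mm=float(hydro.eta_sources_mm[0]),
        eta_blue_mm=float(hydro.eta_sources_mm[1]),
        eta_recycled_mm=float(hydro.eta_sources_mm[2]),
        i_local_mm=hydro.ledger.i_local_mm,
        i_remote_mm=hydro.ledger.i_remote_mm,
        lsv_mm=local_storage_volume(config.geometry),
        yield_loss_pct=hydro.yield_loss_pct(config.crop.factors),
    )


def simulate_season(
    season_weather: pd.DataFrame,
    et0: np.ndarray,
    config: IDUConfig,
    params: NutrientParams,
    yield_t_ha: float,
    freshwater_cap_mm: float = math.inf,
) -> tuple[SeasonTotals, HydroSeason, NutrientSeason]:
    """One-call simulation of a season for a single parameter set."""
    hydro = run_hydrology_season(season_weather, et0, config, freshwater_cap_mm)
    nutr = run_nutrient_season(hydro, params, config)
    return season_totals(hydro, nutr, config, yield_t_ha), hydro, nutr
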
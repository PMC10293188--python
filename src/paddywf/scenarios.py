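"""Monte-Carlo ensembles, dry-year freshwater restriction and the redesign
scenario ladder.

The engine simulates the four IDU management styles over an ensemble of
synthetic climate years crossed with Monte-Carlo nutrient-retention
parameter sets, aggregates styles by their province shares, and evaluates
the redesign ladder:

* RI (recycling irrigation): prioritize retained ditch/pond water for
  irrigation — moves TC shares to PD1 and PD2 shares to QD.
* PR (pond reconnection): reconnect isolated ponds into drainage pathways —
  moves pond-bearing PD1 shares to QD.
* PC (pond construction): dig/dredge ponds until the ditch+pond area share
  reaches a target (capped at 8%, the maximum allowed by farmland
  construction standards), converting field area.

Remote freshwater is guaranteed only up to the province's
probability-of-irrigation (PI) percentile; in climatically drier years the
seasonal remote supply is capped at the district's guaranteed capability
(the PI-percentile of the fully-remote demand distribution), which can
induce crop water stress and yield loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .accounting import irrigation_self_sufficiency, wf_result
from .climate import generate_daily_weather, et0_series, seasonal_aridity_index
from .hydrology import ManagementStyle
from .nutrients import sample_retention_params
from .presets import CLIMATE_PRESETS, ProvinceProfile, idu_geometry
from .simulate import (IDUConfig, default_fertilization, run_hydrology_season,
                       run_nutrient_season, season_totals)
from .hydrology import default_scheme

__all__ = ["ScenarioSpec", "EnsembleSummary", "EnsembleResult", "apply_scenario",
           "current_spec", "restrict_freshwater", "land_tradeoff", "run_ensemble",
           "scenario_ladder", "METRICS"]

MAX_AREA_PCT = 8.0  # ditch+pond area cap (farmland construction standard)

METRICS = ["wf_green", "wf_blue", "wf_gray", "wf_recycled", "wf_total",
           "iss_pct", "yl_pct", "tn_load_kg_ha", "tp_load_kg_ha"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One point on the easy-to-difficult redesign ladder.

    ``ri_pct``: target share (%) of IDUs practicing recycling irrigation
    (PD1 + QD).  ``pr_pct``: target share (%) of existing ponds connected
    for irrigation and drainage.  ``area_pct``: target ditch+pond area share
    (%), at most 8; ``None`` leaves the current area unchanged.
    """

    ri_pct: float = 0.0
    pr_pct: float = 0.0
    area_pct: float | None = None
    index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ri_pct <= 100 or not 0 <= self.pr_pct <= 100:
            raise ValueError("RI and PR targets must be percentages in [0, 100]")
        if self.area_pct is not None and not 0 <= self.area_pct <= MAX_AREA_PCT:
            raise ValueError(f"area target must be <= {MAX_AREA_PCT}%")


def current_spec(profile: ProvinceProfile) -> ScenarioSpec:
    """The ScenarioSpec matching the profile's current status (identity)."""
    ri = (profile.share("PD1") + profile.share("QD")) * 100.0
    bearing = (profile.share("PD2") + profile.share("QD")
               + profile.share("PD1") * profile.pond_bearing_pd1_frac)
    connected = profile.share("PD2") + profile.share("QD")
    pr = 100.0 * connected / bearing if bearing > 0 else 0.0
    return ScenarioSpec(ri_pct=ri, pr_pct=pr, area_pct=None, index=0)


def apply_scenario(profile: ProvinceProfile, spec: ScenarioSpec) -> tuple[ProvinceProfile, float]:
    """Apply a redesign scenario to a province profile.

    Returns the modified profile and the field-area percentage converted to
    new ponds by pond construction (0 for RI/PR-only scenarios).  Shares
    only ever move toward more decentralized styles; targets below the
    current status leave the profile unchanged.
    """
    shares = dict(profile.style_shares)
    bearing_pd1 = shares.get("PD1", 0.0) * profile.pond_bearing_pd1_frac

    # RI: TC -> PD1 and PD2 -> QD, proportionally, until PD1+QD reaches target.
    current_ri = shares.get("PD1", 0.0) + shares.get("QD", 0.0)
    deficit = max(0.0, spec.ri_pct / 100.0 - current_ri)
    movable = shares.get("TC", 0.0) + shares.get("PD2", 0.0)
    if deficit > 0 and movable > 0:
        move = min(deficit, movable)
        move_tc = move * shares.get("TC", 0.0) / movable
        move_pd2 = move * shares.get("PD2", 0.0) / movable
        shares["TC"] = shares.get("TC", 0.0) - move_tc
        shares["PD1"] = shares.get("PD1", 0.0) + move_tc
        shares["PD2"] = shares.get("PD2", 0.0) - move_pd2
        shares["QD"] = shares.get("QD", 0.0) + move_pd2
        # Pond-bearing PD1 share grows only through reconnection, not RI; the
        # TC IDUs moved in have no ponds, so the bearing fraction dilutes.
        new_pd1 = shares["PD1"]
        bearing_frac = bearing_pd1 / new_pd1 if new_pd1 > 0 else 0.0
    else:
        bearing_frac = profile.pond_bearing_pd1_frac

    # PR: pond-bearing PD1 -> QD until the connected-pond share hits target.
    pd1_bearing = shares.get("PD1", 0.0) * bearing_frac
    total_bearing = shares.get("PD2", 0.0) + shares.get("QD", 0.0) + pd1_bearing
    if total_bearing > 0:
        connected = shares.get("PD2", 0.0) + shares.get("QD", 0.0)
        need = max(0.0, spec.pr_pct / 100.0 * total_bearing - connected)
        move = min(need, pd1_bearing)
        if move > 0:
            shares["PD1"] -= move
            shares["QD"] = shares.get("QD", 0.0) + move
            pd1_bearing -= move
            bearing_frac = pd1_bearing / shares["PD1"] if shares["PD1"] > 0 else 0.0

    # PC: raise pond area until ditch+pond reaches the target (fields convert).
    pond_pct = profile.pond_pct
    converted_field_pct = 0.0
    if spec.area_pct is not None:
        add = max(0.0, spec.area_pct - profile.area_pct)
        pond_pct += add
        converted_field_pct = add

    new_profile = replace(profile, style_shares=shares, pond_pct=pond_pct,
                          pond_bearing_pd1_frac=bearing_frac)
    return new_profile, converted_field_pct


def restrict_freshwater(year_aridity_rank_pct: float, pi_pct: float,
                        demand_series_mm: np.ndarray) -> float:
    """Seasonal remote-freshwater cap (mm) for one year.

    Years at or below the PI percentile of aridity have unrestricted supply;
    drier years are capped at the demand level of the PI-percentile year of
    the fully-remote demand distribution.
    """
    if not 0 <= year_aridity_rank_pct <= 100:
        raise ValueError("rank must be a percentile in [0, 100]")
    if year_aridity_rank_pct <= pi_pct:
        return math.inf
    return float(np.percentile(np.asarray(demand_series_mm, dtype=float), pi_pct))


def land_tradeoff(added_pond_frac: float, profile: ProvinceProfile) -> tuple[float, float]:
    """Land occupation of pond construction.

    ``added_pond_frac`` is the new pond area as a fraction of the system
    area.  Assuming all new ponds are converted from paddy fields, returns
    (percent of current fields occupied, percent change of rice production).
    """
    if added_pond_frac < 0:
        raise ValueError("added pond area must be >= 0")
    field_frac = 1.0 - profile.area_pct / 100.0
    if added_pond_frac > field_frac:
        raise ValueError("added pond area exceeds the available field area")
    occupied_pct = added_pond_frac / field_frac * 100.0
    return occupied_pct, -occupied_pct


@dataclass
class EnsembleSummary:
    """Distribution summary of ensemble metrics."""

    stats: pd.DataFrame  # index: metric; columns: mean, median, q05, q25, q75, q95
    run_count: int

    def mean(self, metric: str) -> float:
        return float(self.stats.loc[metric, "mean"])


@dataclass
class EnsembleResult:
    """Per-run table plus per-style tables and the aggregated summary."""

    runs: pd.DataFrame            # share-weighted province-level records
    style_runs: dict[str, pd.DataFrame]
    summary: EnsembleSummary
    freshwater_cap_mm: float
    restricted_years: list[int]


def _summarize(runs: pd.DataFrame) -> EnsembleSummary:
    rows = {}
    for m in METRICS:
        v = runs[m].to_numpy()
        rows[m] = {
            "mean": float(np.mean(v)), "median": float(np.median(v)),
            "q05": float(np.percentile(v, 5)), "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)), "q95": float(np.percentile(v, 95)),
        }
    return EnsembleSummary(stats=pd.DataFrame(rows).T, run_count=len(runs))


def run_ensemble(
    profile: ProvinceProfile,
    spec: ScenarioSpec | None = None,
    *,
    n_years: int = 30,
    n_param_sets: int = 10,
    seed: int = 0,
    restrict: bool = True,
    idu_area_ha: float = 20.0,
    scheme=None,
    fert_events=None,
) -> EnsembleResult:
    """Simulate the style ensemble for one province under one scenario.

    Weather years x parameter sets are simulated per management style
    (hydrology once per year, nutrients per parameter set) and aggregated
    deterministically by the style shares.  When ``restrict`` is set, years
    whose growing-season aridity rank exceeds the province PI get their
    seasonal remote supply capped at the district capability, producing
    water stress and yield loss.
    """
    if n_years < 1 or n_param_sets < 1:
        raise ValueError("ensemble counts must be >= 1")
    eff_profile = profile
    if spec is not None:
        eff_profile, _ = apply_scenario(profile, spec)

    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    climate = CLIMATE_PRESETS[eff_profile.climate]
    weather = generate_daily_weather(climate, n_years, int(seeds[0]))
    et0 = et0_series(weather, climate.latitude_deg, climate.elevation_m)
    season = (climate.season_start_doy, climate.season_end_doy)
    mask = (weather["doy"] >= season[0]) & (weather["doy"] <= season[1])
    years = sorted(weather["year"].unique())
    season_by_year = {
        y: (weather.loc[mask & (weather["year"] == y)].reset_index(drop=True),
            et0[(mask & (weather["year"] == y)).to_numpy()])
        for y in years
    }
    aridity = seasonal_aridity_index(weather, et0, season)
    ranks = aridity.rank(pct=True) * 100.0

    params = sample_retention_params(n_param_sets, int(seeds[1]))
    scheme = scheme or default_scheme(climate.season_length)
    fert = tuple(fert_events) if fert_events is not None else default_fertilization()

    styles = [s for s in ManagementStyle if eff_profile.share(s) > 0]
    configs = {
        s: IDUConfig(geometry=idu_geometry(eff_profile, s, idu_area_ha),
                     style=s, scheme=scheme, fert_events=fert)
        for s in styles
    }

    # Pass 1: unrestricted hydrology; the fully-remote (TC-equivalent) demand
    # defines the district supply capability.
    hydro = {s: {y: run_hydrology_season(*season_by_year[y], configs[s]) for y in years}
             for s in styles}
    ref_style = styles[0]
    total_demand = np.array([hydro[ref_style][y].ledger.i_all_mm for y in years])
    cap = float(np.percentile(total_demand, eff_profile.pi_pct))

    restricted_years: list[int] = []
    if restrict:
        for y in years:
            if ranks[y] > eff_profile.pi_pct:
                restricted_years.append(y)
                for s in styles:
                    hydro[s][y] = run_hydrology_season(*season_by_year[y], configs[s],
                                                       freshwater_cap_mm=cap)

    # Pass 2: nutrient replays per parameter set; style-level records.
    style_rows: dict[str, list[dict]] = {s.value: [] for s in styles}
    for s in styles:
        for y in years:
            h = hydro[s][y]
            for k, p in enumerate(params):
                nutr = run_nutrient_season(h, p, configs[s])
                totals = season_totals(h, nutr, configs[s], eff_profile.yield_t_ha)
                wf = wf_result(totals)
                style_rows[s.value].append({
                    "year": y, "param_set": k,
                    "wf_green": wf.green, "wf_blue": wf.blue, "wf_gray": wf.gray,
                    "wf_recycled": wf.recycled, "wf_total": wf.total,
                    "i_local_mm": totals.i_local_mm, "i_all_mm": totals.i_all_mm,
                    "iss_pct": irrigation_self_sufficiency(totals.i_local_mm, totals.i_all_mm),
                    "yl_pct": totals.yield_loss_pct,
                    "tn_load_kg_ha": totals.l_runoff_n_kg_ha + totals.l_leach_n_kg_ha,
                    "tp_load_kg_ha": totals.l_runoff_p_kg_ha + totals.l_leach_p_kg_ha,
                })
    style_frames = {k: pd.DataFrame(v) for k, v in style_rows.items()}

    # Share-weighted aggregation (deterministic expectation over styles).
    weights = {s.value: eff_profile.share(s) for s in styles}
    wsum = sum(weights.values())
    agg = None
    for k, frame in style_frames.items():
        w = weights[k] / wsum
        part = frame.drop(columns=["year", "param_set"]) * w
        agg = part if agg is None else agg + part
    agg = agg.copy()
    agg.insert(0, "year", style_frames[styles[0].value]["year"])
    agg.insert(1, "param_set", style_frames[styles[0].value]["param_set"])
    # ISS of the aggregate system from the aggregated volumes.
    agg["iss_pct"] = np.where(agg["i_all_mm"] > 0,
                              agg["i_local_mm"] * 100.0 / agg["i_all_mm"], 0.0)

    return EnsembleResult(runs=agg, style_runs=style_frames, summary=_summarize(agg),
                          freshwater_cap_mm=cap, restricted_years=restricted_years)


def scenario_ladder(profile: ProvinceProfile) -> list[tuple[str, ScenarioSpec]]:
    """The canonical current -> RI -> RI+PR -> RI+PR+PC ladder."""
    base = current_spec(profile)
    return [
        ("current", base),
        ("RI", ScenarioSpec(ri_pct=100.0, pr_pct=base.pr_pct, index=1)),
        ("RI+PR", ScenarioSpec(ri_pct=100.0, pr_pct=100.0, index=2)),
        ("RI+PR+PC", ScenarioSpec(ri_pct=100.0, pr_pct=100.0,
                                  area_pct=MAX_AREA_PCT, index=3)),
    ]
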
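"""Daily N and P dynamics of field, ditch and pond compartments.

Concentrations follow fully-mixed mass balances driven by the hydrology
fluxes: fertilization days reset the field concentration, drainage advects
field water into the ditch (and onward to the pond and out of the IDU),
local recycling irrigation moves ditch/pond mass back to the field, and
ditches/ponds retain nutrients following nutrient-spiraling theory — an
areal first-order uptake flux vf * (C - EC0) toward an equilibrium
concentration (ENC0 for nitrogen, EPC0 for phosphorus).  Retention
parameters are uncertain and are sampled from lognormal distributions
fitted to literature ranges.

Rain and remote freshwater are treated as nutrient-free; net release from
sediments when C < EC0 is disabled (retention features only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hydrology import DailyFluxes, IDUGeometry

__all__ = [
    "NutrientParams",
    "FertilizationEvent",
    "ConcState",
    "DailyLoads",
    "DEFAULT_RANGES",
    "fit_lognormal_from_range",
    "sample_retention_params",
    "params_to_frame",
    "retention_flux",
    "apply_fertilization",
    "step_nutrient",
]

#: Literature ranges of the retention parameters, read as 5th-95th percentiles:
#: uptake velocities vf in cm/day, equilibrium concentrations in mg/L.
DEFAULT_RANGES = {
    "vf_n_cm_d": (4.2, 44.0),
    "vf_p_cm_d": (1.5, 9.0),
    "enc0_mg_l": (0.4, 5.0),
    "epc0_mg_l": (0.03, 1.1),
}


@dataclass(frozen=True)
class NutrientParams:
    """One Monte-Carlo draw of ditch/pond retention parameters."""

    vf_n_cm_d: float
    vf_p_cm_d: float
    enc0_mg_l: float
    epc0_mg_l: float

    def __post_init__(self) -> None:
        if self.vf_n_cm_d <= 0 or self.vf_p_cm_d <= 0:
            raise ValueError("uptake velocities must be positive")
        if self.enc0_mg_l < 0 or self.epc0_mg_l < 0:
            raise ValueError("equilibrium concentrations must be >= 0")


@dataclass(frozen=True)
class FertilizationEvent:
    """Field concentrations observed on a fertilization day (mg/L)."""

    day_of_season: int
    n_mg_l: float
    p_mg_l: float

    def __post_init__(self) -> None:
        if self.n_mg_l < 0 or self.p_mg_l < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class ConcState:
    """Nutrient masses (g) per compartment; concentration = mass / volume."""

    field_n_g: float = 0.0
    field_p_g: float = 0.0
    ditch_n_g: float = 0.0
    ditch_p_g: float = 0.0
    pond_n_g: float = 0.0
    pond_p_g: float = 0.0

    def copy(self) -> "ConcState":
        return ConcState(self.field_n_g, self.field_p_g, self.ditch_n_g,
                         self.ditch_p_g, self.pond_n_g, self.pond_p_g)

    def total_n(self) -> float:
        return self.field_n_g + self.ditch_n_g + self.pond_n_g

    def total_p(self) -> float:
        return self.field_p_g + self.ditch_p_g + self.pond_p_g


@dataclass
class DailyLoads:
    """Mass fluxes (g) leaving or removed within the IDU in one day."""

    runoff_n_g: float = 0.0
    runoff_p_g: float = 0.0
    leach_n_g: float = 0.0
    leach_p_g: float = 0.0
    retention_n_g: float = 0.0   # ditch + pond spiraling removal
    retention_p_g: float = 0.0
    field_decay_n_g: float = 0.0  # field first-order sink
    field_decay_p_g: float = 0.0
    fert_input_n_g: float = 0.0   # mass added by fertilization resets
    fert_input_p_g: float = 0.0


def fit_lognormal_from_range(low: float, high: float, coverage: float = 0.90) -> tuple[float, float]:
    """Lognormal (mu, sigma of log) with ``low``/``high`` as symmetric quantiles.

    The two bounds enclose ``coverage`` probability mass symmetrically, i.e.
    for coverage 0.90 they are the 5th and 95th percentiles.
    """
    if not 0 < low <= high:
        raise ValueError("bounds must satisfy 0 < low <= high")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    mu = 0.5 * (np.log(low) + np.log(high))
    sigma = (np.log(high) - np.log(low)) / (2.0 * z)
    return float(mu), float(sigma)


def sample_retention_params(
    n_sets: int,
    seed: int,
    ranges: dict[str, tuple[float, float]] = DEFAULT_RANGES,
    coverage: float = 0.90,
) -> list[NutrientParams]:
    """Draw ``n_sets`` independent retention-parameter sets (reproducible)."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {}
    for key in ("vf_n_cm_d", "vf_p_cm_d", "enc0_mg_l", "epc0_mg_l"):
        mu, sigma = fit_lognormal_from_range(*ranges[key], coverage)
        draws[key] = np.exp(rng.normal(mu, sigma, n_sets))
    return [NutrientParams(draws["vf_n_cm_d"][i], draws["vf_p_cm_d"][i],
                           draws["enc0_mg_l"][i], draws["epc0_mg_l"][i])
            for i in range(n_sets)]


def params_to_frame(params: Sequence[NutrientParams]) -> pd.DataFrame:
    """Parameter sets as a DataFrame (one row per Monte-Carlo draw)."""
    return pd.DataFrame([vars(p) for p in params])


def retention_flux(
    conc_mg_l: float,
    ec0_mg_l: float,
    vf_cm_day: float,
    area_m2: float,
    volume_m3: float,
    dt_days: float = 1.0,
) -> float:
    """Nutrient-spiraling removal (g) over one step.

    flux = vf * (C - EC0) * A * dt with vf converted to m/day and C in g/m3,
    clamped at zero when C <= EC0 (no net release) and capped so the
    compartment cannot be driven below EC0 within the step.
    """
    if min(conc_mg_l, vf_cm_day, area_m2, volume_m3, dt_days) < 0 or ec0_mg_l < 0:
        raise ValueError("all retention inputs must be non-negative")
    if conc_mg_l <= ec0_mg_l:
        return 0.0
    potential = (vf_cm_day / 100.0) * (conc_mg_l - ec0_mg_l) * area_m2 * dt_days
    cap = (conc_mg_l - ec0_mg_l) * volume_m3
    return min(potential, cap)


def apply_fertilization(
    conc: ConcState,
    event: FertilizationEvent,
    field_volume_m3: float,
) -> tuple[ConcState, float, float]:
    """Reset field concentrations to the fertilization-day values.

    Returns the new state plus the N and P mass added (g), i.e. the signed
    difference between the reset mass and the mass present before.
    """
    new = conc.copy()
    new_n = event.n_mg_l * field_volume_m3
    new_p = event.p_mg_l * field_volume_m3
    dn = new_n - conc.field_n_g
    dp = new_p - conc.field_p_g
    new.field_n_g = new_n
    new.field_p_g = new_p
    return new, dn, dp


def _conc(mass_g: float, volume_m3: float) -> float:
    return mass_g / volume_m3 if volume_m3 > 1e-12 else 0.0


def step_nutrient(
    conc: ConcState,
    flux: DailyFluxes,
    params: NutrientParams,
    geom: IDUGeometry,
    *,
    field_decay_per_day: float = 0.15,
    fert_event: FertilizationEvent | None = None,
) -> tuple[ConcState, DailyLoads]:
    """Advance compartment nutrient masses one day using the hydrology fluxes.

    The day is replayed in the hydrological order (rain dilution, ET
    concentration, percolation, irrigation transfer, drainage routing) with
    each advective transfer carrying the source compartment's current
    concentration, so mass is conserved exactly; spiraling retention acts on
    the end-of-day ditch and pond volumes.
    """
    s = conc.copy()
    loads = DailyLoads()
    a_f = geom.field_area_m2

    def vol(depth_mm: float) -> float:
        return depth_mm * a_f / 1000.0

    if fert_event is not None:
        s, dn, dp = apply_fertilization(s, fert_event, vol(flux.depth_start_mm))
        loads.fert_input_n_g = dn
        loads.fert_input_p_g = dp

    # Field first-order decline between fertilization events (soil
    # adsorption / plant uptake stand-in).
    decay = 1.0 - np.exp(-field_decay_per_day)
    loads.field_decay_n_g = s.field_n_g * decay
    loads.field_decay_p_g = s.field_p_g * decay
    s.field_n_g -= loads.field_decay_n_g
    s.field_p_g -= loads.field_decay_p_g

    # Rain dilutes (no mass); ET concentrates (no mass); percolation leaches
    # at the post-ET field concentration.
    v_after_et = vol(flux.depth_after_et_mm)
    perc_v = vol(flux.depth_after_et_mm - flux.depth_after_perc_mm)
    if perc_v > 0 and v_after_et > 0:
        loads.leach_n_g = _conc(s.field_n_g, v_after_et) * perc_v
        loads.leach_p_g = _conc(s.field_p_g, v_after_et) * perc_v
        s.field_n_g -= loads.leach_n_g
        s.field_p_g -= loads.leach_p_g

    # Local recycling irrigation transfers ditch/pond mass to the field.
    for store, vol_at_draw, drawn in (
        ("ditch", flux.ditch_after_evap_m3, flux.irr_from_ditch_m3),
        ("pond", flux.pond_after_evap_m3, flux.irr_from_pond_m3),
    ):
        if drawn > 0 and vol_at_draw > 1e-12:
            frac = min(1.0, drawn / vol_at_draw)
            for nut in ("n", "p"):
                m = getattr(s, f"{store}_{nut}_g") * frac
                setattr(s, f"{store}_{nut}_g", getattr(s, f"{store}_{nut}_g") - m)
                setattr(s, f"field_{nut}_g", getattr(s, f"field_{nut}_g") + m)

    # Field surplus drains to the ditch at the field concentration.
    v_before_drain = vol(flux.depth_after_irr_mm)
    if flux.field_to_ditch_m3 > 0 and v_before_drain > 1e-12:
        frac = min(1.0, flux.field_to_ditch_m3 / v_before_drain)
        for nut in ("n", "p"):
            m = getattr(s, f"field_{nut}_g") * frac
            setattr(s, f"field_{nut}_g", getattr(s, f"field_{nut}_g") - m)
            setattr(s, f"ditch_{nut}_g", getattr(s, f"ditch_{nut}_g") + m)

    # Ditch overflow to pond and out of the IDU.
    out_ditch = flux.ditch_to_pond_m3 + flux.outflow_ditch_m3
    if out_ditch > 0 and flux.ditch_before_overflow_m3 > 1e-12:
        for nut, runoff_attr in (("n", "runoff_n_g"), ("p", "runoff_p_g")):
            c = _conc(getattr(s, f"ditch_{nut}_g"), flux.ditch_before_overflow_m3)
            to_pond_m = c * flux.ditch_to_pond_m3
            out_m = c * flux.outflow_ditch_m3
            setattr(s, f"ditch_{nut}_g", getattr(s, f"ditch_{nut}_g") - to_pond_m - out_m)
            setattr(s, f"pond_{nut}_g", getattr(s, f"pond_{nut}_g") + to_pond_m)
            setattr(loads, runoff_attr, getattr(loads, runoff_attr) + out_m)

    # Pond overflow out of the IDU.
    if flux.outflow_pond_m3 > 0 and flux.pond_before_overflow_m3 > 1e-12:
        for nut, runoff_attr in (("n", "runoff_n_g"), ("p", "runoff_p_g")):
            c = _conc(getattr(s, f"pond_{nut}_g"), flux.pond_before_overflow_m3)
            out_m = c * flux.outflow_pond_m3
            setattr(s, f"pond_{nut}_g", getattr(s, f"pond_{nut}_g") - out_m)
            setattr(loads, runoff_attr, getattr(loads, runoff_attr) + out_m)

    # Nutrient-spiraling retention on end-of-day ditch/pond volumes.
    for store, area, vol_end in (
        ("ditch", geom.ditch_area_m2, flux.ditch_end_m3),
        ("pond", geom.pond_area_m2, flux.pond_end_m3),
    ):
        if vol_end > 1e-12 and area > 0:
            for nut, vf, ec0 in (("n", params.vf_n_cm_d, params.enc0_mg_l),
                                 ("p", params.vf_p_cm_d, params.epc0_mg_l)):
                c = _conc(getattr(s, f"{store}_{nut}_g"), vol_end)
                r = retention_flux(c, ec0, vf, area, vol_end)
                setattr(s, f"{store}_{nut}_g", getattr(s, f"{store}_{nut}_g") - r)
                attr = f"retention_{nut}_g"
                setattr(loads, attr, getattr(loads, attr) + r)

    # Guard against float-cancellation residues (~1 ulp below zero) from the
    # chained subtractions above; far below the mass-balance tolerance.
    for name in ("field_n_g", "field_p_g", "ditch_n_g", "ditch_p_g", "pond_n_g", "pond_p_g"):
        v = getattr(s, name)
        if v < 0:
            if v < -1e-9:
                raise AssertionError(f"negative nutrient mass in {name}: {v}")
            setattr(s, name, 0.0)

    return s, loads
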
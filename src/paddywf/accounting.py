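"""Water-footprint and resilience accounting.

Converts seasonal simulation ledgers into green, blue and gray water
footprints (m3 per ton of rice dry matter), irrigation self-sufficiency and
local storage volume.  The gray WF is the dilution volume needed to
assimilate the nutrient loads exported by runoff and leaching:

    GWF_runoff   = L_runoff  * 1000 / ((c_max,surface - c_nat) * Y)
    GWF_leaching = L_leaching * 1000 / ((c_max,groundwater - c_nat) * Y)

computed separately for nitrogen and phosphorus; the final gray WF is the
larger of the two nutrient-specific values.  Default acceptable
concentrations follow the Chinese surface-water grade V standard (2 mg/L N,
0.4 mg/L P) and groundwater grade III (20 mg/L N); no groundwater P
standard is configured by default, so the P leaching term contributes 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

__all__ = [
    "GrayWFConstants",
    "SeasonTotals",
    "WFResult",
    "gray_wf",
    "green_blue_wf",
    "irrigation_self_sufficiency",
    "percent_change",
    "impact_table",
    "wf_result",
]


@dataclass(frozen=True)
class GrayWFConstants:
    """Maximum acceptable and natural nutrient concentrations, mg/L."""

    c_max_surface_n: float = 2.0
    c_max_surface_p: float = 0.4
    c_max_groundwater_n: float = 20.0
    c_max_groundwater_p: float | None = None  # no standard: leaching P excluded
    c_nat: float = 0.0

    def __post_init__(self) -> None:
        maxima = [self.c_max_surface_n, self.c_max_surface_p, self.c_max_groundwater_n]
        if self.c_max_groundwater_p is not None:
            maxima.append(self.c_max_groundwater_p)
        if any(c <= self.c_nat for c in maxima):
            raise ValueError("c_max values must exceed c_nat")


@dataclass
class SeasonTotals:
    """Per-growing-season ledger of one IDU simulation."""

    yield_t_ha: float
    l_runoff_n_kg_ha: float = 0.0
    l_runoff_p_kg_ha: float = 0.0
    l_leach_n_kg_ha: float = 0.0
    l_leach_p_kg_ha: float = 0.0
    eta_green_mm: float = 0.0
    eta_blue_mm: float = 0.0
    eta_recycled_mm: float = 0.0
    i_local_mm: float = 0.0
    i_remote_mm: float = 0.0
    lsv_mm: float = 0.0
    yield_loss_pct: float = 0.0

    @property
    def eta_mm(self) -> float:
        return self.eta_green_mm + self.eta_blue_mm + self.eta_recycled_mm

    @property
    def i_all_mm(self) -> float:
        return self.i_local_mm + self.i_remote_mm


@dataclass(frozen=True)
class WFResult:
    """Water footprint components, m3 per ton of rice dry matter."""

    green: float
    blue: float
    gray: float
    recycled: float

    @property
    def total(self) -> float:
        """Green + blue + gray WF out of the system (recycled is internal)."""
        return self.green + self.blue + self.gray


def gray_wf(totals: SeasonTotals, consts: GrayWFConstants = GrayWFConstants()) -> float:
    """Gray water footprint, m3/ton: max of the N-based and P-based values."""
    y = totals.yield_t_ha
    if y <= 0:
        raise ValueError("yield must be positive")
    gwf_n = totals.l_runoff_n_kg_ha * 1000.0 / ((consts.c_max_surface_n - consts.c_nat) * y)
    gwf_n += totals.l_leach_n_kg_ha * 1000.0 / ((consts.c_max_groundwater_n - consts.c_nat) * y)
    gwf_p = totals.l_runoff_p_kg_ha * 1000.0 / ((consts.c_max_surface_p - consts.c_nat) * y)
    if consts.c_max_groundwater_p is not None:
        gwf_p += totals.l_leach_p_kg_ha * 1000.0 / ((consts.c_max_groundwater_p - consts.c_nat) * y)
    return max(gwf_n, gwf_p)


def green_blue_wf(totals: SeasonTotals) -> tuple[float, float, float]:
    """(green, blue, recycled) WF in m3/ton: ETa component (mm) * 10 / Y."""
    y = totals.yield_t_ha
    if y <= 0:
        raise ValueError("yield must be positive")
    return (totals.eta_green_mm * 10.0 / y,
            totals.eta_blue_mm * 10.0 / y,
            totals.eta_recycled_mm * 10.0 / y)


def irrigation_self_sufficiency(i_local_mm: float, i_all_mm: float) -> float:
    """ISS (%): share of irrigation supplied locally; 0 when no irrigation."""
    if i_local_mm < 0 or i_all_mm < 0 or i_local_mm > i_all_mm + 1e-9:
        raise ValueError("invalid irrigation ledger")
    if i_all_mm == 0:
        return 0.0
    return i_local_mm * 100.0 / i_all_mm


def wf_result(totals: SeasonTotals, consts: GrayWFConstants = GrayWFConstants()) -> WFResult:
    green, blue, recycled = green_blue_wf(totals)
    return WFResult(green=green, blue=blue, gray=gray_wf(totals, consts), recycled=recycled)


def percent_change(new: float, old: float, decimals: int = 1) -> float:
    """(new - old)/old * 100, rounded half-up to ``decimals`` places."""
    if old == 0:
        raise ZeroDivisionError("reference value is zero")
    pct = (new - old) / old * 100.0
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(pct)).quantize(q, rounding=ROUND_HALF_UP))


def impact_table(redesigned: Mapping[str, float], control: Mapping[str, float],
                 keys: list[str] | None = None) -> dict[str, float]:
    """Percentage changes (redesigned vs control) for each shared key."""
    keys = keys if keys is not None else [k for k in redesigned if k in control]
    return {k: percent_change(redesigned[k], control[k]) for k in keys}
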
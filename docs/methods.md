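# Methods

## Scope and structure

`paddywf` simulates one paddy irrigation-drainage unit (IDU) per run — a
rice field, a drainage ditch, and optionally a pond behind the outlet weir —
at a daily step over one growing season, then scales up by running style ×
climate-year × parameter-set ensembles and aggregating by the management-
style shares of a province profile. The hydrology of a season does not
depend on the nutrient-retention parameters, so it is simulated once per
(IDU, year) and the nutrient mass balance is replayed per Monte-Carlo
parameter set; this makes 100-set ensembles cheap.

## Daily water balance

The daily operation order is fixed as **rain → crop ET and percolation →
irrigation → drainage**. The order is a modelling choice (results depend on
it) and is deliberately conservative for irrigation: the day's rain is
allowed to satisfy ponding before the trigger rule is evaluated, so the
model never irrigates on a day whose rain already refilled the field.

* Field water is a single store of ponded depth plus a root-zone soil
  reservoir of capacity TAW = 60 mm (readily-available fraction p = 0.2,
  both configurable). While ponded, crop ET proceeds at K꜀·ET₀ and
  percolation at a constant rate (default 2 mm/day, configurable; puddled
  ditch/pond bottoms do not percolate). When ponding is gone, ET is
  throttled by the CROPWAT stress coefficient K_s, linear in the depletion
  beyond p·TAW.
* Ditches and ponds receive direct rain and lose open-water evaporation at
  1.05 × ET₀ over their own surface areas.
* Irrigation triggers when ponding falls below the stage trigger depth and
  refills to the stage target plus any soil deficit; it is suppressed in
  scheduled drying windows (a ~7-day midseason drying and final pre-harvest
  drainage in the shipped scheme, which represents normal farmer
  management: 10 mm trigger / 40 mm target / 60 mm maximum ponding).
* Sourcing follows the management style: PD1 draws the ditch first, QD the
  ditch then the pond, TC and PD2 use remote freshwater only. Remote supply
  is limited by the remaining seasonal allowance (infinite in unrestricted
  years).
* Drainage routes field water above the stage maximum into the ditch; ditch
  overflow continues to the pond only for styles with the pond in the
  drainage path (PD2, QD); residual overflow leaves the IDU. There is no
  backflow through the outlet.

Field water carries a three-way source partition (rain / remote freshwater
/ local recycled) updated by perfect volume-weighted mixing; ET removes
proportionally, which yields the green/blue/recycled split of ETₐ used by
the water-footprint accounting. The pre-season saturated soil water is
attributed to rain (green), the conventional choice for antecedent soil
moisture. Water is conserved identically — the test suite closes daily and
seasonal budgets to 10⁻⁶ relative (measured residuals are at machine
precision).

## Nutrients

Compartments are fully mixed; the state variable is mass, concentration is
mass/volume. The nutrient step replays the day's hydrological transfers in
the same order with each advective flux carrying its source compartment's
current concentration, so mass closes exactly. Specifics:

* Fertilization days reset the field concentration to configured values
  (typical floodwater values after dressing are shipped: 25/15/12 mg N/L
  and 1.5/0.5/0.3 mg P/L at transplanting, tillering and panicle stages);
  the mass difference is booked as fertilizer input.
* The field pool declines first-order at 0.15/day (configurable) between
  events. This is an explicit stand-in for soil adsorption and plant uptake
  and is reported as a separate sink, not as ditch/pond retention.
* Ditch and pond retention follows nutrient spiraling: an areal uptake flux
  v_f (C − EC₀) A per day, applied on end-of-day volumes, clamped at zero
  when C ≤ EC₀ (no sediment release — ditches/ponds are treated strictly as
  retention features; a release term would require a sediment-pool state
  the model does not carry) and capped so a step cannot push C below EC₀.
* Rain and remote freshwater are nutrient-free; recycled irrigation moves
  ditch/pond mass back onto the field, which is why decentralized styles
  can show slightly higher leaching while exporting far less via runoff.

Retention parameters (v_f,N, v_f,P, ENC₀, EPC₀) are uncertain. Literature
ranges (4.2–44 and 1.5–9.0 cm/d; 0.4–5.0 and 0.03–1.1 mg/L) are read as
5th–95th percentiles of lognormal distributions — the 90% coverage is a
package choice, configurable — and parameter sets are drawn independently
per distribution with a seeded generator.

## Crop response

Yield loss uses stage-wise yield-response factors K_y = (1.0, 1.09, 1.32,
0.5) for the initial, development, mid-season and late-season stages, with
stage losses K_y,i (1 − ETₐ,i/ET꜀,i) clipped to [0, 1] and combined
multiplicatively (the CROPWAT convention; the stage-wise formula alone does
not define a seasonal combination, so the product rule is an explicit
design decision). Crop coefficients default to the FAO-56 paddy values
(1.05, 1.10, 1.20, 0.90).

## Freshwater restriction in dry years

Remote supply is guaranteed up to the province's probability-of-irrigation
percentile (PI = 79 / 83 / 87% by region). Which years are restricted is
decided by the growing-season aridity rank; the cap level is the
PI-percentile of the *fully-remote* seasonal demand distribution, applied
as a seasonal total. Two deliberate choices here: the cap is a property of
the irrigation district, not of the IDU style (a per-style cap would
penalize decentralized styles for their lower remote demand and make the
style comparison incoherent), and the seasonal-total form is the simplest
reading of a supply-capability limit. Because aridity rank and demand rank
correlate imperfectly, a restricted year's cap occasionally does not bind;
the yield-loss comparison between styles is then an equality, which the
directional checks accept.

## Synthetic climate

A standard two-part stochastic weather generator: first-order two-state
Markov occurrence with month-specific stationary wet-day probability and
wet-after-wet persistence (the dry-to-wet probability is derived from
stationarity), and gamma-distributed wet-day amounts (shape 0.75) whose
mean preserves the configured monthly totals. Temperature, humidity, wind
and sunshine are drawn around monthly normals, with overcast wet days and a
compensating dry-day sunshine mean. Years are 365 days; leap days are not
generated. The three shipped archetypes (NE ~41°N, CJ ~30.5°N, SE ~23°N)
use climatological monthly values typical of the northeast, Changjiang
basin and southeast coastal rice regions, each with a 120-day growing
season.

What the generator does *not* emulate: multi-year persistence (droughts are
serially independent), typhoon-scale extreme daily totals, within-month
trends, and spatial correlation between stations. Passing tests therefore
demonstrate internal consistency and the direction and rough magnitude of
management effects under realistic forcing — not site-specific predictions;
reproducing observed provincial values would require the original station
records and survey shares, which are intentionally out of scope.

## Scenario engine

Scenario application is share bookkeeping: RI moves TC→PD1 and PD2→QD
(proportionally to their sizes) until the recycling share reaches its
target; PR moves the pond-bearing part of PD1 into QD (the fraction of PD1
IDUs possessing an isolated pond is a profile input, default 0.5); PC
raises the pond area share until ditch+pond reaches the target (≤ 8%),
recording the converted field area. Provincial pond area is concentrated in
the pond-bearing IDUs when constructing per-style geometries (capped at 12%
of an IDU), so the system-wide pond share is conserved.

Styles are aggregated by deterministic share-weighted averaging — the
expectation of proportional random sampling, with less variance; ISS is
recomputed from the aggregated irrigation volumes rather than averaged as a
ratio. Ensemble summaries report mean, median, inter-quartile and 5–95%
ranges over year × parameter-set records.

## Numerical and reporting choices

* All randomness flows from one root seed through named substreams
  (weather, parameters), so any component can be re-run reproducibly.
* Impact tables round half-up to one decimal, matching the convention of
  the published trial table they mirror.
* Default problem sizes in the tests and the acceptance script — 30 synthetic
  years × 4 parameter sets for matched-style comparisons, 10 × 2 for each
  ladder point, 50–100 randomized configurations for the conservation
  suites, 10⁵ draws for the distribution check — are chosen as the smallest
  ensembles whose checked properties are stable across seeds.
* Degenerate inputs are handled explicitly: zero growing-season rainfall
  yields an infinite aridity index with a warning; zero total irrigation
  defines ISS = 0; zero yield and zero field area are rejected.

## Known limitations

* No NH₄/NO₃ speciation, sediment P pool, or greenhouse-gas fluxes; no
  groundwater-table dynamics, canal hydraulics or multi-IDU routing.
* The field-side nutrient decline is a single first-order constant, not a
  process model; absolute load levels inherit its calibration.
* Three of the published trial impact rows are not recoverable from the
  printed observation cells (rounded inputs at the source); they are
  flagged, not reproduced.
* Yield per unit area is held constant across styles in normal years (the
  styles change irrigation sources, not quantities); yield enters the WF
  denominators as a province constant, and only dry-year stress modifies it
  through the K_y response.
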
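# Methods

`hazex` implements a grid-cell exposure analysis for four types of
climate extreme — heatwaves, soil-moisture droughts, river floods and
wildfires — of the kind applied to multi-model climate-impact ensembles
in global biodiversity assessments.  Every quantitative step (threshold
calibration, event classification, windowed frequencies, ensemble
statistics, range-weighted exposure) lives in the library under `src/`;
the numbered scripts under `analysis/` are thin drivers over it.

## Event definitions

Extremes are defined *relative to each cell's own reference climate*: a
long stationary "pre-industrial control" run supplies the reference
distribution, so spatial variation in the mean state never masquerades
as a change in extremes.  The default tail is the 97.5th percentile
(2.5th for droughts), with 95/97.5/99 available for sensitivity work.
All comparisons are strict (`>` upper tail, `<` lower tail): a value
that ties the threshold never flags.

**Heatwave.** Two steps. First, heatwave periods: runs of at least
three consecutive days on which daily maximum temperature exceeds the
day-of-year 90th percentile of the control, where the percentile for
day *d* pools all control values in the 31-day window centred on *d*
(wrapping the December–January boundary).  Second, the annual heatwave
magnitude index (HWMId): each period day contributes
`max(0, (T_d − Q25) / (Q75 − Q25))`, where Q25/Q75 are the quartiles of
the control *annual-maximum* temperature series for that cell; the
period magnitude is the daily sum and the annual index the maximum over
periods (zero in a year with no period).  A year is an extreme-heatwave
year when its HWMId exceeds the control HWMId percentile.  Periods are
not stitched across calendar years, so a 3–4 day event split across the
year boundary can be missed; this affects control and scenario years
alike.  Cells with a degenerate magnitude reference (Q75 = Q25) are
flagged unusable rather than classified.

**Drought.** A year flags when root-zone soil moisture sits strictly
below the low-tail percentile for three or more consecutive calendar
months.  The percentile is computed from all control months pooled, not
per calendar month — the reference is the cell's overall soil-moisture
distribution; a per-month variant would instead measure seasonal
anomalies and is deliberately not the default.  Runs are evaluated
within calendar years only (a November–January run flags neither year
unless three of its months fall in one year).  Cells with annual-mean
discharge below 0.1 mm/day are excluded: in climatologically dry cells
"soil moisture below the 2.5th percentile" is numerically fragile and
ecologically uninformative.  A discharge of exactly 0.1 mm/day is
retained (the exclusion reads strictly below).

**River flood.** A generalized extreme value (GEV) distribution is
fitted to the control annual maxima of daily outflow; the flood
threshold is the 40-year return level, i.e. the GEV quantile at
non-exceedance probability 1 − 1/40 = 0.975, so the flood definition
tracks the same percentile as the other event types (and 20/100-year
levels pair with the 95th/99th percentiles in sensitivity runs).  A
year flags when the annual maximum outflow exceeds that level *and* at
least 1% of the cell is flooded that year *and* the cell passes the
dryness mask.  The flooded-fraction condition is evaluated per year;
a static per-cell variant would be slightly more permissive in wet
cells and is not the default because the fraction is an annual field
here.  Fitting is maximum likelihood (scipy `genextreme`) started from
Hosking L-moment estimates; if the MLE fails or leaves the shape
parameter outside (−0.5, 0.5) — where quantile variance explodes — the
clamped L-moment estimate is used.  Constant annual-maximum series are
flagged unusable.

**Wildfire.** Annual burned-area fraction above the control percentile.

On a stationary control these constructions are self-calibrating: by
definition of an empirical percentile with strict exceedance, each
annual-metric classifier flags ≈ 2.5% of control years (exactly the
discretized tail at finite sample sizes), and the drought run
requirement can only remove flags relative to the single-month rate.
The test suite measures these rates on a 2,000-year control over a
20×20 grid.

## Windows, ensembles, multi-hazard counts, exposure

Event frequency is the number of flagged years in a 30-year window
divided by 30, stored as integer counts so that threshold comparisons
are exact in rational arithmetic (10/30 qualifies at 0.33/yr even
though 0.3333… and 0.33 are not comparable reliably in floats).  The
baseline window is fixed at 1985–2014 (centred on 2000); future windows
are centred 2030–2085.  Change is future minus baseline frequency.

A cell's multi-hazard count is the number of event types whose window
frequency reaches the qualification threshold (default ≥ 0.33/yr, i.e.
at least every third year on average; 0.2–0.5 supported).

Entity exposure (species range or ecoregion) is the frequency-, area-
and overlap-weighted mean

    E = Σᵢ fᵢ aᵢ oᵢ / Σᵢ aᵢ oᵢ

over grid cells *i*, with fᵢ the window frequency, aᵢ the exact
spherical band area `R² Δλ (sin φ₂ − sin φ₁)` (R = 6371 km) and oᵢ the
fraction of cell *i* covered by the entity.  Cells where an event type
is undefined (ocean, dryness-masked, unusable GEV) count as frequency
zero — the entity's area there is unexposed, not dropped.  Multi-hazard
exposure replaces fᵢ with the indicator `multi_hazard_count ≥ k`.
Entities whose ranges have no overlap with grid land cells (small-island
species at a coarse resolution) are excluded before any exposure
computation, with per-taxon bookkeeping.

Ensemble order of operations: exposure is computed per climate × impact
model combination, then summarized as mean/min/max across combinations,
so the reported min–max genuinely spans model combinations.  (Averaging
frequency fields first and thresholding the mean is a different
statistic; mapping output uses the frequency-ensemble mean, but entity
tables are per-combination first.)  Counts of entities above an
exposure cutoff are reported both from the ensemble-mean exposure and
as the per-combination min–max range, since the two conventions answer
different questions.

## Synthetic forcing

The generator emulates the *statistical structure* the pipeline
assumes, not the physics of any model:

- **tasmax** (daily, °C): latitude-dependent mean (28 °C at the equator
  falling 35 °C toward the poles), hemisphere-phased seasonal sine
  (amplitude 3–15 °C with latitude), and AR(1) noise with lag-1
  autocorrelation 0.7 and stationary s.d. 3 °C — autocorrelation makes
  exceedance days cluster into multi-day runs, which is what stresses
  the heatwave run detector.
- **soil moisture** (monthly, fraction): logistic transform of a
  seasonal AR(1) latent process (lag-1 0.5), guaranteed in (0, 1).
- **outflow** (daily, positive): lognormal — exp(cell level + seasonal
  + AR(1) with lag-1 0.6), giving heavy-tailed annual maxima suitable
  for GEV fitting.
- **burned area** (annual, fraction): Beta-distributed with per-cell
  mean drawn in [0.002, 0.08], i.i.d. across years.
- **discharge** (annual mean, mm/day): static lognormal wet/dry map;
  with log-s.d. 1.5 around 1 mm/day roughly 6% of cells fall below the
  0.1 mm/day dryness cutoff.
- **flooded fraction** (annual): saturating transform of the year's
  maximum outflow relative to the cell median, capped per cell in
  [0.005, 0.6] so a few cells sit persistently under the 1% exclusion.

Scenario runs add deterministic trends from a start year (default 2015,
so the 1985–2014 baseline window is trend-free): warming in °C/decade
on tasmax, a fractional multiplicative decline per decade on soil
moisture, and multiplicative growth per decade on outflow and burned
area.  The trend presets `ssp126`/`ssp370`/`ssp585` (0.15/0.45/0.70
°C/decade warming with correspondingly scaled drying/flow/burning
rates) are ordered low/medium-high/high; a zero-trend spec reproduces
the control process exactly under the same seed.  The pseudo-ensemble
perturbs noise s.d., autocorrelation, seasonal amplitude and mean state
per member (±8–20%) around a shared static world map, mimicking
inter-model spread without inter-model structural differences.

Noise streams are seeded per (variable, 128-cell block, run kind,
ensemble member) from one base seed, so regenerating one variable never
shifts another, and all output is bit-reproducible.  The calendar is
365-day no-leap throughout.

What the generator does *not* emulate: spatially correlated weather
(cells are independent given the seasonal/mean structure), compound
inter-variable dependence beyond flooded-fraction-from-outflow, river
routing, fire spread, megafire behaviour, or observed CMIP6 variance
structure.  Passing tests therefore demonstrate correctness of the
calibration/classification/exposure machinery under known statistical
conditions, not fidelity to any real impact-model archive — headline
numbers from the real multi-model data (e.g. global exposure
percentages) are out of reach at desk scale by design.

## Problem sizes and numerical choices

The default desk-scale configuration is a 20×20 grid, 100-year
controls, 1985–2100 scenarios, a 5×3 ensemble, 200 species (5 of them
off-land to exercise island exclusion) and 12 ecoregions; the
self-calibration checks use a 2,000-year control where percentile
discreteness at n = 100 (3/100 years above the 97.5th percentile)
would otherwise dominate.  The day-of-year percentile climatology is
computed by an exact two-order-statistic selection over the pooled
31-day window (identical to `numpy.percentile` with linear
interpolation) in a cells-major layout; this is the single most
expensive step and runs in O(window × years × cells) per day-of-year.
Generation uses float32 fields; thresholds and exposure statistics are
float64.

Known limitations: no spatial correlation in the noise (ensemble spread
of spatially aggregated statistics is optimistic); drought attribution
ignores cross-year runs; no bias adjustment concepts (the control and
scenario share a generator by construction); the exposure weighting
assumes range overlap is static over time.
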
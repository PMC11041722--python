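# Methods

This note documents the models implemented in `burnwindows`, the defaults
chosen where the design was open, and what the synthetic test bed does and
does not establish about real data.

## Fuel moisture model

The dead-fuel moisture chain follows the classic (1978/1985) National Fire
Danger Rating System formulation.  Equilibrium moisture content (EMC, % of
dry weight) is a three-regime polynomial in relative humidity RH (%) and
dry-bulb temperature T (°F):

- RH < 10: `0.03229 + 0.281073·RH − 0.000578·RH·T`
- 10 ≤ RH ≤ 50: `2.22749 + 0.160107·RH − 0.014784·T`
- RH > 50: `21.0606 + 0.005565·RH² − 0.00035·RH·T − 0.483199·RH`

The daily EMC uses the standard day/night convention: the daytime value at
(Tmax, RHmin), the nighttime value at (Tmin, RHmax), weighted by hours of
daylight D from solar declination, `EMC̄ = (D·EMC_min + (24−D)·EMC_max)/24`.
Fine fuels track this directly (`FM1 = 1.03·EMC̄`, `FM10 = 1.28·EMC̄`).  The
100-h and 1000-h classes relax once per day toward boundary values that mix
EMC̄ with wet-hour saturation terms,

```
B100  = ((24 − PDUR)·EMC̄ + PDUR·(0.5·PDUR + 41)) / 24
B1000 = ((24 − PDUR)·EMC̄ + PDUR·(2.7·PDUR + 76)) / 24
```

with retained fractions `0.87·e^(−0.24)` (100-h) and `0.82·e^(−0.168)`
(1000-h); the 1000-h class relaxes toward the trailing 7-day mean of its
boundary.  Both recursions are contractions, so any initialization error
decays geometrically (gap ratio ≈ 0.79/day and 0.69/day); we initialize
from the first boundary values and discard a 90-day spin-up, far beyond the
~15-day e-folding memory of the 1000-h buffered recursion, before any
RxDay is counted.

**Precipitation duration.**  The boundary formulas need wet hours (PDUR),
which daily grids do not carry.  We model `PDUR = min(8, ⌈P/5 mm⌉)` hours
for P ≥ 0.25 mm, else 0 — monotone in the amount, capped at a
one-working-day duration, and exposed as a constant table entry.  Any
monotone choice preserves the qualitative behaviour; the cap prevents a
single deluge from saturating heavy fuels unrealistically fast.

**Ignition component.**  We use the probability-of-ignition polynomial:
heat of ignition `QIGN = 144.5 − 0.266·T − 0.00058·T² − 0.01·T·m +
18.54·(1 − e^(−0.151·m)) + 6.4·m` with fine-fuel moisture m, then
`P(I) = 0.001846·((344 − QIGN)/10)^3.66` clamped to [0, 100], with P(I) = 0
at or beyond 33% extinction moisture.  The full NFDRS ignition component
additionally scales P(I) by a spread-component factor; the spread component
depends on fuel-model and wind inputs outside this package's scope (it is
not part of the prescription variables), so the index used here *is* the
ignition probability.  It has the properties prescriptions rely on: bounded
in [0, 100], decreasing in fuel moisture, increasing in temperature.
Fuel temperature is approximated by the daily maximum air temperature (no
solar-radiation adjustment, which would require cloud cover).

All interfaces are SI (°C, m/s, mm); conversion to °F happens once at the
module boundary.  Every NFDRS constant sits in one table
(`fuel_moisture.NFDRS_CONSTANTS`) for auditability.

## Prescription envelopes and RxDays

Each burn plan carries inclusive [lower, upper] bounds for temperature,
relative humidity, mid-flame wind, FM1, FM10, ignition component, and — in
forest plans only — FM100 and FM1000.  Class envelopes take, per variable,
the median of available lower bounds and the median of available upper
bounds (even counts use the mean of the middle two); variables present in
only some plans use the median over the plans that carry them.

A grid-day is an RxDay iff every bounded variable is inside its range.
Bounds are treated as **inclusive**: plans state acceptable ranges, and a
value exactly at a stated limit is operationally acceptable.  If an
envelope bounds a variable the evaluation vector lacks, classification
raises rather than silently passing — dropping a constraint must be an
explicit variant, never an accident of missing data.  Evaluation uses
peak-burn conditions: daily Tmax, daily RHmin, and mid-flame wind obtained
by scaling the daily-mean 10 m wind by 1.5 (afternoon peak over daily mean)
and then 0.4 (mid-flame frictional reduction), net ×0.6.

Definition variants: vegetation-aware (forest envelope on forest/woodland
cells, non-forest elsewhere), each envelope applied uniformly, an
all-plans-pooled envelope, a meteorology-only definition (all FM and
ignition bounds dropped), and a no-heavy-fuels definition (only
FM100/FM1000 dropped).  Because classification is a conjunction, dropping
bounds can only add RxDays — a property the tests enforce cell-by-cell.

## Bias correction

Fuel-moisture metrics are nonlinear functionals of several weather
variables at once, so model series whose marginals are individually
unbiased still inherit distributional biases through covariance and serial
correlation.  We therefore correct the *derived* metrics, not the raw
weather: empirical quantile mapping per grid cell with 100 evenly spaced
nodes, pooled by calendar month (an all-days pooling exists for short
records), linear interpolation between nodes, and constant-offset
extrapolation beyond the training range (the correction at the extreme
node), which passes modeled change signals outside the training support
through unchanged.  The transform is monotone, hence rank-preserving
within each pool.  Defaults (node count, pooling, tail rule, training
window) are package choices exposed as arguments.

## Air stagnation

A day is stagnant when 10 m daily-mean wind < 3.2 m/s **and** daily
precipitation < 1 mm, both strict inequalities.  The classical
air-stagnation index adds a 500 mb wind criterion; we keep only the
near-surface pair, as surface ventilation and precipitation scavenging
dominate smoke exposure at the surface.  The metric is a proxy for
ventilation, not a regulatory air-quality rule.

## Aggregation and trends

Seasonal counting uses meteorological seasons with December attached to the
*following* year's DJF; season-years not fully covered by the record
(including the first, December-less winter) are dropped so every count
spans a complete season.  Regional series are cosine-latitude-weighted
means over land cells inside the domain box (31.3–48.9°N, 235.3–256.9°E)
or its sub-regions (Pacific Southwest 32–42°N/235.3–246°E, Northern Tier
42–48.9°N/235.3–256.9°E, Four Corners 31.3–42°N/246–256°E); an unweighted
option exists for sensitivity.  Trends are ordinary least squares on yearly
values, with accumulated change = slope × (span of years), percent change
relative to the fitted value at the first year (period-mean baseline
available), and a two-tailed t-test on the slope.  Running means are
centered with truncated endpoint windows so smoothed series span the full
period.  Ensemble statistics average member series year-by-year and count
members whose own accumulated change exceeds a threshold in a stated
direction.  RxDays are computed per member first and then averaged —
classifying the ensemble-mean weather would systematically understate
variability and is not offered.

## Synthetic data: what it emulates and what it does not

The generator produces, per variable, a sinusoidal seasonal climatology
plus a linear secular trend plus AR(1) anomalies (lag-1 autocorrelation
0.7) whose innovations are spatially smoothed white noise; RH anomalies are
anti-correlated with temperature anomalies (coefficient −0.6) so hot/dry
extremes co-occur as they do in fire weather.  Tmin and RHmax derive from
Tmax and RHmin by fixed offsets, which enforces the physical ordering
invariants by construction.  Precipitation is an independent Bernoulli
wet-day process with seasonal probabilities (winter-wet defaults 0.40 /
0.28 / 0.10 / 0.25 for DJF/MAM/JJA/SON) and gamma amounts (shape 0.7,
scale 8 mm).  Pseudo-model ensembles add per-member additive biases and
trend perturbations with per-member seed streams.  Burn-plan sets jitter
class templates (defaults: a 14-forest + 8-non-forest archive; every
forest plan bounds FM100/FM1000, no non-forest plan does).  Vegetation
masks threshold a smoothed noise field at the quantile matching the
requested forest fraction.

Deliberately **not** emulated: orographic and coastal structure, realistic
spatial covariance of precipitation, wet-day persistence, the monsoon's
summer precipitation maximum, and any coupling of wind to synoptic state.
Consequently, passing tests establish the correctness and invariances of
the *algorithms* (recursions, classification semantics, counting, trend
statistics) and the qualitative climate responses (e.g. drying increases
RxDays where fuels are too moist and decreases them where fuels are near
the dry edge), but say nothing about the magnitude of real-world RxDay
climatologies or trends, which depend on the real archives.

## Problem sizes and numerical choices

The test suite and the acceptance script run on 3×3 to 10×10 grids over
2–80 years and a 6-member ensemble — sizes chosen so that every stage,
including the daily slow-fuel recursion loop, completes in seconds to a
couple of minutes while still exercising multi-decade trend estimation.
Medians and quantiles use the standard linear-interpolation definitions;
the sample standard deviation uses the n−1 denominator; OLS significance
comes from the two-tailed t distribution.  Degenerate inputs error loudly:
empty plan classes, humidity outside [0, 100], negative wind or rain,
series shorter than the spin-up, regions that miss the grid, and unknown
definition variants.

## Known limitations

- The 1978/1985 NFDRS constants are used throughout; the 2016 revision of
  the rating system changes the fuel-moisture model and is out of scope.
- Precipitation duration from daily totals is a modelling convenience; any
  dataset carrying true wet hours should bypass it.
- The quantile mapping is univariate and not trend-preserving beyond the
  constant-offset tail rule; quantile-delta variants are out of scope.
- Grid-cell classification ignores microclimate, regulatory, staffing and
  ecological constraints, so RxDay counts are an upper envelope of
  meteorological opportunity, not predicted burn activity.
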
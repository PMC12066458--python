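# Methods

This note documents the accounting model, the conventions the package
fixes where the field leaves room, the synthetic-data generator, and
the numerical choices, in enough detail to reproduce every number the
code emits.

## Accounting model

The unit of account is one crop season (winter wheat, sown in autumn
and harvested the following early summer; or summer maize, grown
June–September) on one hectare. Three layers are chained:

1. **Soil carbon.** SOC concentration (g kg⁻¹) comes either directly
   from measurement or from soil organic matter via the van Bemmelen
   factor 0.58. The stock of the accounting layer is
   SCS = SOC × BD × H × 10 in Mg C ha⁻¹ (BD in g cm⁻³, H in m; the
   factor 10 converts kg m⁻² to Mg ha⁻¹). The seasonal sequestration
   rate is the stock change over one season, harvest minus pre-season,
   times 44/12 (C → CO₂). Defaults: BD = 1.33 g cm⁻³ (a long-term site
   average; per-observation values are honoured when supplied) and
   H = 0.2 m, the tilled topsoil. The rate is computed in
   Mg CO₂-eq ha⁻¹ and multiplied by 1000 before it meets the
   kg-basis GHG inventory, so all per-area terms are commensurate.

2. **GHG inventory** (kg CO₂-eq ha⁻¹), by the emission-factor method:
   embodied emissions quantity × EF per input category (N, P, K
   fertilizer; irrigation water; electricity; diesel; seeds;
   pesticides — an open registry: extra categories in the factor table
   contribute only when the record applies them), plus soil N₂O from
   the applied-N pool N = synthetic fertilizer N + straw-returned N
   (straw mass × measured N mass fraction). Direct N₂O is
   N × σ₁ × 44/28; indirect N₂O adds the volatilization pathway
   (× Frac_vol × σ₂) and the leaching pathway (× Frac_leach × σ₃); the
   44/28 N→N₂O mass conversion is implemented as an exact rational.
   N₂O mass is weighted by its 100-year global warming potential,
   default 265. CH₄ has no fields anywhere: dryland wheat–maize
   systems emit negligibly. All terms are linear, so the total is
   additive over category partitions and scales with the inputs — both
   are property-tested invariants.

3. **Economics and footprints.** NEEB = Y_gain − A_cost − C_cost, with
   C_cost = carbon price × total emissions (default US$ 17 per t
   CO₂-eq). CF_a = emissions − sequestration (or emissions alone
   without the soil term); CF_y = CF_a / yield; CF_NEEB = CF_a / NEEB.
   Negative CF is a net sink. A negative NEEB flips the CF_NEEB sign;
   it is allowed with a logged warning rather than an error, because
   net budgets can genuinely be negative in bad years.

## Conventions fixed by this package

* **Multi-year aggregation of ratio footprints.** Two conventions are
  computed and labelled on every run: the arithmetic mean of per-year
  ratios (default) and the ratio of column means. They differ whenever
  the denominator varies across years — for the packaged 14-season
  wheat table the mean of yearly GHG/NEEB ratios is 7.36 while the
  ratio of means is 5.87. Reports should state the mode; the package
  always emits both.

* **Long-term SOC rate estimator.** Published per-crop SOC rates are
  usually stated without a method. The convention here: accumulate the
  within-season SOC changes of one crop over years and take the OLS
  slope of that cumulative series against calendar year. With a
  constant per-season increment the slope equals the increment
  exactly, and under independent observation noise the estimator is
  unbiased. It is deliberately insensitive to what the *other* crop
  does to the soil between this crop's seasons.

* **Trend statistics.** OLS against calendar year (not a sequential
  index), so a missing year enters as a gap rather than shifting the
  design; duplicate years are rejected. r² is reported as 0 for a
  constant series, where it is formally undefined. Display rounding is
  half-away-from-zero (`round_half_up`), matching report-table
  conventions; CSV outputs always carry full precision.

* **Per-row NEEB verification tolerance.** The packaged fixture stores
  integer-rounded income, cost, emissions and NEEB. Recomputing
  NEEB = income − cost − 0.017 × GHG from those rounded columns can
  deviate from the stored NEEB by slightly more than 1 US$ before
  rounding; the verification check therefore rounds the recomputed
  value to the nearest integer first and requires agreement within
  ±1 US$. All 29 fixture rows pass.

## Emission-factor configuration

Authoritative embodied emission factors are inventory- and
region-specific, so the package ships only documented defaults and
treats the table as user configuration (YAML or TOML). The default N₂O
coefficient set is IPCC-style: σ₁ = 0.01, Frac_vol = 0.1, σ₂ = 0.01,
Frac_leach = 0.2, σ₃ = 0.0075. Default embodied factors (per kg N 8.3,
per kg P 0.79, per kg K 0.55, per kWh 1.0, per L diesel 3.3, per kg
seed 1.0, per kg a.i. 18.0 kg CO₂-eq; irrigation water 0, with pumping
energy accounted under electricity) are order-of-magnitude values for
Chinese cropping systems; any serious application should supply its
own table. Every verification statistic that involves emissions uses
the fixture's stored GHG totals, never these defaults. Whether P and K
quantities are elemental or oxide basis is a property of the factor
table the user supplies; the package does not convert.

## Synthetic rotation generator

The generator emulates a 20-year on-farm wheat–maize rotation with the
linear structure the trend statistics assume. Defaults are the study
conditions of a two-decade North China Plain rotation: yield trends
+70 (wheat) and +184 (maize) kg ha⁻¹ yr⁻¹ around first-year means of
5877 and 6949 kg ha⁻¹ (chosen so the 20-year averages are ≈6542 and
≈8697 kg ha⁻¹); seasonal SOC increments +0.58 (wheat, straw
incorporated by pre-sowing tillage) and −0.72 (maize, straw
surface-mulched) g kg⁻¹ yr⁻¹ from an initial 7.0 g kg⁻¹
(= 12.06 g kg⁻¹ SOM × 0.58); warming +0.08 °C yr⁻¹ from 14.4 °C;
sunshine +57 h yr⁻¹. Grain prices (0.33 / 0.27 US$ kg⁻¹) are the
published mean incomes divided by mean yields; mean input costs are
814 / 576 US$ ha⁻¹. Straw returned is a fixed fraction (0.9) of the
previous season's non-grain aboveground biomass, derived from yield
and harvest index (0.45 wheat, 0.50 maize) — wheat receives the
previous maize straw, maize the same year's wheat straw.

Noise is Gaussian on the *observations* (yields 300 kg ha⁻¹, SOC
measurements 0.3 g kg⁻¹, input costs 60 US$ ha⁻¹, temperature 0.4 °C,
sunshine 90 h — one-time choices of realistic interannual scatter for
this system), while the underlying trajectories stay noiseless. Two
consequences, both tested: with all noise at zero every configured
trend is recovered *exactly* by the corresponding estimator, and with
noise the estimators are unbiased — the recovery harness defines each
parameter's true value by regenerating the dataset noiselessly and
running the same estimator, so generator and estimator can never
drift apart silently. The calibration test averages the estimated
wheat yield trend over 600 fixed seeds and requires agreement with the
configured 70 kg ha⁻¹ yr⁻¹ within two Monte-Carlo standard errors.

What the generator does **not** emulate: yield plateaus or any
deceleration of trends, price dynamics, heavy-tailed or autocorrelated
weather, crop failures, within-field spatial variation, and any
process-level coupling between climate and yield (the climate series
is generated alongside, not fed into, the yields). Passing tests
therefore demonstrate that the accounting and estimators are correct
under the linear-trend-plus-noise model, not that the model describes
any particular farm.

## Problem sizes and determinism

Generated datasets are 20 years × 2 crops (40 season records, 80 soil
observations) and build in milliseconds; the test suite, including the
600-seed calibration run, completes in a few seconds on one CPU. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical CSV
outputs, and pipeline reruns on the same inputs are byte-identical
(the JSON summary carries no timestamp for exactly this reason).

## Known limitations

* Only the tilled topsoil layer (default 0.2 m) is accounted; deeper
  SOC dynamics are out of scope.
* N₂O is emission-factor based; no process model of nitrification or
  denitrification, and no response to timing or placement of N.
* No discounting, inflation or currency handling; monetary values are
  taken as given in US$.
* The per-season sequestration pairs pre-season and harvest
  observations of the same season; inter-season (fallow) changes are
  attributed to neither crop.
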
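# Methods

This note documents what `nfert` computes, the assumptions each stage
leans on, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## 1. The reconstruction

### Harvested area

County harvested area is the year-2000 reference map times the national
ratio `HareaFAO(cro,y,j) / HareaFAO(cro,2000,j)` — i.e. counties are
assumed to follow their country's annual changes.  Political
disintegrations are handled on the national series first: parent-era values
are distributed to successors in proportion to each successor's value in
the first post-split year (equal split with a warning if all successors
report zero).  County totals are spread over cells in proportion to
cropland (rice layer for rice, upland otherwise; a county with area but no
matching cropland falls back to a uniform spread over its land cells), and
the cube is finally rescaled by one factor per crop-country-year so
national sums match the statistics exactly.  Matching is applied *after*
disintegration handling and gridding; the county table consumed by the rate
stage is re-aggregated from the matched cube so both stages see identical
areas.

Degenerate input: a zero reference-year national value with positive later
values leaves the reference share undefined; the national amount is then
spread uniformly over the country's counties.  This conserves totals
without inventing spatial structure.

### Rates

The class amounts (synthetic fertilizer SN, manure MA, crop residues CR)
follow the chain: extension beyond the prior product's last year (2014)
with national ratios → SN correction to national statistics (one factor per
country-year; MA/CR pass through) → crop split under the constant-ratio
assumption → survey calibration.

The constant-ratio split is

```
Nrate(cro,f,y,i) = NrateZ(cro,f,2000,i) · Namount(f,y,i) / Σ_cro NrateZ(cro,f,2000,i)·Harea(cro,y,i)
```

whose scale factor is shared by all crops in the county, so
`Σ_cro rate·area` reproduces the class amount identically.  Survey
calibration multiplies SN rates by one factor per country, crop group, and
anchor year (`2003–2006→2006, 2007–2008→2007, 2009–2012→2010,
2013–2016→2014, ≥2017→2018`); factors are computed once from
pre-calibration rates — a single multiplicative correction reproduces the
survey totals exactly, so no fixed-point iteration is needed.  Years before
2003 are left uncalibrated.  Calibration applies to SN only: the surveys
report synthetic fertilizer.

A per-country cropland-use fraction (default 1) removes pasture
applications from the national SN statistic before the correction; it is an
input, not an estimate.

### Fertilizer types

Missing survey consumption is imputed with a bootstrap-EM scheme for
time-series cross-section data: rows are (reporting unit, year), columns
are log1p consumption of the 11 synthetic types, log1p unit-aggregated
covariates (GDP, population, cropland area), and time polynomials t, t²,
t³.  Each of *m* = 5 imputations fits a multivariate normal by EM on a
bootstrap resample of rows and draws missing entries from their conditional
normal; draws are averaged, transformed back, and clamped at zero.
Averaging the draws (rather than keeping one) is used because the pipeline
consumes a single panel; the spread across draws is not propagated.
Observed cells are never touched.  Units with fewer than 3 observed years
for a type fall back to within-unit linear interpolation.

Shares follow the amount identity: CR and MA shares are their amounts over
the total; each synthetic type's share is its consumption proportion times
the county's SN share.  Component proportions are normalized to the
component sum — the reported total is only trusted when it agrees within
1%, which guarantees the shares sum to one wherever the total amount is
positive.  A unit-year with zero component consumption but positive SN
amount routes the synthetic mass to urea, the globally dominant carrier.

### Placement

The national no-till fraction is a monotone scaled logistic in
log(cropland per rural capita) — labour scarcity favouring no-till — fitted
to the census countries' national fractions unless curve parameters are
supplied; census country-years use census areas directly.  Potential
no-till area per cell is the rain-fed area of the 11 suitable annual crops,
zeroed in low-income cells without dominant large fields (high-income
countries keep all field sizes).  Cell probability is a four-predictor
logit in erosion, aridity (precipitation/PET), crop mix, and field size;
slopes and midpoints are a mandatory configuration block (the synthetic
generator ships slope 1 and per-driver medians as documented placeholders,
not as estimates of any published coefficients).  Cells are selected in
decreasing probability order (ties by cell index, for determinism), each
contributing potential × probability, with the last cell partially selected
so the national target is hit exactly; targets above the available
contribution select everything and log the shortfall.  Cell no-till area is
split across crops by harvested-area share.

Placement rules: injected fertilizers (anhydrous ammonia and nitrogen
solutions by default; a config switch restores the alternative grouping
`{AA, AN}`) are fully deep; other synthetic types are deep at
`0.7 × NoTill` — 0.7 being the base-topdressing ratio, the fraction applied
before sowing and hence incorporable — and manure/residues at `1 − NoTill`,
since they are incorporated only where tillage remains.  Surface is the
complement, so surface + deep = 1 holds exactly by construction.  The 0.7
ratio is applied uniformly across crops.

### Uncertainty

The Monte Carlo targets the constant-ratio assumption only.  Per crop group
and region, the CV of survey consumption across the five anchor years sets
the scale; each year-to-year change ratio is multiplied by an independent
N(1, CV) draw truncated at zero (negative ratios are meaningless), and
trajectories are rebuilt outward from the year-2000 anchor — the reference
year of the whole reconstruction — in both directions.  Percentiles
2.5/97.5 and the SD are taken across 1,000 iterations by default (tests use
a few hundred).  Truncation at zero and the multiplicative mean-1 form are
this package's choices where the perturbation convention was open.

### Diagnostics

The country-wise relative difference is
`Dif = (Nrate − Nrate_ref) / Nrate × 100` — the denominator is always the
reconstructed rate, so the statistic is *not* antisymmetric under swapping
its arguments; entries with a zero reconstructed rate are undefined,
excluded from summaries, and counted.  Conservation audits compare, at
1e-9 relative tolerance (every correction is a single multiplicative
factor, so anything beyond rounding error is a defect): gridded vs national
harvested area, county vs national SN, anchor-year group amounts vs the
surveys, type-share sums vs 1, and placement sums vs 1.

## 2. The synthetic world

The generator emits every input the pipeline consumes from one seeded
ground truth: county rates are a year-2000 map times country-uniform
logistic growth per class; county areas are a reference map times
country-uniform growth per crop; amounts, national series, survey tables,
and type-consumption panels are the corresponding aggregations, each
optionally perturbed by multiplicative log-normal noise (`noise_sd`,
default 0.05; 0 gives the exact regime).  One political disintegration is
always generated; the 1962–1972 type-consumption block is blanked for all
units plus 6% of the remaining cells at random; cropland is
decadal-constant before 2000, annual to 2017, constant after.

Two generative constraints are deliberate: the parent-era growth shape is
crop-independent, and national crop growth shares one country shape after
2014.  Both are exactly the premises of the re-attribution and extension
rules — a world violating them cannot be recovered exactly by *any* method
using those rules, so the noise-free world is built on the premises and the
noisy world probes robustness instead.

Default study conditions: 1961–2020, 4 countries × 3 rectangular counties
on a 24 × 48 grid (the production 5-arc-min grid, 2160 × 4320, runs through
the same code path), 2 survey-reporting regions, no-till adoption amplitude
0.25 of cropland (the upper end of observed global adoption), year-2000
rate levels of 20–130 kg N ha⁻¹ depending on the crop group.  Rates,
areas, and compositions are drawn once per seed; identical configuration
gives a bit-identical world.

What the generator does **not** emulate: realistic geography or borders,
multi-cropping calendars, correlated cross-country shocks, reporting-unit
changes other than one clean disintegration, and measurement error
structure beyond independent log-normal noise.  Passing recovery tests
therefore shows the allocation algebra is implemented correctly and is
exact under its own premises — not that the premises hold for real
statistics.

## 3. Numerical conventions

- Cells are indexed row-major from the north-west corner; areas are
  per-cell totals (ha), computed by spherical approximation.
- Zero denominators never poison results: 0/0 ratios resolve to 0 and the
  paired amount is either spread uniformly (where a target must be
  conserved) or flagged unallocatable (where it must not be invented);
  every such event is logged.
- EM: ridge 1e-6 on the covariance, convergence at 1e-6 relative change,
  100 iterations maximum; rows grouped by missing pattern.
- The no-till regression fit is bounded (amplitude ≤ 1, positive scale) so
  the fitted curve is monotone non-decreasing and clips to [0, 1].
- HDF5 records are year-major, gzip level 4, with timestamp tracking
  disabled so identical runs are byte-identical.  File names use a plain
  hyphen in the year span by default; `--en-dash` reproduces the deposited
  spelling.

## 4. Known limitations

- The constant-ratio assumption is wrong in reality (crop-specific rates do
  not move in lockstep); the Monte Carlo quantifies exactly this and
  nothing else — imputation and no-till uncertainty are not propagated.
- Calibration before 2003 is absent; early-period rates inherit the prior
  product's structure unchecked.
- The placement rules reduce agronomy to three branches and one constant;
  application timing and frequency are out of scope.
- County-level rates are broadcast uniformly to cells, so within-county
  heterogeneity is absent by construction.
- The real global inputs (statistics downloads, reference rasters) are not
  fetched; adapters expect their shapes, and all testing is against the
  synthetic world.
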
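# Methods

This note documents the modelling choices behind `vitivuln`: the
procedure each stage implements, the parameters that matter and their
defaults, the conventions adopted where the underlying methodology is
genuinely open, and what the synthetic studies do and do not demonstrate.

## Bioclimatic indices

All three indices are computed from monthly climatologies (12 values per
cell per variable), the resolution at which gridded climate normals are
commonly distributed. The growing season is fixed to April–September;
only Northern-Hemisphere latitudes are supported.

**Huglin index.** The index is defined on daily data; on monthly inputs we
approximate the daily sum by the monthly mean excess times the month
length, applying the `max(0, ·)` clamp at month level so that cold months
cannot offset warm ones. An unclamped variant is exposed
(`huglin_index(..., clamp=False)`) for sensitivity analyses; the clamp is
the default because a negative monthly heliothermal contribution has no
physical meaning. The day-length coefficient `K` uses the published
stepwise table (1.00 below 40°N rising to 1.06 at 48–50°N); between 50 and
60°N the last value is carried forward, and beyond 60°N the function
raises unless `extend_k=True` — the table is simply not defined there.

**Cool Night Index** is the September monthly-mean minimum temperature,
exactly; no smoothing or weighting.

**Dryness Index.** Riou's potential water balance with the standard
parameterisation: initial and maximal reserve `Wo = 200 mm`; vegetation
absorption coefficient `k = 0.1` (April), `0.3` (May), `0.5` (June to
September); effective bare-soil evaporation days `JPm = min(N, P/5)`. The
reserve is capped at `Wo` (surplus runs off) but may go negative — the
conventional reading, in which negative end-of-season values express a
potential deficit class rather than a physical water content. All
constants live in `DIParams` and are configurable.

**PET.** The input contract carries no humidity, wind or radiation
observations, so potential evapotranspiration defaults to the Hargreaves
temperature-only formula, `0.0023 · Ra · (T + 17.8) · √(Tmax − Tmin)` per
day, with extraterrestrial radiation `Ra` from the standard astronomical
formulas at mid-month, converted at 2.45 MJ kg⁻¹. A `pet` variable in the
climate input overrides the estimate, which is the recommended route when
a proper PET product is available; Hargreaves is known to drift from
Penman–Monteith in humid and windy climates.

**Regional aggregation** is the weighted mean over member cells.
Memberships are whole cells in the synthetic studies, but the aggregation
honours fractional weights, so partial-coverage rasterisations of real
polygon boundaries plug in without code changes. The within-region
weighted SD of HI is reported (`hi_sd`) as the spatial thermal-variability
diagnostic that feeds the climatic-niches indicator in real applications.

## Exposure

Per-region deltas between a present and a future period are oriented so
that the adverse direction is positive: warming raises HI and CNI, and
drying *lowers* DI, so the DI delta is sign-flipped. Deltas are signed by
default — a region whose climate gets wetter scores low on the DI
component rather than high; `mode="absolute"` treats any change as
adverse. Aggregation order follows the cell → region mean → cross-region
min–max scale sequence, then the three scaled components are averaged.

A min–max scale over an all-equal column is undefined; it maps to all
zeros here, on the reasoning that an index that changed identically
everywhere differentiates no region. This matters mostly in degenerate
test fixtures, but the rule is deliberate and tested.

The ensemble-spread diagnostic (per-cell range and SD across climate-model
members) quantifies model disagreement; it is reporting-only and does not
enter the exposure score.

## Varieties and sensitivity

**Canonicalisation** maps variety names through country-scoped synonym
tables, consulting the primary list (tier 1) before the secondary list,
mirroring how name homogenisation is done against national registers.
Unmatched names are kept verbatim, flagged, and — because they can carry
no cultivation area — drop out of sensitivity with a logged count.
Conflicting synonym targets within one country are an error, not a
silent choice.

**Primary-variety fallback**: regions that explicitly split primary from
additional varieties keep the split; regions with no split have all
authorized varieties treated as primary.

**Cultivation-area allocation.** Areas given at macro-region level are
distributed over the macro's member regions that authorize the variety,
proportionally to each member's total vineyard area. The split conserves
the macro total exactly (tested to 1e-9 relative); a macro-level variety
authorized by no member is dropped with a warning.

**Climate groups.** Regions are grouped by the multicriteria class triple
of (HI, CNI, DI), with edges defaulting to the Géoviticulture multicriteria
classification (HI: 1500/1800/2100/2400/3000 °C·days; CNI: 12/14/18 °C;
DI: −100/50/150 mm). The group inventory is the set of observed triples —
a reconstruction, since assessments of this kind typically publish the
count of groups rather than the exact table. Bins are right-closed
(a value exactly on an edge takes the lower class) and values beyond the
outer edges take the terminal class.

**Bioregional ranges.** Per (variety, group, index): cultivation-area-
weighted mean, area-weighted population-style SD, and upper limit
mean + m·SD with multiplier `m = 1` by default (configurable via
`range_sd_multiplier`; the ±1 SD width is the natural reading of
"mean combined with the standard deviation").

**Sensitivity.** The margin `upper_limit − current value` is computed per
(region, primary variety, index). Because the three margins live in
different units (°C·days, °C, mm) they are standardised per index before
averaging; z-scoring across all (region, variety) pairs is the default,
with min–max and raw-unit strategies available
(`standardization="minmax" | "raw"`). The averaged margin is negated
(small or negative margin ⇒ high sensitivity), area-weighted over the
region's primary varieties, and min–max scaled across regions. The
qualitative ordering — regions near or beyond their varieties' upper
limits score highest — is invariant to the strategy choice; the tests pin
the ordering, not the strategy.

**Positive effects.** A variety benefits from a scenario if its mean
absolute standardised deviation from the reference value (the group-wise
present-day weighted mean) is strictly smaller under future than under
present conditions; ties count as not benefiting. A per-index majority
rule (`benefit_rule="majority"`) is provided as an alternative. The
regional share is area-weighted by default (`weighting="count"` for a
plain fraction). Deviations are standardised by the across-region SD of
each present-period index so the three indices contribute comparably.

## Adaptive capacity

Each of the 15 indicators is scaled by `AC_i = (X − Q5)/(Q95 − Q5)`,
clamped to [0, 1] — the 5th/95th-percentile thresholds winsorise outliers
by construction. Percentiles use linear interpolation between order
statistics (conventions differ between software packages; this one is
stated and tested). A degenerate column (Q5 = Q95) contributes a constant
zero. Indicators whose larger raw values mean *less* capacity — aging
index, dependency ratio, population density, research-accessibility
distance, debt ratio, subsidy dependence — are inverted after scaling.
This direction table is a reconstruction from the meaning of each
indicator and ships as editable configuration (`directions.toml` in
fixtures); both polarities are covered by tests.

The composite is the flat equal-weight mean of the 15 scaled indicators
(the neutral choice when region-specific weights cannot be justified
continent-wide), min–max rescaled across regions. Dimension means (social,
physical, natural, human, financial) are attached for reporting only —
the flat mean, not a dimension-nested mean, is the score.

**AHP.** Expert pairwise-comparison matrices are reduced to weights by the
principal eigenvector (power iteration, tolerance 1e-10), with consistency
ratio `CR = ((λmax − n)/(n − 1))/RI(n)` using Saaty's random-index table
through n = 15. A matrix is accepted only if CR < 0.10, strictly. AHP
weights are an alternative aggregation mode; equal weights remain the
default. Rank correlations between expert weight vectors
(`weight_concordance`) quantify inter-expert agreement.

## Vulnerability classification

Scores are cut at the 33.33rd/66.67th percentiles; ties on a cut resolve
downward (v ≤ cut → lower class), consistent with the right-closed binning
used elsewhere. The level rules are evaluated in precedence order —
very-high, high, low, moderate — which turns the prose rules into a true
partition of all 27 class triples; the full truth table is exercised
exhaustively in the tests, together with the consistency of the group →
level projection (6 → very high; 3, 4, 5 → high; 2 → moderate; 1 → low)
and a monotonicity check (worsening any one class never lowers the level).
Classification is scale-free: any strictly increasing transform of a score
column leaves all classes unchanged.

## Synthetic studies

The generator emulates every input the pipeline consumes, from one integer
seed through one explicit random generator (no global state):

- smooth monthly climate fields with a north–south temperature gradient,
  low-frequency pseudo-orographic texture, a summer-dry precipitation
  cycle, and i.i.d. noise of scale `noise_sd` (one shared temperature
  shift per cell keeps `tasmin ≤ tas ≤ tasmax` exact);
- future scenarios as uniform additive warming plus multiplicative
  precipitation change, with their own noise realisation; pseudo-GCM
  members are the scenario field plus zero-mean perturbations, so the
  ensemble mean reproduces the scenario exactly by construction;
- regions as contiguous blobs (discrete Voronoi partition around jittered
  seeds with a flood-fill contiguity repair), with lognormal vineyard
  areas and longitude-band country labels;
- varieties with true climatic optima placed in the observed regional
  climate space; cultivation areas decay as a Gaussian in standardised
  climate distance from the optimum (bandwidth 0.6 by default), which
  makes the area-weighted range mean a consistent estimator of the
  optimum — the premise of the recovery tests;
- macro-region indirection (a configurable share of cultivation rows
  re-addressed at macro level), country-scoped synonym aliasing of a
  configurable fraction of variety mentions, an equicorrelated indicator
  table, and an AHP matrix built from a known weight vector with small
  multiplicative noise.

The ground truth (variety optima, noise-free exposure ranking, true AHP
weights) is persisted with each fixture so recovery can be scored without
re-deriving it.

Default problem sizes: a 60×60 grid over 36–51°N, 60 regions, 20
varieties, a +2.5 °C / −15 % precipitation scenario, 5 ensemble members.
The recovery and monotonicity studies use 200 regions; the scenario-ladder
study uses 80 regions on a 40×40 grid with warming factors 0.5/1.0/1.6 of
the configured delta standing in for an ssp126/ssp370/ssp585 ladder. The
recovery study narrows the cultivation kernel to bandwidth 0.3 and sets
`noise_sd = 0.05`, realising the "areas concentrated at the optima, noise
small" premise under which the weighted-mean estimator is consistent;
with the wider default kernel the recovery correlation for DI degrades
toward ~0.87 on some seeds because the regional DI distribution is
narrower than HI's and partially capped at `Wo`.

What passing these studies does **not** show: the fixtures are statistical
stand-ins, not European geography. Real applications face partial-cell
polygon coverage, non-Gaussian cultivation patterns shaped by history and
regulation rather than climate distance, synonym tables with genuine gaps
(match rates well below 1), spatially structured indicator errors, and
climate-model spread that is not a zero-mean perturbation of a known
scenario. The pipeline surfaces the relevant levers (fractional weights,
match reports, dropped-allocation warnings, the spread diagnostic) but the
synthetic results validate the machinery, not continental conclusions.

## Numerical conventions and reproducibility

- Identical configuration ⇒ byte-identical outputs; fixtures and runs are
  hashed (SHA-256) in their manifests and the determinism is tested.
- Stage CSVs are written with `%.17g` floats and read with exactly-rounded
  parsing so that stage-wise reruns reproduce `run_all` bit for bit;
  without this, last-ulp differences can flip a tertile class at a tied
  cut.
- NetCDF I/O uses xarray's scipy backend (NetCDF3 classic); GeoJSON
  regions are round-tripped through shapely point-in-polygon tests on
  cell centres.
- All randomness flows from `SynthConfig.seed` via child generators; no
  library or global seed is touched.

## Known limitations

- Monthly approximations of HI and of the Riou balance differ from their
  daily-resolution definitions; the bias is systematic and shared across
  regions, which the relative (min–max) scaling largely absorbs.
- Hargreaves PET is temperature-only; supply a `pet` variable for humid
  or windy regimes.
- Southern-Hemisphere seasons and latitudes beyond 60°N are out of scope.
- The sensitivity functional form (standardise → negate → weight →
  rescale) makes a qualitatively stated relation concrete; alternative forms reorder
  mid-scale regions but not the extremes, and the strategy switch exists
  precisely to probe that.
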
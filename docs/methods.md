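# Methods

## Basket construction

The basket adapts per-subgroup daily gram targets (an EAT–Lancet-style
reference diet) to a reference population's revealed purchase structure.
Shares are computed on purchased *mass* within each subgroup (an
expenditure-share variant would be possible but mass is the default and the
only mode exercised by the packaged tables); the subgroup target is then
distributed proportionally and converted to purchase quantities with the
food transformation index (FTI), purchased = consumed / FTI. All arithmetic
is carried at full precision; two-decimal rounding is applied only by
`round_for_report` and in printed output, matching how published tables are
rounded.

Options that shape the share table, with defaults:

* `min_share` (0): drop items below this within-subgroup share, renormalise.
* `coverage` (1.0): alternatively keep the largest items until this fraction
  of subgroup mass is covered. The published basket keeps long-tail items
  down to 0.13%, so both default to "keep everything".
* `marginal_fraction` (0.001 in the pipeline): a subgroup holding less than
  this fraction of the stratum's total purchased mass is treated as
  marginal consumption and receives a zero allocation. A fractional
  threshold was chosen over an absolute one because it is invariant to
  units and to the number of households surveyed; an absolute
  `marginal_quantity` is also accepted. The packaged synthetic survey puts
  nuts-and-seeds at ~0.006% of stratum mass, an order of magnitude below
  the cutoff, while the smallest genuinely consumed subgroup (saturated
  oils) sits near 0.7%, far above it.
* Items are keyed by (subgroup, item): the same name may legitimately occur
  in two subgroups (cucumber appears under both vegetables and fruits) with
  different adjustment factors. Prices, however, are per item *name*; when
  costing, the grams of duplicate names are summed.
* A missing FTI entry defaults to 1 with a logged warning rather than
  failing, since factor tables are assembled from heterogeneous sources.

One cell of the packaged basket fixture deviates from its printed source:
the melons adjustment factor is stored as 0.52 (flagged `back-solved` in
the source column) because the printed factor is inconsistent with both the
printed purchased-gram cell and the printed fruits subgroup total, which
the stored value reproduces.

## Nutrient profile

Per-item nutrient values (kcal and g per 100 g) multiply the consumed-gram
column by default; a `purchased` basis is available because composition
tables differ in whether they describe prepared or as-purchased food.
Atwater factors are configurable constants, default 4/4/9 kcal per g of
protein/carbohydrate/lipid. Macronutrient energy shares need not sum
to 100%: fibre, alcohol and rounding leave unaccounted energy.

The packaged per-item nutrient table is *synthetic*: the published record
gives only subgroup totals, which constrain per-item densities one
equation per subgroup. The fixture freezes the minimal solution — every
item in a subgroup carries the subgroup-average density — so aggregation
reproduces the published totals exactly while making no claim about real
per-item composition. Real analyses should supply a measured composition
table.

## Price panel

CPI-style price series arrive in base-year segments with segment-scoped
item labels and levels. The panel builder:

1. **Screens** gross outliers *per raw (segment-scoped) series*, before any
   splicing, so corrupt observations cannot distort splice ratios. With an
   admissible-range table, hard bounds apply; without one, a robust
   fallback flags prices further than max(k·MAD, 0.5·median) from the
   centred 12-month rolling window median (k = 5). The relative floor
   reflects what admissible ranges are for — catching order-of-magnitude
   recording errors, not trimming ordinary dispersion — and keeps the false
   positive rate at zero under realistic noise while leaving ten-fold
   errors unmistakable.
2. **Splices** segments chronologically, latest authoritative: each earlier
   segment is rescaled per item by the ratio of mean prices in the overlap
   months (flagged rows excluded from the means); items without overlap use
   the median ratio of items that have one. In overlap months the later
   segment's observations win.
3. **Collapses** to item × month cells: mean and minimum over retained
   observations, with status `observed`, or `corrected` if any observation
   in the cell was removed.
4. **Imputes** every missing cell in the analysis window from the same
   item's temporally nearest observed month; an exact tie averages the two
   neighbours. A donor-item variant (most price-correlated other item,
   level-rescaled) exists behind `method="donor"` for series with long
   gaps, but temporal is the default and the tested path. Observed cells
   are never altered, and imputed cells are marked as such, so
   observed + corrected + imputed counts partition the window exactly.

Months are (year, month) integer pairs and windows are closed intervals;
April 2014 – December 2023, the default analysis window, spans 117 months.

## Costing and comparison

Monthly cost sums daily purchased kilograms × price per kg × days in the
month, at minimum prices by default (the reference-basket convention).
`days_policy` defaults to calendar month lengths — this convention makes
monthly and per-day USD figures mutually consistent — with a fixed-30-day
alternative. USD conversion divides by the month's mean daily exchange
rate.

Gap analysis reports the monthly percentage gap, its mean, and three peak
locators: the single widest/narrowest months on record, the calendar month
with the highest average gap across years, and a first-harmonic phase
estimate (`peak_phase_month`) obtained by regressing the gaps on an annual
cosine. The harmonic estimator is the right tool when the seasonal pattern
is smooth: comparing twelve month-of-year averages discriminates poorly
near a flat seasonal peak (adjacent months differ by less than one noisy
standard error), while the phase fit pools all months and locates the peak
with a standard error of a few hundredths of a month at the generator's
default noise.

Poverty thresholds follow the Orshansky construction: total line =
coefficient × monthly basket cost (default 2.68), extreme line = ⅔ of the
total line.

## Synthetic data generator

The generator stands in for three undistributable sources and is the basis
of all closed-loop tests; every draw is keyed to a seed through
stage-tagged independent streams, so runs are reproducible and stages
independent.

* **Survey**: per stratum and subgroup, a true share vector is drawn from a
  Dirichlet centred on geometrically decaying weights (decay 0.8,
  concentration 50), yielding the concentrated, right-skewed structure of
  real purchase shares — a top item near 20% and a long tail. Households
  (default 2000 per stratum; 10,000 in the share-recovery check) draw
  lognormal subgroup totals (σ = 0.4) scaled to 30× the subgroup's daily
  gram target, split across items by a Dirichlet with concentration 25
  around the true shares. Aggregated shares are unbiased for the truth; at
  10,000 households the maximum absolute error is ~0.002, comfortably
  within the 0.01 recovery requirement. Nuts-and-seeds totals are overridden
  to ~3 g/household/month to emulate a marginally consumed subgroup.
* **Prices**: monthly true price = item level × (1 + 0.04·t years) ×
  (1 + a·sin seasonal), with a = 0.10 for fresh produce and 0.03 otherwise
  (fresh items are genuinely more seasonal), item-specific peak months,
  lognormal observation noise σ = 0.03 across 4 outlets, whole item-months
  missing at 5% (never a segment-break month, so overlap always exists),
  observations inflated 10× at 2% with truth labels, and a known lognormal
  level shift (σ = 0.15) per pre-break segment with one overlap month at
  each break (default break April 2018). Price levels are plausible
  CLP-per-kg magnitudes only; matching any real price history is a
  non-goal.
* **Exchange rates**: a daily geometric random walk (level 800, daily log-sd
  0.004), averaged monthly downstream.
* **Paired cost series**: a reference series (trend + mild seasonality +
  1% noise) and a target equal to the reference × (1 + premium(month)) ×
  independent 1% noise, where the premium is a sinusoid (default mean
  13.9%, amplitude 7 pp, peak October). The expected monthly gap equals the
  premium exactly, so mean- and peak-recovery tests have analytic truth.

What passing these tests shows — and does not. They demonstrate that each
stage recovers known structure under realistic noise, missingness and
level breaks; they cannot show that real CPI microdata satisfy the
generator's assumptions (multiplicative lognormal noise, sinusoidal
seasonality, a single annual harmonic in the premium, missingness
independent of price). In particular the December trough reported for the
real series is not reproducible by a sinusoid peaking in October; the
premium profile accepts arbitrary 12-month vectors for such shapes.

## Numerical choices and degenerate inputs

Empty share sets allocate zero grams; all-zero subgroups are flagged, not
errors. Non-positive FTI factors, prices, exchange rates, targets and
basket costs are rejected with the offending item named. Share
renormalisation tolerates floating error to 1e-9. Imputation of an item
with no observations at all is an error rather than a guess. The
coverage cutoff uses a stable sort, so ties keep input order.

## Known limitations

* The official reference-basket series is an input; the package never
  re-derives its composition, and poverty-headcount simulation is out of
  scope.
* The temporal nearest-neighbour rule ignores seasonality: a month imputed
  from its neighbour inherits the neighbour's seasonal level. Over the
  default 5% missingness this biases monthly costs negligibly, but long
  gaps in strongly seasonal items would benefit from the donor method.
* Splice ratios rest on a single overlap month per break; their sampling
  noise (~σ/√n_outlets per segment pair) shifts whole pre-break segments
  coherently.
* Analysis sizes in tests and scripts (households, window lengths, outlet
  counts) are the module defaults above, chosen to keep closed-loop
  standard errors well inside the recovery margins.
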
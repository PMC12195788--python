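# basketcost

Tools for costing a *healthy and sustainable* basic food basket against the
reference basket that anchors a poverty line.

Official basic food baskets (the kind used to define poverty lines in Latin
America) are built for caloric sufficiency at minimum cost. Public-health
researchers increasingly want to know what it would cost the same low-income
households to eat a diet that is also healthy and environmentally
sustainable — for instance one aligned with the EAT–Lancet reference diet's
per-food-group gram targets. `basketcost` implements that analysis end to
end: it adapts group-level gram targets to a population's observed purchase
shares, converts consumed grams into purchase quantities with
edible-portion/yield factors, profiles the resulting basket's energy and
macronutrients, builds a continuous monthly price panel from consumer price
index (CPI) segments, and compares the basket's monthly cost against an
official reference series in local currency and USD.

## Method

For each food subgroup *g* with daily gram target *T_g*, item *i*'s share of
the reference stratum's purchases is

    s_i = q_i / Σ_{j∈g} q_j

where *q_i* is the quantity purchased (household budget survey, lowest
income quintile by default). Consumed grams are allocated proportionally,
`c_i = s_i · T_g`, and converted to purchased grams with the item's food
transformation index *f_i* (prepared mass per purchased mass):

    p_i = c_i / f_i

so a peeling loss (*f* < 1) raises the purchase quantity and a cooking gain
such as rice absorbing water (*f* > 1) lowers it. Subgroups with marginal
consumption are excluded (zero allocation). Energy and macronutrients come
from per-100 g values; macronutrient energy shares use Atwater factors
(4/4/9 kcal/g for protein/carbohydrate/lipid).

Pricing follows the reference-basket convention: per item and month, the
*minimum* observed price; monthly basket cost is

    C(m) = Σ_i (p_i / 1000) · P_i(m) · days(m)

with *P_i(m)* in currency per kg. The price panel is built from CPI
base-year segments by name standardisation, ratio splicing on overlap
months (latest segment authoritative), admissible-range outlier screening
(hard ranges, or a robust median ± k·MAD fallback), and temporal
nearest-neighbour imputation of missing months. Costs convert to USD with
monthly-mean daily exchange rates; gaps between two baskets are reported
month by month with mean and seasonal extremes, and an Orshansky multiplier
(default 2.68, extreme line = ⅔) turns a basket cost into poverty
thresholds.

Because the underlying survey and CPI microdata are not redistributable,
the package ships (a) the published basket/target/factor and nutrient-total
tables as fixtures and (b) a synthetic-data module that generates survey,
price, exchange-rate and reference-cost inputs with known ground truth, so
every stage is testable closed-loop.

## Worked example

```
$ python analysis/01_simulate.py     # synthetic inputs -> scratch/
$ python analysis/02_build_basket.py
fixture basket: 65 items; max purchased-gram deviation from the published table 0.0093 g
  tomato: share 22.57% of vegetables -> 67.72 g/day consumed
  purchased totals: vegetables 369.85 g, whole grains 223.02 g, fruits 411.85 g, legumes 68.54 g
synthetic-survey basket: 65 items; marginal subgroups excluded: ['Nuts and Seeds']
$ python analysis/03_nutrient_profile.py
daily energy: 2001.22 kcal (73.58 g protein, 260.23 g carbohydrate, 71.98 g lipid)
energy shares: protein 14.71%, carbohydrate 52.02%, lipid 32.37%
```

Reading: of the 300 g/day vegetable target, tomatoes get 22.57% (their
share of the quintile's vegetable purchases) = 67.72 g consumed; after
yield adjustment the 300 g of vegetables require 369.85 g purchased. The
full basket delivers ~2001 kcal/day with a balanced macronutrient split.
Steps 04–05 build the price panel (screening recall and provenance counts
are printed against the generator's truth labels) and run the cost
comparison, e.g.:

```
$ python analysis/05_cost_comparison.py
premium recovery: configured mean 13.98% peak month 10; recovered mean 14.01% peak month 10
```

The same stages are scriptable via the `basketcost` CLI (`simulate`,
`build-basket`, `nutrients`, `price-panel`, `cost`, `run`) or the
`basketcost.pipeline.run_pipeline` API.

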
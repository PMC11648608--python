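# dietswap

Multicriteria assessment of meat and milk alternatives: a tested, reusable
pipeline for comparing foods — and whole-diet replacement scenarios — from
nutritional, health, environmental, and cost perspectives, and for
synthesizing the four domains into a single 0–100 score.

It is aimed at nutrition and sustainability researchers who want to run
product comparisons and "replace all meat / all dairy" scenario analyses on
their own composition, footprint, price, and mortality tables, with every
modelling step exposed as an importable, unit-tested function.

## What it computes

**Nutritional imbalance.** For a diet with nutrient intakes $I_n$ and
recommendations $R_n$ (each a *minimum* or a *maximum*), the imbalance
indicator is the mean violation magnitude over the $N$ recommended
nutrients, in percent:

$$\mathrm{NI} = \frac{100}{N}\left[\sum_{\text{min},\,I_n<R_n}\frac{R_n-I_n}{R_n} \;+\; \sum_{\text{max},\,I_n>R_n}\frac{I_n-R_n}{R_n}\right]$$

Compliant nutrients contribute zero; calcium is excluded. Zinc and iron
requirements are diet-dependent: zinc by linear interpolation in a
phytate–requirement reference table, iron as target absorbed iron divided
by a blended absorption fraction (constant heme absorption; nonheme
absorption log-linear in phytate, calcium, vitamin C, and meat intake).

**Comparative risk assessment.** Six exposures drive chronic-disease risk:
PUFAs, fiber, and potassium (protective; potassium benefits capped at
3,500 mg/day), cholesterol, sodium, and heme iron (harmful). Dose–response
is log-linear, $RR(\Delta) = RR_{\mathrm{unit}}^{\Delta/u}$, factors
combine multiplicatively, and the population impact fraction for an
exposure shift is $\mathrm{PIF} = (RR_{\mathrm{base}} -
RR_{\mathrm{scen}})/RR_{\mathrm{base}}$, applied to cause-specific deaths
(CHD, stroke, cancer) to yield attributable deaths and the all-cause
mortality change.

**Environment.** Footprints (GHG kg CO₂eq, land m², water L, per kg) are
converted to serving/calorie bases, expressed per domain as a percentage of
a high-impact benchmark (beef; or the whole/low-fat milk average), and
averaged with planetary-boundary weights $w = (0.65, 0.17, 0.18)$ for
(GHG, land, water).

**Cost.** Prices are CPI-deflated to 2020 and PPP-converted to
international dollars; diet cost is linear in quantities.

**Replacement and synthesis.** A scenario removes all foods of a category
and substitutes one alternative, conserving calories (or servings). The six
per-domain outcomes are min-max normalized within a candidate pool (best
change → 1, worst → 0) and combined as

$$S = 100\left[\tfrac13\left(\tfrac12 s_{\mathrm{nut}} + \tfrac12 s_{\mathrm{mort}}\right) + \tfrac13\left(0.65\,s_{\mathrm{GHG}} + 0.17\,s_{\mathrm{land}} + 0.18\,s_{\mathrm{water}}\right) + \tfrac13 s_{\mathrm{cost}}\right].$$

A seeded synthetic-data generator produces complete, internally consistent
input bundles (foods, diets, recommendations, relative risks, footprints,
prices, mortality) so the whole pipeline is runnable and testable without
any external data. The packaged recommendation/relative-risk defaults are
illustrative; substitute your own harmonized tables for real analyses.

## Worked example

```sh
dietswap synth --seed 0 --out bundle/
dietswap run --bundle bundle/ --replace meat --with soybeans --basis calorie --out changes.csv
```

prints the six domain changes of replacing all meat calories with soybeans
in the synthetic high-income baseline diet:

```
  nutrition_pp: +0.56
 mortality_pct: -14.24
       ghg_pct: -36.33
      land_pct: -37.13
     water_pct: -36.45
      cost_pct: -10.41
```

Nutrition is in percentage points of the imbalance indicator; the rest are
percent of the baseline diet's value (negative = improvement): the swap
cuts diet-attributable mortality by ~14%, every environmental footprint by
~36–37%, and diet cost by ~10%, while the imbalance indicator worsens
slightly (+0.6 pp) because the packaged illustrative diet then undershoots
some micronutrient recommendations. `dietswap run-all` +
`dietswap synthesize` score and rank the full candidate pool; see
`examples/` for the library-level equivalents (per-serving comparisons,
environmental benchmarking, synthesis scores and weight-scheme
sensitivity).

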
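# Methods

This note documents the models behind `dietswap`, their assumptions, the
parameters that matter, and the choices made where the design was open.

## Nutritional imbalance

The indicator is the mean violation magnitude across all nutrients carrying
a recommendation: shortfalls below minimum recommendations and excesses
above maximum limits both enter as positive percentages of the recommended
value, compliant nutrients contribute zero, and the sum is divided by the
number of recommended nutrients. Consequences of this definition, all
covered by property tests: the indicator is non-negative and zero exactly
when no recommendation is violated; it is invariant to nutrients without
recommendations; doubling every violation magnitude doubles it; and
per-nutrient deviations are uncapped (a 60% saturated-fat excess counts as
60). Energy ("calories") participates as a maximum-limit nutrient. Calcium
is excluded by construction — current reference values derive from balance
studies of current intake, so comparing intake to them is circular.

Two requirements are diet-dependent and re-resolved for every diet
(baseline and each scenario) before the indicator is computed:

- **Zinc.** The requirement is linearly interpolated in a monotone
  (phytate, requirement) reference table and clamped at the table ends.
  The packaged table (300→6.2 mg … 1200→10.2 mg) is an illustrative,
  editable stand-in at the magnitude of published phytate-dependent
  population references.
- **Iron.** Requirement = target absorbed iron / blended absorption.
  Heme iron is absorbed at a constant, configurable fraction (default
  0.25); nonheme absorption is log-linear in four dietary mediators —
  phytate (−), calcium (−), vitamin C (+), meat (+) — clamped in log space
  into (0, 0.5] so extreme intakes cannot overflow or exceed a plausible
  ceiling. The blend weighs heme vs. nonheme absorption by their shares of
  total dietary iron; an iron-free diet falls back to the nonheme fraction
  (marginal iron would be nonheme). Coefficients live in
  `IronModelParams`, packaged as labeled, editable defaults; tests use
  closed forms (an all-heme diet needs target/0.25) and monotonicity, not
  the default values.

The change decomposition assigns each nutrient the change in its violation
term divided by the number of recommended nutrients; because the indicator
is additive over violation terms, each contribution equals the leave-one-out
indicator change, which is the oracle the tests use. Shares are sign-aware
and sum to 100% of the total change.

## Comparative risk assessment

Exposures are the daily intakes of PUFAs, fiber, potassium, cholesterol,
sodium, and heme iron. Modelling assumptions:

- **Log-linear dose–response**: the relative risk of an exposure shift Δ is
  `RR_unit ** (Δ/u)` for a tabulated RR per increment u. This is the
  standard comparative-risk-assessment form and the only one under which
  per-unit RRs compose across shifts.
- **Multiplicative combination** across risk factors, the standard CRA
  independence assumption.
- **Potassium cap**: exposure above 3,500 mg/day confers no further
  benefit. The cap is applied inside the risk computation only; raw
  exposures are preserved in outputs.
- **Reference exposure cancels** in the PIF ratio, so the implementation
  normalizes RRs to the baseline exposure (baseline RR = 1, PIF = 1 −
  RR_scenario), which is numerically stable; a test checks equality with an
  independent recomputation against an arbitrary common reference over an
  exposure grid.

PIFs are computed per endpoint (CHD, stroke, cancer) and applied to
cause-specific death envelopes; the mortality change is total averted
deaths as a percentage of all-cause deaths. Per-serving risk changes
combine endpoint-level RR shifts into one number by weighting endpoints
with their shares of cause-specific deaths in the analysis region — the
combiner is explicit, configurable (any endpoint subset), and reduces to
RR − 1 for a single endpoint. Two comparison modes exist: one serving added
to a context diet (default context: zero) or a swap against a benchmark
food's serving. The factor decomposition reports |Δlog RR| shares, endpoint
weighted the same way.

The packaged RR table is illustrative: all six factors map to CHD and
stroke, heme iron and fiber additionally to cancer; magnitudes are at the
scale of meta-analysis estimates (e.g. fiber 0.93/10 g for CHD, sodium
1.06/1000 mg). Uncertainty propagation of RR confidence intervals and
age/sex stratification are out of scope (population-aggregate analysis).

## Environment

Footprints are stored per 100 g internally (the composition-table
convention), read and written per kg (the LCA convention). Per-serving and
per-calorie conversions are exact rescalings and are tested for dimensional
consistency. Relative impacts divide a food's per-domain footprint by a
benchmark's on the same basis; the weighted score uses the
planetary-boundary weights GHG 0.65 / land 0.17 / water 0.18, reflecting
the relative contribution dietary change must make per domain to stay
within environmental limits. The milk benchmark is the mean of the whole
and low-fat milk footprints; the meat benchmark is beef; both are
configurable. Weighted scores are convex combinations (bounded by the
domain extremes) and scale-invariant, both property-tested. Reported
percentages are rounded half-away-from-zero to integers for presentation;
machine outputs keep full precision. A processing-emissions sensitivity
adds a per-kg GHG increment (e.g. cooking) to flagged foods, touching only
the GHG domain.

## Cost

CPI deflation (`price × CPI_base/CPI_year`) and PPP conversion
(`price/ppp`) commute; the harmonized price records full provenance
(source year, currency, CPI factor, PPP rate). Base year defaults to 2020.
Diet cost is linear in quantities at per-kg prices; serving conversions
reuse the core serving sizes. Where several observations exist per food,
users should supply the mean of harmonized observations; the bundle format
carries one record per food.

## Replacement scenarios

A scenario zeroes every food of the replaced category (meat, dairy, or
both) and adds a single alternative. On the calorie basis the alternative's
grams are removed-calories / energy-density, and total dietary energy is
asserted conserved to 1e-6 relative on every run; on the serving basis
replaced servings are matched one-for-one and energy is intentionally not
conserved. Removed intake is pooled across the category ("replace all
meat"), not mapped food-by-food. The candidate pool deliberately includes
animal comparators — consolidating a category into one of its own members
(all meat → only poultry) is a valid scenario so that comparators appear in
the synthesis ranking; only the degenerate identity replacement (the
alternative is the sole replaced food) is rejected. The added-salt
sensitivity adds sodium per 100 g to the alternative's profile; the
cultivated-meat style scoping enters as ordinary food entries with variant
tags and user-supplied footprints/prices — no separate machinery.

## Synthesis

Within a pool (one replaced category × basis × region), each domain's
changes are min-max normalized: score = 1 − (x − best)/(worst − best) with
"best" the most favorable (most negative) change. The anchors are
per-domain, so a food can score 1 in one domain and 0 in another; the
animal comparators are in-pool but do not necessarily anchor the worst end
of every domain. A degenerate pool (all changes equal) carries no
information and scores every food 1, with a warning. The summary score is
the 0–100 weighted combination described in the README; ties in ranking
break lexicographically by food id for determinism. Three weight schemes
ship: planetary-boundary (main), equal environmental subweights, and equal
weights across all six subdomains; rank correlations between schemes are
computed and reported, not asserted.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
database: per-category archetypes (beef/pork/poultry/burger; two milks; six
processed alternatives; six unprocessed plant foods; three staple
components) with small multiplicative jitter (default ±6%), fat
subcomponents generated as fractions of total fat and heme iron as a
fraction of iron so profile invariants hold for any draw. Structural knobs
— animal saturated-fat/heme/cholesterol elevation, plant
fiber/potassium/PUFA elevation, fortification of processed alternatives
(B12 +1.2 µg, riboflavin +0.25 mg, vitamin A +120 µg per 100 g), footprint
tiers (beef 50, other meat 8, dairy 3, plant 1.5 kg CO₂eq/kg, with land and
water scaled along), and a 1.8× price markup on processed alternatives —
are `GeneratorSpec` fields. The baseline diet allocates 2,500 kcal/day as
15% meat, 10% dairy, 75% other, evenly within category; the mortality
envelope is a fixed plausible high-income profile (10 M population, 90,000
all-cause deaths; 13,500 CHD, 7,000 stroke, 25,000 cancer). A single
integer seed drives one PRNG stream with deterministic substreams;
identical specs yield byte-identical bundles.

What the generator does **not** emulate: real nutrient covariance
structures, within-category price dispersion, regional footprint variation,
or inter-country CPI/PPP heterogeneity (one USD series, 2% inflation).
Passing tests on synthetic bundles therefore demonstrate correctness of the
computations and of the qualitative orderings forced by construction (beef
≫ plants environmentally, plants outranking beef overall), not agreement
with any published diet-level magnitudes — those depend on the real
composition, recommendation, RR, footprint, price, and mortality tables,
which users must supply in the bundle format.

Known-answer mode (`generate_known_answer_diet`) inverts the imbalance
indicator: given signed target deviations for every recommended nutrient it
builds a one-food diet (100 g/day) whose per-100 g profile equals
`rec × (1 + dev/100)`, padding total fat and iron so profile invariants
hold. The nutrition module recovers the targets to 1e-9 relative; this is
the parameter-recovery harness used throughout the tests.

## Numerical choices and degenerate inputs

- Weight trees validate to 1 ± 1e-9 at every level.
- Nonheme absorption clamps in log space to (0, max_absorption].
- Calorie-basis replacement requires a positive-energy alternative and
  asserts energy conservation at 1e-6 relative.
- Zero benchmark footprints, zero baseline domain totals, zero baseline
  diet cost, empty recommendation sets, non-monotone zinc tables, and
  all-zero risk-decomposition deltas are rejected with named errors.
- CSV readers use round-trip float parsing so write→read reproduces values
  to full precision; unknown or missing columns are hard errors.

## Problem sizes

The packaged defaults run a 21-food bundle, ~30 scenarios per matrix, and
six domains per scenario; the full test suite, including the end-to-end
pipeline smoke test, completes in well under a minute on a single CPU.

## Limitations

Population-average intakes vs. average requirements only (no intake
distributions); no uncertainty intervals; no partial-replacement fractions
or optimization over replacement mixes; footprints are inputs (no LCA
harmonization); the packaged reference tables are illustrative stand-ins,
so absolute baseline levels of the imbalance indicator and mortality change
are bundle-dependent even though all comparative structure is not.
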
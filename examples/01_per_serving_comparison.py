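"""Per-serving comparison of foods: nutrient density, disease risk, cost.

Generates a synthetic bundle, then for a few foods prints (a) which
nutrients one serving is a good (10-19% of the daily recommendation) or
high (>=20%) source of, (b) the overall disease-risk change of adding one
serving to the diet, and (c) the harmonized cost per serving.
"""

from dietswap import GeneratorSpec, generate_bundle
from dietswap import cost, health_cra, nutrition

bundle = generate_bundle(GeneratorSpec(seed=0))
prices = cost.harmonize_prices(bundle.foods, bundle.cpi, bundle.ppp)
mortality = bundle.mortality["HIC"]

densities = nutrition.nutrient_density_table(bundle.foods, bundle.recommendations)

for fid in ("beef", "soybeans", "veggie_burger", "whole_milk", "soy_milk"):
    food = bundle.foods[fid]
    good_or_high = densities[
        (densities["food_id"] == fid) & (densities["classification"] != "none")
    ]
    risk = health_cra.per_serving_risk_change(food, bundle.rr_table, mortality)
    per_serving = cost.cost_per_basis(food, prices[fid], "serving")
    print(f"\n{food.name} ({food.serving_g:.0f} g serving)")
    print(f"  good/high source of: "
          f"{', '.join(sorted(good_or_high['nutrient'])) or 'nothing'}")
    print(f"  disease-risk change per serving: {risk:+.1f}%  (negative = protective)")
    print(f"  cost per serving: {per_serving:.2f} int$ (2020)")
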
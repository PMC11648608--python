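"""Benchmark-relative environmental scores with planetary-boundary weights.

Expresses each meat alternative's footprint per serving as a percentage of
beef (the high-impact benchmark, 100% in every domain) and averages the
three domains with weights GHG 0.65, land 0.17, water 0.18. Lower weighted
scores mean smaller environmental impact relative to the benchmark.
"""

from dietswap import GeneratorSpec, generate_bundle
from dietswap.environment import relative_impact

bundle = generate_bundle(GeneratorSpec(seed=0))
beef = bundle.foods["beef"]
weights = bundle.config.weights.env_weights

print(f"relative impact vs {beef.name} (per serving), weighted "
      f"{weights['ghg']:.2f}/{weights['land']:.2f}/{weights['water']:.2f}:")
rows = []
for food in bundle.foods.values():
    if food.category not in ("meat", "processed_alternative", "unprocessed_alternative"):
        continue
    ri = relative_impact(food, beef, basis="serving", env_weights=weights)
    rows.append((ri.weighted_pct, food.name, ri.rounded()))
for weighted, name, r in sorted(rows):
    print(f"  {name:>15}: {r['weighted']:>3d}%  "
          f"(GHG {r['ghg']}%, land {r['land']}%, water {r['water']}%)")
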
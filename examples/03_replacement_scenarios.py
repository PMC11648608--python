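"""Diet replacement: swap all meat calories for one alternative food.

Builds the calorie-conserving replacement diet (all meat intake removed,
the same calories added as the alternative) and prints the resulting change
in each assessment domain versus the baseline diet: nutritional imbalance
in percentage points, the others in percent of the baseline value.
Negative values are improvements.
"""

from dietswap import GeneratorSpec, generate_bundle
from dietswap.core_tables import ScenarioSpec
from dietswap.replacement import run_scenario, with_scenarios

bundle = generate_bundle(GeneratorSpec(seed=0))

for alt in ("soybeans", "veggie_burger", "poultry"):
    scenario = ScenarioSpec(
        id=f"meat_to_{alt}",
        region="HIC",
        replace="meat",
        alternatives={"meat": alt},
        basis="calorie",
    )
    changes = run_scenario(scenario, with_scenarios(bundle, [scenario]))
    print(f"\nreplace all meat with {alt} (calorie basis):")
    for c in changes:
        unit = "pp" if c.domain == "nutrition_pp" else "%"
        print(f"  {c.domain:>14}: {c.value:+7.2f} {unit}")
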
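"""Replacement diets and the cross-domain scenario orchestration.

A replacement scenario removes every food of a category (all meat, all
dairy, or both) from the baseline diet and substitutes a single alternative
food, either matching the removed calories (calorie basis: total dietary
energy is conserved) or the removed servings (serving basis: servings are
conserved, energy generally is not). Removed intake is pooled across the
category before conversion — the scenario replaces "all meat", not food by
food.

``run_scenario`` evaluates one scenario across all four domains and emits
tidy :class:`~dietswap.core_tables.DomainChange` records: nutrition in
percentage points of the imbalance indicator, mortality/GHG/land/water/cost
in percent of the baseline diet's value.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace
from typing import Mapping

import pandas as pd

from . import cost as cost_mod
from . import environment as env_mod
from . import health_cra, nutrition
from .core_tables import (
    ENDPOINTS,
    Bundle,
    DietaryIntake,
    DomainChange,
    FoodProduct,
    ScenarioSpec,
    TableError,
    with_sodium_addon,
)


def build_replacement_diet(
    baseline: DietaryIntake,
    scenario: ScenarioSpec,
    foods: Mapping[str, FoodProduct],
) -> DietaryIntake:
    """Construct the scenario diet: replaced category zeroed, alternative added."""
    categories = ("meat", "dairy") if scenario.replace == "both" else (scenario.replace,)
    intakes = dict(baseline.intakes)
    for category in categories:
        alt_id = scenario.alternatives[category]
        alt = foods.get(alt_id)
        if alt is None:
            raise TableError(f"scenario {scenario.id!r}: unknown alternative {alt_id!r}")
        replaced = {
            fid: g
            for fid, g in intakes.items()
            if foods[fid].category == category and g > 0
        }
        if not replaced:
            raise TableError(
                f"scenario {scenario.id!r}: no positive {category} intake to replace"
            )
        # Consolidating a category into one of its own members (an animal
        # comparator scenario) is allowed; replacing a food with itself alone
        # is a no-op and rejected.
        if set(replaced) == {alt_id}:
            raise TableError(
                f"scenario {scenario.id!r}: alternative {alt_id!r} is the only "
                f"replaced food; identity replacement is not a scenario"
            )
        if scenario.basis == "calorie":
            removed_kcal = sum(
                g / 100.0 * foods[fid].profile.energy_kcal_per_100g
                for fid, g in replaced.items()
            )
            if alt.kcal_per_g <= 0:
                raise TableError(
                    f"scenario {scenario.id!r}: alternative {alt_id!r} has zero energy "
                    "density, cannot replace on a calorie basis"
                )
            add_grams = removed_kcal / alt.kcal_per_g
        else:  # serving basis
            servings = sum(g / foods[fid].serving_g for fid, g in replaced.items())
            add_grams = servings * alt.serving_g
        for fid in replaced:
            intakes[fid] = 0.0
        intakes[alt_id] = intakes.get(alt_id, 0.0) + add_grams
    diet = DietaryIntake(
        region=baseline.region, intakes=intakes, waste_adjusted=baseline.waste_adjusted
    )
    if scenario.basis == "calorie":
        base_kcal = baseline.total_energy_kcal(foods)
        scen_kcal = diet.total_energy_kcal(foods)
        if abs(scen_kcal - base_kcal) > 1e-6 * max(base_kcal, 1.0):
            raise TableError(
                f"scenario {scenario.id!r}: energy not conserved "
                f"({base_kcal:.6f} vs {scen_kcal:.6f} kcal)"
            )
    return diet


def run_scenario(scenario: ScenarioSpec, bundle: Bundle) -> list[DomainChange]:
    """Evaluate one scenario across nutrition, health, environment, and cost."""
    foods = bundle.foods
    if scenario.sodium_addon_mg_per_100g > 0:
        foods = with_sodium_addon(
            foods, scenario.alternatives.values(), scenario.sodium_addon_mg_per_100g
        )
    baseline = bundle.diets[scenario.region]
    scenario_diet = build_replacement_diet(baseline, scenario, foods)

    try:
        return _domain_changes(scenario, bundle, foods, baseline, scenario_diet)
    except TableError as err:
        raise TableError(f"scenario {scenario.id!r}: {err}") from err


def _domain_changes(
    scenario: ScenarioSpec,
    bundle: Bundle,
    foods: Mapping[str, FoodProduct],
    baseline: DietaryIntake,
    scenario_diet: DietaryIntake,
) -> list[DomainChange]:
    iron_model = bundle.config.iron_model
    imb_base = nutrition.imbalance_for_diet(
        baseline, foods, bundle.recommendations, bundle.zinc_phytate_table,
        iron_model, scenario="baseline",
    )
    imb_scen = nutrition.imbalance_for_diet(
        scenario_diet, foods, bundle.recommendations, bundle.zinc_phytate_table,
        iron_model, scenario=scenario.id,
    )
    nutrition_pp = imb_scen.indicator - imb_base.indicator

    exp_base = health_cra.exposure_from_diet(baseline, foods)
    exp_scen = health_cra.exposure_from_diet(scenario_diet, foods)
    mortality_pct = health_cra.mortality_change_pct(
        exp_base, exp_scen, bundle.rr_table, bundle.mortality[scenario.region]
    )

    env_base = env_mod.diet_environmental_totals(
        baseline, foods, include_processing=scenario.processing_emissions
    )
    env_scen = env_mod.diet_environmental_totals(
        scenario_diet, foods, include_processing=scenario.processing_emissions
    )
    env_changes = env_mod.replacement_environment_change(
        env_base, env_scen, bundle.config.weights.env_weights
    )

    prices = cost_mod.harmonize_prices(
        foods, bundle.cpi, bundle.ppp, bundle.config.base_year
    )
    cost_base = cost_mod.diet_cost(baseline, prices)
    cost_scen = cost_mod.diet_cost(scenario_diet, prices)
    cost_pct = cost_mod.replacement_cost_change(cost_base, cost_scen)

    sid = scenario.id
    return [
        DomainChange(sid, "nutrition_pp", nutrition_pp),
        DomainChange(sid, "mortality_pct", mortality_pct),
        DomainChange(sid, "ghg_pct", env_changes["ghg"]),
        DomainChange(sid, "land_pct", env_changes["land"]),
        DomainChange(sid, "water_pct", env_changes["water"]),
        DomainChange(sid, "cost_pct", cost_pct),
    ]


def run_all(bundle: Bundle) -> pd.DataFrame:
    """Run every scenario in the bundle's config; tidy (scenario, domain, value).

    The result also carries scenario metadata columns (region, replaced
    category, alternative ids, basis) so downstream synthesis can group by
    replaced category and basis.
    """
    rows = []
    for scenario in bundle.config.scenarios:
        for change in run_scenario(scenario, bundle):
            rows.append(
                {
                    "scenario": change.scenario,
                    "domain": change.domain,
                    "value": change.value,
                    "region": scenario.region,
                    "replace": scenario.replace,
                    "alternative": "+".join(
                        scenario.alternatives[c] for c in sorted(scenario.alternatives)
                    ),
                    "basis": scenario.basis,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["scenario", "domain", "value", "region", "replace", "alternative", "basis"],
    )


def scenario_matrix(
    bundle: Bundle,
    replace: str,
    region: str = "HIC",
    basis: str = "calorie",
    candidate_categories: tuple[str, ...] = (
        "processed_alternative",
        "unprocessed_alternative",
    ),
    include_comparators: bool = True,
) -> list[ScenarioSpec]:
    """One scenario per candidate food for a replaced category.

    With ``include_comparators`` the animal products of the replaced
    category itself are also enrolled (consolidation scenarios: all meat
    becomes only beef, only poultry, ...), so the synthesis pool contains
    the animal comparators alongside the alternatives. A comparator that is
    the sole food of its category would be an identity replacement and is
    left out.
    """
    baseline = bundle.diets[region]
    replaced_foods = {
        fid
        for fid, g in baseline.intakes.items()
        if bundle.foods[fid].category == replace and g > 0
    }
    candidates = [
        f
        for f in sorted(bundle.foods.values(), key=lambda f: f.id)
        if f.category in candidate_categories
        or (include_comparators and f.category == replace)
    ]
    return [
        ScenarioSpec(
            id=f"{replace}_to_{food.id}_{basis}",
            region=region,
            replace=replace,
            alternatives={replace: food.id},
            basis=basis,
        )
        for food in candidates
        if replaced_foods != {food.id}
    ]


def with_scenarios(bundle: Bundle, scenarios: list[ScenarioSpec]) -> Bundle:
    """Bundle copy whose config carries the given scenario list."""
    config = dc_replace(bundle.config, scenarios=tuple(scenarios))
    new = Bundle(
        foods=bundle.foods,
        diets=bundle.diets,
        recommendations=bundle.recommendations,
        rr_table=bundle.rr_table,
        mortality=bundle.mortality,
        zinc_phytate_table=bundle.zinc_phytate_table,
        cpi=bundle.cpi,
        ppp=bundle.ppp,
        config=config,
    )
    new.validate()
    return new
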
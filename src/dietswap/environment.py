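"""Environmental footprints, benchmark-relative impacts, and diet totals.

Footprints (GHG in kg CO2eq, land in m2, blue/freshwater in L, all per kg
food in input tables) are compared on a serving, calorie, or weight basis.
Each food's per-domain impact is expressed as a percentage of a high-impact
benchmark (beef for meats, the whole/low-fat milk average for dairy) and the
three domains are averaged with planetary-boundary weights — GHG 0.65, land
0.17, water 0.18 — reflecting how much dietary change must contribute to
staying within environmental limits in each domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core_tables import (
    DietaryIntake,
    EnvironmentalFootprint,
    FoodProduct,
    SynthesisWeights,
    TableError,
)

ENV_DOMAINS = ("ghg", "land", "water")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (presentation only)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def footprint_per_basis(
    food: FoodProduct, basis: str = "serving", include_processing: bool = False
) -> dict[str, float]:
    """Per-domain footprint per serving, per kcal, or per kg."""
    per_kg = {
        d: food.footprint.per_kg(d, include_processing=include_processing)
        for d in ENV_DOMAINS
    }
    if basis == "weight":
        return per_kg
    if basis == "serving":
        scale = food.serving_g / 1000.0
        return {d: v * scale for d, v in per_kg.items()}
    if basis == "calorie":
        kcal_per_kg = food.profile.energy_kcal_per_100g * 10.0
        if kcal_per_kg <= 0:
            raise TableError(f"{food.id}: zero energy density, cannot use calorie basis")
        return {d: v / kcal_per_kg for d, v in per_kg.items()}
    raise TableError(f"unknown basis {basis!r}")


def weighted_domain_score(
    per_domain_pct: Mapping[str, float], env_weights: Mapping[str, float]
) -> float:
    """Weighted average of per-domain percentages (weights must sum to 1)."""
    total_w = sum(env_weights[d] for d in ENV_DOMAINS)
    if abs(total_w - 1.0) > 1e-9:
        raise TableError(f"environment weights sum to {total_w}, expected 1")
    return sum(env_weights[d] * per_domain_pct[d] for d in ENV_DOMAINS)


@dataclass(frozen=True)
class RelativeImpact:
    food_id: str
    benchmark_id: str
    basis: str
    per_domain_pct: Mapping[str, float]
    weighted_pct: float

    def rounded(self) -> dict[str, int]:
        out = {d: round_half_away(v) for d, v in self.per_domain_pct.items()}
        out["weighted"] = round_half_away(self.weighted_pct)
        return out


def relative_impact(
    food: FoodProduct,
    benchmark: FoodProduct,
    basis: str = "serving",
    env_weights: Mapping[str, float] | None = None,
    include_processing: bool = False,
) -> RelativeImpact:
    """Food's footprint as a percentage of a benchmark food, per domain and weighted."""
    if env_weights is None:
        env_weights = SynthesisWeights().env_weights
    f = footprint_per_basis(food, basis, include_processing=include_processing)
    b = footprint_per_basis(benchmark, basis)
    pct = {}
    for d in ENV_DOMAINS:
        if b[d] <= 0:
            raise TableError(f"benchmark {benchmark.id}: zero {d} footprint")
        pct[d] = 100.0 * f[d] / b[d]
    return RelativeImpact(
        food_id=food.id,
        benchmark_id=benchmark.id,
        basis=basis,
        per_domain_pct=pct,
        weighted_pct=weighted_domain_score(pct, env_weights),
    )


def mean_footprint(foods: Iterable[FoodProduct]) -> EnvironmentalFootprint:
    """Average footprint across foods (used for the whole/low-fat milk benchmark)."""
    foods = list(foods)
    if not foods:
        raise TableError("cannot average an empty food set")
    n = len(foods)
    return EnvironmentalFootprint(
        ghg=sum(f.footprint.ghg for f in foods) / n,
        land=sum(f.footprint.land for f in foods) / n,
        water=sum(f.footprint.water for f in foods) / n,
        processing_ghg=sum(f.footprint.processing_ghg for f in foods) / n,
    )


def diet_environmental_totals(
    diet: DietaryIntake,
    foods: Mapping[str, FoodProduct],
    include_processing: bool = False,
) -> dict[str, float]:
    """Absolute per-domain totals of a diet (kg CO2eq, m2, L per person-day)."""
    missing = set(diet.intakes) - set(foods)
    if missing:
        raise TableError(f"missing footprints for: {sorted(missing)}")
    totals = {d: 0.0 for d in ENV_DOMAINS}
    for fid, grams in diet.intakes.items():
        fp = foods[fid].footprint
        for d in ENV_DOMAINS:
            totals[d] += grams / 1000.0 * fp.per_kg(d, include_processing=include_processing)
    return totals


def replacement_environment_change(
    baseline_totals: Mapping[str, float],
    scenario_totals: Mapping[str, float],
    env_weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-domain % changes vs. baseline plus the weighted % change."""
    if env_weights is None:
        env_weights = SynthesisWeights().env_weights
    changes = {}
    for d in ENV_DOMAINS:
        if baseline_totals[d] <= 0:
            raise TableError(f"zero baseline total for domain {d}")
        changes[d] = 100.0 * (scenario_totals[d] - baseline_totals[d]) / baseline_totals[d]
    changes["weighted"] = weighted_domain_score(changes, env_weights)
    return changes


def relative_impact_table(
    foods: Mapping[str, FoodProduct],
    benchmark: FoodProduct,
    basis: str = "serving",
    env_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tidy relative impacts of many foods against one benchmark."""
    rows = []
    for food in foods.values():
        ri = relative_impact(food, benchmark, basis=basis, env_weights=env_weights)
        rows.append(
            {
                "food_id": food.id,
                "benchmark_id": benchmark.id,
                "basis": basis,
                **{f"{d}_pct": ri.per_domain_pct[d] for d in ENV_DOMAINS},
                "weighted_pct": ri.weighted_pct,
            }
        )
    return pd.DataFrame(rows)
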
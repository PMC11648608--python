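"""Nutrient intakes, density classification, and the imbalance indicator.

The diet-level **nutritional imbalance indicator** is the mean magnitude of
recommendation violations across all nutrients that carry a recommendation:
shortfalls below minimum recommendations and excesses above maximum limits
both enter as positive percentages of the recommended value; nutrients
within their recommendation contribute zero. Calcium carries no
recommendation and is excluded by construction.

Zinc and iron requirements are diet-dependent and are resolved per diet
before the indicator is computed: the zinc requirement rises with dietary
phytate (linear interpolation in a reference table), and the iron
requirement is the target amount of absorbed iron divided by a blended
absorption fraction that weighs heme and nonheme iron by their shares of
total dietary iron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_tables import (
    DietaryIntake,
    FoodProduct,
    IronModelParams,
    NutrientRecommendation,
    TableError,
)
from .nutrients import NUTRIENTS


def nutrient_intake(
    diet: DietaryIntake, foods: Mapping[str, FoodProduct]
) -> pd.Series:
    """Daily intake per nutrient: sum over foods of grams/100 x density."""
    missing = set(diet.intakes) - set(foods)
    if missing:
        raise TableError(f"missing composition data for: {sorted(missing)}")
    totals = np.zeros(len(NUTRIENTS))
    for fid, grams in diet.intakes.items():
        profile = foods[fid].profile
        totals += grams / 100.0 * np.array([profile[n] for n in NUTRIENTS])
    return pd.Series(totals, index=list(NUTRIENTS), name=diet.region)


def classify_source(density: float) -> str:
    """Classify a per-serving nutrient density: none, good (10-19%), high (>=20%)."""
    if density < 0 or not math.isfinite(density):
        raise ValueError(f"density must be finite and >= 0, got {density}")
    if density >= 0.20:
        return "high"
    if density >= 0.10:
        return "good"
    return "none"


def nutrient_density_table(
    foods: Mapping[str, FoodProduct], recommendations: Sequence[NutrientRecommendation]
) -> pd.DataFrame:
    """Per-serving nutrient content as a fraction of the daily recommendation.

    Only nutrients with recommendations appear; densities use the static
    recommended values (diet-dependent handlers do not apply to a single
    serving).
    """
    rows = []
    for food in foods.values():
        for rec in recommendations:
            amount = food.profile[rec.nutrient] * food.serving_g / 100.0
            density = amount / rec.daily_value
            rows.append(
                {
                    "food_id": food.id,
                    "nutrient": rec.nutrient,
                    "density": density,
                    "classification": classify_source(density),
                }
            )
    return pd.DataFrame(rows, columns=["food_id", "nutrient", "density", "classification"])


def zinc_requirement(phytate_intake_mg: float, reference_table: pd.DataFrame) -> float:
    """Phytate-adjusted zinc requirement by linear interpolation.

    ``reference_table`` holds monotone (phytate_mg, zinc_mg) pairs; the
    requirement is clamped at the table ends.
    """
    if len(reference_table) == 0:
        raise TableError("zinc-phytate reference table is empty")
    phytate = reference_table["phytate_mg"].to_numpy(dtype=float)
    zinc = reference_table["zinc_mg"].to_numpy(dtype=float)
    if np.any(np.diff(phytate) <= 0) or np.any(np.diff(zinc) < 0):
        raise TableError("zinc-phytate reference table must be monotone")
    return float(np.interp(phytate_intake_mg, phytate, zinc))


def nonheme_absorption(
    phytate_mg: float,
    calcium_mg: float,
    vitamin_c_mg: float,
    meat_g: float,
    model: IronModelParams,
) -> float:
    """Nonheme-iron absorption fraction, log-linear in dietary mediators."""
    log_a = (
        model.log_intercept
        + model.coef_phytate_per_mg * phytate_mg
        + model.coef_calcium_per_mg * calcium_mg
        + model.coef_vitamin_c_per_mg * vitamin_c_mg
        + model.coef_meat_per_g * meat_g
    )
    # clamp in log space so extreme mediator intakes cannot overflow exp
    log_a = min(log_a, math.log(model.max_absorption))
    return float(max(math.exp(log_a), 1e-9))


def iron_requirement(
    intakes: pd.Series,
    meat_intake_g: float,
    model: IronModelParams,
) -> float:
    """Absorption-adjusted iron requirement for a diet.

    The blended absorption fraction weighs heme and nonheme absorption by
    their shares of total dietary iron; the requirement is the target
    absorbed iron divided by that fraction. A diet with no iron at all falls
    back to the nonheme fraction (all marginal iron would be nonheme).
    """
    total_iron = float(intakes["iron_mg"])
    heme_iron = float(intakes["heme_iron_mg"])
    a_nonheme = nonheme_absorption(
        float(intakes["phytate_mg"]),
        float(intakes["calcium_mg"]),
        float(intakes["vitamin_c_mg"]),
        meat_intake_g,
        model,
    )
    if total_iron > 0:
        heme_share = min(heme_iron / total_iron, 1.0)
    else:
        heme_share = 0.0
    blended = heme_share * model.heme_absorption + (1 - heme_share) * a_nonheme
    if not 0 < blended <= 1:
        raise TableError(f"blended absorption fraction {blended} outside (0, 1]")
    return model.target_absorbed_mg / blended


def meat_intake_grams(diet: DietaryIntake, foods: Mapping[str, FoodProduct]) -> float:
    return sum(g for fid, g in diet.intakes.items() if foods[fid].category == "meat")


def resolve_recommendations(
    recommendations: Sequence[NutrientRecommendation],
    intakes: pd.Series,
    meat_intake_g: float,
    zinc_phytate_table: pd.DataFrame,
    iron_model: IronModelParams,
) -> list[NutrientRecommendation]:
    """Replace handler-flagged daily values with diet-adjusted requirements."""
    resolved = []
    for rec in recommendations:
        if rec.handler == "zinc_phytate":
            value = zinc_requirement(float(intakes["phytate_mg"]), zinc_phytate_table)
        elif rec.handler == "iron_absorption":
            value = iron_requirement(intakes, meat_intake_g, iron_model)
        else:
            value = rec.daily_value
        resolved.append(
            NutrientRecommendation(
                nutrient=rec.nutrient,
                direction=rec.direction,
                daily_value=value,
                source=rec.source,
                handler="none",
            )
        )
    return resolved


@dataclass(frozen=True)
class ImbalanceResult:
    """Imbalance indicator (%) with per-nutrient signed deviations (%)."""

    scenario: str
    indicator: float
    deviations: Mapping[str, float]  # signed % difference from recommendation
    violations: Mapping[str, float]  # violation magnitude in % (0 if compliant)

    @property
    def n_recommended(self) -> int:
        return len(self.deviations)


def imbalance_indicator(
    intakes: pd.Series,
    recommendations: Sequence[NutrientRecommendation],
    scenario: str = "baseline",
) -> ImbalanceResult:
    """Mean violation magnitude over recommended nutrients, in percent.

    Only violations count: intake below a minimum recommendation or above a
    maximum limit contributes its percentage distance from the recommended
    value; compliant nutrients contribute zero.
    """
    if not recommendations:
        raise TableError("recommendation set is empty")
    deviations: dict[str, float] = {}
    violations: dict[str, float] = {}
    for rec in recommendations:
        if rec.handler != "none":
            raise TableError(
                f"recommendation for {rec.nutrient} has unresolved handler "
                f"{rec.handler!r}; call resolve_recommendations first"
            )
        if rec.daily_value <= 0:
            raise TableError(f"zero daily value for {rec.nutrient}")
        intake = float(intakes[rec.nutrient])
        dev = (intake - rec.daily_value) / rec.daily_value * 100.0
        deviations[rec.nutrient] = dev
        if rec.direction == "minimum":
            violations[rec.nutrient] = max(-dev, 0.0)
        else:
            violations[rec.nutrient] = max(dev, 0.0)
    indicator = sum(violations.values()) / len(recommendations)
    return ImbalanceResult(
        scenario=scenario, indicator=indicator, deviations=deviations, violations=violations
    )


def imbalance_for_diet(
    diet: DietaryIntake,
    foods: Mapping[str, FoodProduct],
    recommendations: Sequence[NutrientRecommendation],
    zinc_phytate_table: pd.DataFrame,
    iron_model: IronModelParams,
    scenario: str = "baseline",
) -> ImbalanceResult:
    """Convenience: intakes, handler resolution, and the indicator in one call."""
    intakes = nutrient_intake(diet, foods)
    resolved = resolve_recommendations(
        recommendations,
        intakes,
        meat_intake_grams(diet, foods),
        zinc_phytate_table,
        iron_model,
    )
    return imbalance_indicator(intakes, resolved, scenario=scenario)


def imbalance_change_decomposition(
    baseline: ImbalanceResult, scenario: ImbalanceResult
) -> pd.DataFrame:
    """Per-nutrient contributions to the indicator change, in pp and % shares.

    The contribution of a nutrient is the change in its violation term
    divided by the number of recommended nutrients; contributions sum to the
    total indicator change, and shares sum to 100% of it (sign-aware: a
    contribution opposing the total change has a negative share).
    """
    if set(baseline.violations) != set(scenario.violations):
        raise TableError("decomposition requires identical recommendation sets")
    n = baseline.n_recommended
    total = scenario.indicator - baseline.indicator
    rows = []
    for nutrient in baseline.violations:
        contrib = (scenario.violations[nutrient] - baseline.violations[nutrient]) / n
        share = contrib / total * 100.0 if total != 0 else 0.0
        rows.append({"nutrient": nutrient, "contribution_pp": contrib, "share_pct": share})
    return pd.DataFrame(rows, columns=["nutrient", "contribution_pp", "share_pct"])
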
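"""Price harmonization (CPI deflation, PPP conversion) and diet costs.

Prices observed in different years and currencies are made comparable by
(1) deflating to a common base year (2020) with a consumer-price-index
series for food and (2) converting national currency to international
dollars with purchasing-power-parity (PPP) rates. The two steps commute.
Diet cost is then linear in quantities at harmonized per-kg prices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core_tables import DietaryIntake, FoodProduct, PriceRecord, TableError


def _series_value(series: pd.DataFrame, entity: str, year: int, what: str) -> float:
    rows = series[(series["entity"] == entity) & (series["year"] == year)]
    if rows.empty:
        raise TableError(f"no {what} value for entity {entity!r}, year {year}")
    return float(rows["value"].iloc[0])


def deflate_to_base_year(
    price: float,
    year: int,
    cpi_series: pd.DataFrame,
    entity: str,
    base_year: int = 2020,
) -> float:
    """Rescale a price from its observation year to the base year via CPI."""
    cpi_year = _series_value(cpi_series, entity, year, "CPI")
    cpi_base = _series_value(cpi_series, entity, base_year, "CPI")
    if cpi_year <= 0:
        raise TableError(f"nonpositive CPI for {entity!r}, year {year}")
    return price * cpi_base / cpi_year


def to_international_dollars(price_local: float, ppp_rate: float) -> float:
    """Convert a local-currency price to international dollars."""
    if ppp_rate <= 0:
        raise TableError(f"PPP rate must be > 0, got {ppp_rate}")
    return price_local / ppp_rate


@dataclass(frozen=True)
class HarmonizedPrice:
    """Price in international dollars per kg at the base year, with provenance."""

    food_id: str
    intl_dollars_per_kg: float
    source_year: int
    source_currency: str
    cpi_factor: float
    ppp_rate: float
    base_year: int = 2020

    def __post_init__(self) -> None:
        if self.intl_dollars_per_kg < 0:
            raise TableError(f"{self.food_id}: harmonized price must be >= 0")


def harmonize_price(
    food_id: str,
    record: PriceRecord,
    cpi_series: pd.DataFrame,
    ppp_series: pd.DataFrame,
    base_year: int = 2020,
) -> HarmonizedPrice:
    """CPI-deflate then PPP-convert one price observation (order is immaterial)."""
    deflated = deflate_to_base_year(
        record.value, record.year, cpi_series, record.currency, base_year
    )
    ppp_rate = _series_value(ppp_series, record.currency, base_year, "PPP")
    return HarmonizedPrice(
        food_id=food_id,
        intl_dollars_per_kg=to_international_dollars(deflated, ppp_rate),
        source_year=record.year,
        source_currency=record.currency,
        cpi_factor=deflated / record.value if record.value else 1.0,
        ppp_rate=ppp_rate,
        base_year=base_year,
    )


def harmonize_prices(
    foods: Mapping[str, FoodProduct],
    cpi_series: pd.DataFrame,
    ppp_series: pd.DataFrame,
    base_year: int = 2020,
) -> dict[str, HarmonizedPrice]:
    return {
        fid: harmonize_price(fid, f.price, cpi_series, ppp_series, base_year)
        for fid, f in foods.items()
    }


def cost_per_basis(
    food: FoodProduct, harmonized: HarmonizedPrice, basis: str = "serving"
) -> float:
    """Cost per serving, per 1000 kcal, or per kg, in international dollars."""
    per_kg = harmonized.intl_dollars_per_kg
    if basis == "weight":
        return per_kg
    if basis == "serving":
        return per_kg * food.serving_g / 1000.0
    if basis == "calorie":
        kcal_per_kg = food.profile.energy_kcal_per_100g * 10.0
        if kcal_per_kg <= 0:
            raise TableError(f"{food.id}: zero energy density, cannot use calorie basis")
        return per_kg / kcal_per_kg * 1000.0
    raise TableError(f"unknown basis {basis!r}")


def diet_cost(
    diet: DietaryIntake, harmonized_prices: Mapping[str, HarmonizedPrice]
) -> float:
    """Diet cost in international dollars per person per day."""
    missing = set(diet.intakes) - set(harmonized_prices)
    if missing:
        raise TableError(f"missing prices for: {sorted(missing)}")
    return sum(
        grams / 1000.0 * harmonized_prices[fid].intl_dollars_per_kg
        for fid, grams in diet.intakes.items()
    )


def replacement_cost_change(baseline_cost: float, scenario_cost: float) -> float:
    """Diet-cost change in percent of the baseline cost."""
    if baseline_cost <= 0:
        raise TableError("baseline diet cost must be > 0")
    return 100.0 * (scenario_cost - baseline_cost) / baseline_cost
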
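from __future__ import annotations

import pytest

from dietswap.core_tables import (
    EnvironmentalFootprint,
    FoodProduct,
    NutrientProfile,
    PriceRecord,
)
from dietswap.synthetic_data import GeneratorSpec, default_scenarios, generate_bundle


def make_food(
    fid: str,
    category: str = "other_diet_component",
    serving_g: float = 100.0,
    nutrients: dict | None = None,
    ghg_per_kg: float = 1.0,
    land_per_kg: float = 1.0,
    water_per_kg: float = 1.0,
    processing_ghg_per_kg: float = 0.0,
    price: float = 1.0,
    price_year: int = 2020,
) -> FoodProduct:
    """Minimal valid food for targeted unit tests."""
    amounts = {"energy_kcal": 100.0}
    amounts.update(nutrients or {})
    return FoodProduct(
        id=fid,
        name=fid,
        category=category,
        serving_g=serving_g,
        profile=NutrientProfile(amounts),
        footprint=EnvironmentalFootprint.from_per_kg(
            ghg_per_kg, land_per_kg, water_per_kg, processing_ghg_per_kg
        ),
        price=PriceRecord(value=price, currency="USD", year=price_year),
    )


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(GeneratorSpec(seed=7))


@pytest.fixture(scope="session")
def scenario_bundle(bundle):
    return default_scenarios(bundle, basis="calorie")
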
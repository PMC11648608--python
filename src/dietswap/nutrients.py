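"""Canonical nutrient registry.

Every composition table in the package is keyed by the identifiers below:
29 nutrients plus phytate, which travels with phosphorus in composition
tables (it is an absorption mediator, not a nutrient with its own
recommendation). Amounts are always per 100 g edible food, in the unit
embedded in the identifier (``_g``, ``_mg``, ``_ug``; energy in kcal).
"""

from __future__ import annotations

PROXIMATES = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "carbohydrate_g",
    "sugar_g",
    "fiber_g",
)

LIPIDS = (
    "saturated_fat_g",
    "mufa_g",
    "pufa_g",
    "trans_fat_g",
    "cholesterol_mg",
)

MINERALS = (
    "calcium_mg",
    "iron_mg",
    "heme_iron_mg",
    "magnesium_mg",
    "phosphorus_mg",
    "phytate_mg",
    "potassium_mg",
    "sodium_mg",
    "zinc_mg",
    "copper_mg",
)

VITAMINS = (
    "vitamin_c_mg",
    "thiamine_mg",
    "riboflavin_mg",
    "niacin_mg",
    "pantothenate_mg",
    "vitamin_b6_mg",
    "folate_ug",
    "vitamin_b12_ug",
    "vitamin_a_ug_rae",
)

#: All composition-table columns, in canonical order.
NUTRIENTS: tuple[str, ...] = PROXIMATES + LIPIDS + MINERALS + VITAMINS

#: Fat subcomponents that must not exceed total fat.
FAT_PARTS = ("saturated_fat_g", "mufa_g", "pufa_g", "trans_fat_g")

#: Tolerance for the fat-component mass balance (rounding slack in
#: composition tables).
FAT_BALANCE_TOL = 0.05


def validate_nutrient_id(nutrient: str) -> str:
    if nutrient not in NUTRIENTS:
        raise KeyError(f"unknown nutrient id: {nutrient!r}")
    return nutrient
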
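"""Seeded generator of complete, internally consistent input bundles.

The generator emulates the statistical structure the analysis assumes,
without attempting to match any real composition database: animal-source
foods are high in saturated fat, cholesterol, heme iron, and sodium;
legumes, nuts, and whole grains are high in fiber, potassium, and PUFAs;
processed alternatives are fortified (vitamin B12, riboflavin, vitamin A)
and priced above their unprocessed ingredients; footprints follow the
hierarchy beef >> pork/poultry >> plant foods. Every knob of that structure
is a field of :class:`GeneratorSpec`.

A single integer seed drives one PRNG stream with deterministic per-table
substreams, so identical specs produce byte-identical bundles.

``generate_known_answer_diet`` is the testing scaffold for the nutrition
module: it constructs a one-food diet whose per-nutrient deviations from
the recommendations equal requested targets exactly, so the imbalance
indicator can be checked against hand-computed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._defaults import (
    default_recommendations,
    default_rr_table,
    default_zinc_phytate_table,
    static_recommendations,
)
from .core_tables import (
    AnalysisConfig,
    Bundle,
    DietaryIntake,
    EnvironmentalFootprint,
    FoodProduct,
    MortalityData,
    NutrientProfile,
    NutrientRecommendation,
    PriceRecord,
    TableError,
)
from .nutrients import NUTRIENTS


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything the bundle generator needs, with study-like defaults."""

    seed: int = 0
    region: str = "HIC"
    #: foods drawn per category (archetypes cycle if n exceeds them)
    n_meat: int = 4
    n_dairy: int = 2
    n_processed: int = 6
    n_unprocessed: int = 6
    n_other: int = 3
    #: multiplicative elevation of animal-food saturated fat, heme iron,
    #: cholesterol relative to the archetype baselines
    animal_satfat_factor: float = 1.0
    animal_heme_factor: float = 1.0
    animal_cholesterol_factor: float = 1.0
    #: multiplicative elevation of plant-food fiber, potassium, PUFA
    plant_fiber_factor: float = 1.0
    plant_potassium_factor: float = 1.0
    plant_pufa_factor: float = 1.0
    #: additive fortification of processed alternatives (per 100 g)
    fortification: bool = True
    fortify_b12_ug: float = 1.2
    fortify_riboflavin_mg: float = 0.25
    fortify_vitamin_a_ug: float = 120.0
    #: per-kg GHG footprint scale of each tier; land and water scale along
    footprint_beef: float = 50.0
    footprint_other_meat: float = 8.0
    footprint_dairy: float = 3.0
    footprint_plant: float = 1.5
    #: price of processed alternatives relative to unprocessed plant foods
    price_markup_processed: float = 1.8
    #: baseline-diet composition
    total_kcal: float = 2500.0
    meat_kcal_share: float = 0.15
    dairy_kcal_share: float = 0.10
    #: relative nutrient jitter between foods of one archetype
    jitter: float = 0.06

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise TableError("seed must be >= 0")
        for name in ("n_meat", "n_dairy", "n_processed", "n_unprocessed", "n_other"):
            if getattr(self, name) < 1:
                raise TableError(f"{name} must be >= 1 (degenerate spec)")
        if not 0 <= self.meat_kcal_share + self.dairy_kcal_share < 1:
            raise TableError("meat and dairy calorie shares must sum to < 1")
        if not 0 <= self.jitter < 0.5:
            raise TableError("jitter must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# Archetypes: nutrient baselines per 100 g. Fat subcomponents are specified
# as fractions of total fat and heme iron as a fraction of iron so that the
# profile invariants hold for any jitter.
# ---------------------------------------------------------------------------

_BASE = {n: 0.0 for n in NUTRIENTS}

_ARCHETYPES: dict[str, list[tuple[str, dict]]] = {
    "meat": [
        ("beef", dict(energy_kcal=250, protein_g=26, fat_g=17, frac_sat=0.42,
                      frac_mufa=0.44, frac_pufa=0.04, frac_trans=0.05,
                      cholesterol_mg=90, iron_mg=2.6, heme_frac=0.65,
                      magnesium_mg=21, phosphorus_mg=200, potassium_mg=320,
                      sodium_mg=70, zinc_mg=6.0, copper_mg=0.08,
                      thiamine_mg=0.06, riboflavin_mg=0.18, niacin_mg=5.0,
                      pantothenate_mg=0.6, vitamin_b6_mg=0.35, folate_ug=8,
                      vitamin_b12_ug=2.5, vitamin_a_ug_rae=5, calcium_mg=15)),
        ("pork", dict(energy_kcal=290, protein_g=25, fat_g=21, frac_sat=0.37,
                      frac_mufa=0.45, frac_pufa=0.10, frac_trans=0.01,
                      cholesterol_mg=80, iron_mg=1.0, heme_frac=0.4,
                      magnesium_mg=19, phosphorus_mg=190, potassium_mg=300,
                      sodium_mg=620, zinc_mg=2.4, copper_mg=0.07,
                      thiamine_mg=0.6, riboflavin_mg=0.25, niacin_mg=4.5,
                      pantothenate_mg=0.7, vitamin_b6_mg=0.4, folate_ug=5,
                      vitamin_b12_ug=0.8, vitamin_a_ug_rae=2, calcium_mg=14)),
        ("poultry", dict(energy_kcal=190, protein_g=27, fat_g=8, frac_sat=0.28,
                         frac_mufa=0.40, frac_pufa=0.22, frac_trans=0.01,
                         cholesterol_mg=85, iron_mg=1.0, heme_frac=0.4,
                         magnesium_mg=25, phosphorus_mg=200, potassium_mg=240,
                         sodium_mg=85, zinc_mg=1.8, copper_mg=0.06,
                         thiamine_mg=0.07, riboflavin_mg=0.17, niacin_mg=9.0,
                         pantothenate_mg=1.0, vitamin_b6_mg=0.5, folate_ug=6,
                         vitamin_b12_ug=0.3, vitamin_a_ug_rae=16, calcium_mg=14)),
        ("beef_burger", dict(energy_kcal=260, protein_g=24, fat_g=18, frac_sat=0.41,
                             frac_mufa=0.44, frac_pufa=0.04, frac_trans=0.05,
                             cholesterol_mg=85, iron_mg=2.4, heme_frac=0.62,
                             magnesium_mg=20, phosphorus_mg=185, potassium_mg=300,
                             sodium_mg=350, zinc_mg=5.5, copper_mg=0.08,
                             thiamine_mg=0.06, riboflavin_mg=0.17, niacin_mg=4.8,
                             pantothenate_mg=0.6, vitamin_b6_mg=0.33, folate_ug=8,
                             vitamin_b12_ug=2.3, vitamin_a_ug_rae=5, calcium_mg=18)),
    ],
    "dairy": [
        ("whole_milk", dict(energy_kcal=61, protein_g=3.2, fat_g=3.3, frac_sat=0.57,
                            frac_mufa=0.25, frac_pufa=0.06, frac_trans=0.03,
                            cholesterol_mg=12, iron_mg=0.03, heme_frac=0.0,
                            magnesium_mg=10, phosphorus_mg=84, potassium_mg=132,
                            sodium_mg=43, zinc_mg=0.37, copper_mg=0.025,
                            carbohydrate_g=4.8, sugar_g=5.1,
                            thiamine_mg=0.046, riboflavin_mg=0.17, niacin_mg=0.09,
                            pantothenate_mg=0.37, vitamin_b6_mg=0.04, folate_ug=5,
                            vitamin_b12_ug=0.45, vitamin_a_ug_rae=46, calcium_mg=113)),
        ("lowfat_milk", dict(energy_kcal=47, protein_g=3.3, fat_g=1.9, frac_sat=0.60,
                             frac_mufa=0.25, frac_pufa=0.04, frac_trans=0.03,
                             cholesterol_mg=8, iron_mg=0.02, heme_frac=0.0,
                             magnesium_mg=11, phosphorus_mg=92, potassium_mg=140,
                             sodium_mg=44, zinc_mg=0.42, copper_mg=0.013,
                             carbohydrate_g=4.9, sugar_g=5.0,
                             thiamine_mg=0.039, riboflavin_mg=0.19, niacin_mg=0.09,
                             pantothenate_mg=0.36, vitamin_b6_mg=0.04, folate_ug=5,
                             vitamin_b12_ug=0.47, vitamin_a_ug_rae=59, calcium_mg=120)),
    ],
    "processed_alternative": [
        ("veggie_burger", dict(energy_kcal=220, protein_g=21, fat_g=10, frac_sat=0.12,
                               frac_mufa=0.30, frac_pufa=0.50, frac_trans=0.0,
                               carbohydrate_g=9, sugar_g=1, fiber_g=4.5,
                               iron_mg=2.8, heme_frac=0.0, phytate_mg=180,
                               magnesium_mg=45, phosphorus_mg=210, potassium_mg=400,
                               sodium_mg=450, zinc_mg=1.5, copper_mg=0.25,
                               vitamin_c_mg=0.5, thiamine_mg=0.2, riboflavin_mg=0.12,
                               niacin_mg=4.0, pantothenate_mg=0.5, vitamin_b6_mg=0.3,
                               folate_ug=60, calcium_mg=80)),
        ("soy_milk", dict(energy_kcal=45, protein_g=3.3, fat_g=1.9, frac_sat=0.14,
                          frac_mufa=0.24, frac_pufa=0.55, frac_trans=0.0,
                          carbohydrate_g=3.2, sugar_g=2.4, fiber_g=0.5,
                          iron_mg=0.5, heme_frac=0.0, phytate_mg=60,
                          magnesium_mg=17, phosphorus_mg=55, potassium_mg=140,
                          sodium_mg=40, zinc_mg=0.3, copper_mg=0.12,
                          thiamine_mg=0.06, riboflavin_mg=0.07, niacin_mg=0.4,
                          pantothenate_mg=0.35, vitamin_b6_mg=0.06, folate_ug=15,
                          calcium_mg=25)),
        ("veggie_sausage", dict(energy_kcal=200, protein_g=18, fat_g=9, frac_sat=0.12,
                                frac_mufa=0.34, frac_pufa=0.46, frac_trans=0.0,
                                carbohydrate_g=8, sugar_g=1, fiber_g=3.8,
                                iron_mg=2.2, heme_frac=0.0, phytate_mg=150,
                                magnesium_mg=38, phosphorus_mg=180, potassium_mg=320,
                                sodium_mg=550, zinc_mg=1.2, copper_mg=0.2,
                                thiamine_mg=0.18, riboflavin_mg=0.1, niacin_mg=3.6,
                                pantothenate_mg=0.45, vitamin_b6_mg=0.25, folate_ug=50,
                                calcium_mg=60)),
        ("oat_milk", dict(energy_kcal=47, protein_g=1.0, fat_g=1.5, frac_sat=0.13,
                          frac_mufa=0.40, frac_pufa=0.40, frac_trans=0.0,
                          carbohydrate_g=7.0, sugar_g=4.0, fiber_g=0.8,
                          iron_mg=0.3, heme_frac=0.0, phytate_mg=40,
                          magnesium_mg=6, phosphorus_mg=45, potassium_mg=120,
                          sodium_mg=40, zinc_mg=0.2, copper_mg=0.05,
                          thiamine_mg=0.03, riboflavin_mg=0.06, niacin_mg=0.3,
                          pantothenate_mg=0.2, vitamin_b6_mg=0.02, folate_ug=6,
                          calcium_mg=20)),
        ("tofu", dict(energy_kcal=95, protein_g=10, fat_g=5.5, frac_sat=0.15,
                      frac_mufa=0.22, frac_pufa=0.56, frac_trans=0.0,
                      carbohydrate_g=2.0, sugar_g=0.5, fiber_g=1.0,
                      iron_mg=2.7, heme_frac=0.0, phytate_mg=200,
                      magnesium_mg=37, phosphorus_mg=120, potassium_mg=150,
                      sodium_mg=10, zinc_mg=1.0, copper_mg=0.2,
                      thiamine_mg=0.08, riboflavin_mg=0.06, niacin_mg=0.2,
                      pantothenate_mg=0.1, vitamin_b6_mg=0.06, folate_ug=19,
                      calcium_mg=200)),
        ("almond_milk", dict(energy_kcal=17, protein_g=0.6, fat_g=1.2, frac_sat=0.08,
                             frac_mufa=0.62, frac_pufa=0.25, frac_trans=0.0,
                             carbohydrate_g=0.7, sugar_g=0.3, fiber_g=0.4,
                             iron_mg=0.3, heme_frac=0.0, phytate_mg=25,
                             magnesium_mg=7, phosphorus_mg=10, potassium_mg=50,
                             sodium_mg=60, zinc_mg=0.1, copper_mg=0.04,
                             thiamine_mg=0.01, riboflavin_mg=0.06, niacin_mg=0.1,
                             pantothenate_mg=0.05, vitamin_b6_mg=0.01, folate_ug=2,
                             vitamin_c_mg=0.0, calcium_mg=120)),
    ],
    "unprocessed_alternative": [
        ("soybeans", dict(energy_kcal=172, protein_g=18, fat_g=9, frac_sat=0.14,
                          frac_mufa=0.22, frac_pufa=0.56, frac_trans=0.0,
                          carbohydrate_g=8.4, sugar_g=3.0, fiber_g=6.0,
                          iron_mg=5.1, heme_frac=0.0, phytate_mg=520,
                          magnesium_mg=86, phosphorus_mg=245, potassium_mg=515,
                          sodium_mg=1, zinc_mg=1.2, copper_mg=0.4,
                          vitamin_c_mg=1.7, thiamine_mg=0.16, riboflavin_mg=0.29,
                          niacin_mg=0.4, pantothenate_mg=0.18, vitamin_b6_mg=0.23,
                          folate_ug=54, calcium_mg=102)),
        ("peas", dict(energy_kcal=118, protein_g=8.3, fat_g=0.4, frac_sat=0.14,
                      frac_mufa=0.21, frac_pufa=0.42, frac_trans=0.0,
                      carbohydrate_g=21, sugar_g=2.9, fiber_g=8.3,
                      iron_mg=1.3, heme_frac=0.0, phytate_mg=230,
                      magnesium_mg=36, phosphorus_mg=99, potassium_mg=362,
                      sodium_mg=2, zinc_mg=1.0, copper_mg=0.18,
                      vitamin_c_mg=0.4, thiamine_mg=0.19, riboflavin_mg=0.06,
                      niacin_mg=0.9, pantothenate_mg=0.6, vitamin_b6_mg=0.05,
                      folate_ug=65, calcium_mg=14)),
        ("beans", dict(energy_kcal=127, protein_g=8.7, fat_g=0.5, frac_sat=0.2,
                       frac_mufa=0.1, frac_pufa=0.55, frac_trans=0.0,
                       carbohydrate_g=23, sugar_g=0.3, fiber_g=6.4,
                       iron_mg=2.9, heme_frac=0.0, phytate_mg=310,
                       magnesium_mg=45, phosphorus_mg=147, potassium_mg=405,
                       sodium_mg=1, zinc_mg=1.1, copper_mg=0.24,
                       vitamin_c_mg=1.2, thiamine_mg=0.16, riboflavin_mg=0.06,
                       niacin_mg=0.6, pantothenate_mg=0.22, vitamin_b6_mg=0.12,
                       folate_ug=130, calcium_mg=28)),
        ("oats", dict(energy_kcal=379, protein_g=13, fat_g=6.5, frac_sat=0.17,
                      frac_mufa=0.31, frac_pufa=0.37, frac_trans=0.0,
                      carbohydrate_g=68, sugar_g=1.0, fiber_g=10.1,
                      iron_mg=4.2, heme_frac=0.0, phytate_mg=740,
                      magnesium_mg=138, phosphorus_mg=410, potassium_mg=362,
                      sodium_mg=6, zinc_mg=3.6, copper_mg=0.4,
                      thiamine_mg=0.46, riboflavin_mg=0.16, niacin_mg=1.1,
                      pantothenate_mg=1.1, vitamin_b6_mg=0.1, folate_ug=32,
                      calcium_mg=52)),
        ("almonds", dict(energy_kcal=579, protein_g=21, fat_g=50, frac_sat=0.076,
                         frac_mufa=0.62, frac_pufa=0.25, frac_trans=0.0,
                         carbohydrate_g=22, sugar_g=4.4, fiber_g=12.5,
                         iron_mg=3.7, heme_frac=0.0, phytate_mg=1280,
                         magnesium_mg=270, phosphorus_mg=481, potassium_mg=733,
                         sodium_mg=1, zinc_mg=3.1, copper_mg=1.0,
                         thiamine_mg=0.2, riboflavin_mg=1.1, niacin_mg=3.6,
                         pantothenate_mg=0.47, vitamin_b6_mg=0.14, folate_ug=44,
                         calcium_mg=269)),
        ("rice", dict(energy_kcal=365, protein_g=7.1, fat_g=0.7, frac_sat=0.27,
                      frac_mufa=0.31, frac_pufa=0.36, frac_trans=0.0,
                      carbohydrate_g=80, sugar_g=0.1, fiber_g=1.3,
                      iron_mg=0.8, heme_frac=0.0, phytate_mg=240,
                      magnesium_mg=25, phosphorus_mg=115, potassium_mg=115,
                      sodium_mg=5, zinc_mg=1.1, copper_mg=0.22,
                      thiamine_mg=0.07, riboflavin_mg=0.05, niacin_mg=1.6,
                      pantothenate_mg=1.0, vitamin_b6_mg=0.16, folate_ug=8,
                      calcium_mg=28)),
    ],
    "other_diet_component": [
        ("bread", dict(energy_kcal=265, protein_g=9, fat_g=3.2, frac_sat=0.22,
                       frac_mufa=0.2, frac_pufa=0.45, frac_trans=0.0,
                       carbohydrate_g=49, sugar_g=5, fiber_g=2.7,
                       iron_mg=3.6, heme_frac=0.0, phytate_mg=120,
                       magnesium_mg=23, phosphorus_mg=98, potassium_mg=115,
                       sodium_mg=490, zinc_mg=0.7, copper_mg=0.1,
                       thiamine_mg=0.5, riboflavin_mg=0.3, niacin_mg=4.8,
                       pantothenate_mg=0.55, vitamin_b6_mg=0.09, folate_ug=85,
                       calcium_mg=144)),
        ("vegetables", dict(energy_kcal=35, protein_g=2.0, fat_g=0.3, frac_sat=0.15,
                            frac_mufa=0.05, frac_pufa=0.45, frac_trans=0.0,
                            carbohydrate_g=7, sugar_g=3, fiber_g=2.8,
                            iron_mg=0.8, heme_frac=0.0, phytate_mg=30,
                            magnesium_mg=15, phosphorus_mg=35, potassium_mg=250,
                            sodium_mg=30, zinc_mg=0.3, copper_mg=0.06,
                            vitamin_c_mg=25, thiamine_mg=0.06, riboflavin_mg=0.07,
                            niacin_mg=0.7, pantothenate_mg=0.25, vitamin_b6_mg=0.12,
                            folate_ug=45, vitamin_a_ug_rae=180, calcium_mg=35)),
        ("fruit", dict(energy_kcal=55, protein_g=0.7, fat_g=0.2, frac_sat=0.2,
                       frac_mufa=0.1, frac_pufa=0.3, frac_trans=0.0,
                       carbohydrate_g=14, sugar_g=10, fiber_g=2.2,
                       iron_mg=0.3, heme_frac=0.0, phytate_mg=10,
                       magnesium_mg=9, phosphorus_mg=15, potassium_mg=180,
                       sodium_mg=1, zinc_mg=0.1, copper_mg=0.06,
                       vitamin_c_mg=30, thiamine_mg=0.03, riboflavin_mg=0.03,
                       niacin_mg=0.4, pantothenate_mg=0.2, vitamin_b6_mg=0.08,
                       folate_ug=15, vitamin_a_ug_rae=25, calcium_mg=12)),
    ],
}

_SERVING_G = {
    "meat": 110.0,
    "dairy": 240.0,  # ml treated as g
    "veggie_burger": 110.0,
    "veggie_sausage": 110.0,
    "tofu": 85.0,
    "soy_milk": 240.0,
    "oat_milk": 240.0,
    "almond_milk": 240.0,
    "unprocessed_alternative": 40.0,
    "other_diet_component": 100.0,
}

# land (m2/kg) and water (L/kg) per unit of GHG-tier scale
_LAND_PER_GHG = 3.3
_WATER_PER_GHG = 35.0

_PRICE_PER_KG = {  # USD/kg, 2020-ish magnitudes before markup/jitter
    "meat": 9.0,
    "dairy": 1.2,
    "unprocessed_alternative": 2.5,
    "other_diet_component": 2.0,
}


def _jittered(rng: np.random.Generator, value: float, jitter: float) -> float:
    if value == 0:
        return 0.0
    return float(value * rng.uniform(1 - jitter, 1 + jitter))


def _build_profile(
    rng: np.random.Generator, base: dict, spec: GeneratorSpec, animal: bool
) -> NutrientProfile:
    amounts = dict(_BASE)
    fracs = {k: base.get(k, 0.0) for k in ("frac_sat", "frac_mufa", "frac_pufa", "frac_trans")}
    heme_frac = base.get("heme_frac", 0.0)
    if animal:
        fracs["frac_sat"] *= spec.animal_satfat_factor
        heme_frac = min(heme_frac * spec.animal_heme_factor, 1.0)
    else:
        fracs["frac_pufa"] *= spec.plant_pufa_factor
    total_frac = sum(fracs.values())
    if total_frac > 1.0:
        fracs = {k: v / total_frac for k, v in fracs.items()}
    for key, value in base.items():
        if key.startswith("frac_") or key == "heme_frac":
            continue
        v = value
        if animal and key == "cholesterol_mg":
            v *= spec.animal_cholesterol_factor
        if not animal and key == "fiber_g":
            v *= spec.plant_fiber_factor
        if not animal and key == "potassium_mg":
            v *= spec.plant_potassium_factor
        amounts[key] = _jittered(rng, v, spec.jitter)
    fat = amounts["fat_g"]
    amounts["saturated_fat_g"] = fat * fracs["frac_sat"]
    amounts["mufa_g"] = fat * fracs["frac_mufa"]
    amounts["pufa_g"] = fat * fracs["frac_pufa"]
    amounts["trans_fat_g"] = fat * fracs["frac_trans"]
    amounts["heme_iron_mg"] = amounts["iron_mg"] * heme_frac
    return NutrientProfile(amounts)


def _fortify(profile: NutrientProfile, spec: GeneratorSpec) -> NutrientProfile:
    amounts = dict(profile.amounts)
    amounts["vitamin_b12_ug"] += spec.fortify_b12_ug
    amounts["riboflavin_mg"] += spec.fortify_riboflavin_mg
    amounts["vitamin_a_ug_rae"] += spec.fortify_vitamin_a_ug
    return NutrientProfile(amounts)


def _footprint(
    rng: np.random.Generator, spec: GeneratorSpec, category: str, archetype: str
) -> EnvironmentalFootprint:
    if archetype in ("beef", "beef_burger"):
        tier = spec.footprint_beef * (0.9 if archetype == "beef_burger" else 1.0)
    elif category == "meat":
        tier = spec.footprint_other_meat
    elif category == "dairy":
        tier = spec.footprint_dairy
    else:
        tier = spec.footprint_plant
    ghg = _jittered(rng, tier, spec.jitter)
    land = _jittered(rng, tier * _LAND_PER_GHG, spec.jitter)
    water = _jittered(rng, tier * _WATER_PER_GHG, spec.jitter)
    return EnvironmentalFootprint.from_per_kg(ghg, land, water)


def _price(
    rng: np.random.Generator, spec: GeneratorSpec, category: str, year: int
) -> PriceRecord:
    if category == "processed_alternative":
        base = _PRICE_PER_KG["unprocessed_alternative"] * spec.price_markup_processed
    else:
        base = _PRICE_PER_KG[category]
    return PriceRecord(value=_jittered(rng, base, spec.jitter), currency="USD", year=year)


def _serving(category: str, archetype: str) -> float:
    return _SERVING_G.get(archetype, _SERVING_G.get(category, 100.0))


def generate_foods(spec: GeneratorSpec) -> dict[str, FoodProduct]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    counts = {
        "meat": spec.n_meat,
        "dairy": spec.n_dairy,
        "processed_alternative": spec.n_processed,
        "unprocessed_alternative": spec.n_unprocessed,
        "other_diet_component": spec.n_other,
    }
    foods: dict[str, FoodProduct] = {}
    years = (2018, 2019, 2020, 2021, 2022)
    for category, n in counts.items():
        archetypes = _ARCHETYPES[category]
        for i in range(n):
            name, base = archetypes[i % len(archetypes)]
            fid = name if i < len(archetypes) else f"{name}_{i // len(archetypes) + 1}"
            animal = category in ("meat", "dairy")
            profile = _build_profile(rng, base, spec, animal)
            if category == "processed_alternative" and spec.fortification:
                profile = _fortify(profile, spec)
            foods[fid] = FoodProduct(
                id=fid,
                name=name.replace("_", " "),
                category=category,
                serving_g=_serving(category, name),
                profile=profile,
                footprint=_footprint(rng, spec, category, name),
                price=_price(rng, spec, category, years[int(rng.integers(len(years)))]),
            )
    return foods


def generate_baseline_diet(
    spec: GeneratorSpec, foods: Mapping[str, FoodProduct]
) -> DietaryIntake:
    """Baseline diet allocating calorie shares to meat, dairy, and other foods."""
    shares = {
        "meat": spec.meat_kcal_share,
        "dairy": spec.dairy_kcal_share,
        "other_diet_component": 1 - spec.meat_kcal_share - spec.dairy_kcal_share,
    }
    intakes: dict[str, float] = {}
    for category, share in shares.items():
        members = [f for f in foods.values() if f.category == category]
        if not members:
            raise TableError(f"degenerate spec: no foods in category {category!r}")
        kcal_each = spec.total_kcal * share / len(members)
        for f in members:
            if f.kcal_per_g <= 0:
                raise TableError(f"{f.id}: zero energy density in baseline diet")
            intakes[f.id] = kcal_each / f.kcal_per_g
    return DietaryIntake(region=spec.region, intakes=intakes, waste_adjusted=True)


def generate_mortality(spec: GeneratorSpec) -> MortalityData:
    # fixed HIC-like envelope: crude death rate 9/1000, cause mix typical
    population = 10_000_000.0
    return MortalityData(
        region=spec.region,
        deaths={"CHD": 13_500.0, "stroke": 7_000.0, "cancer": 25_000.0, "all_cause": 90_000.0},
        population=population,
    )


def generate_series(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CPI (food, 2% inflation, base 2020 = 100) and PPP series for USD."""
    years = list(range(2015, 2026))
    cpi = pd.DataFrame(
        {
            "entity": "USD",
            "year": years,
            "value": [100.0 * 1.02 ** (y - 2020) for y in years],
        }
    )
    ppp = pd.DataFrame({"entity": ["USD"], "year": [2020], "value": [1.0]})
    return cpi, ppp


def generate_bundle(spec: GeneratorSpec) -> Bundle:
    """Produce a complete input bundle; all tables pass core validation.

    Raises if the construction knobs fail to produce the structure they
    encode (e.g. a footprint ratio <= 1 making beef no worse than legumes).
    """
    foods = generate_foods(spec)
    diet = generate_baseline_diet(spec, foods)
    cpi, ppp = generate_series(spec)
    bundle = Bundle(
        foods=foods,
        diets={spec.region: diet},
        recommendations=default_recommendations(),
        rr_table=default_rr_table(),
        mortality={spec.region: generate_mortality(spec)},
        zinc_phytate_table=default_zinc_phytate_table(),
        cpi=cpi,
        ppp=ppp,
        config=AnalysisConfig(regions=(spec.region,), seed=spec.seed),
    )
    bundle.validate()
    _assert_structure(bundle)
    return bundle


def _assert_structure(bundle: Bundle) -> None:
    foods = bundle.foods
    beef_like = [f for f in foods.values() if f.category == "meat" and f.id.startswith("beef")]
    legumes = [f for f in foods.values() if f.category == "unprocessed_alternative"]
    if beef_like and legumes:
        min_beef_ghg = min(f.footprint.ghg for f in beef_like)
        max_plant_ghg = max(f.footprint.ghg for f in legumes)
        if min_beef_ghg <= max_plant_ghg:
            raise TableError(
                "generated bundle violates footprint hierarchy: beef GHG "
                "<= plant GHG; check the footprint tier knobs"
            )
        meat_sat = min(
            f.profile["saturated_fat_g"] * f.serving_g / 100
            for f in foods.values()
            if f.category == "meat"
        )
        plant_sat = max(
            f.profile["saturated_fat_g"] * f.serving_g / 100 for f in legumes
        )
        if meat_sat <= plant_sat:
            raise TableError(
                "generated bundle violates nutrient structure: meat saturated "
                "fat per serving <= plant saturated fat per serving"
            )


def generate_known_answer_diet(
    target_deviations: Mapping[str, float],
    recommendations: Sequence[NutrientRecommendation] | None = None,
) -> tuple[DietaryIntake, dict[str, FoodProduct], list[NutrientRecommendation]]:
    """Construct a one-food diet realizing exact per-nutrient deviations.

    ``target_deviations`` maps every recommended nutrient to its signed
    percentage deviation from the recommendation ((intake - rec)/rec x 100).
    Returns the diet (100 g/day of one synthetic food), the food table, and
    the static recommendation list the targets refer to. Running the
    nutrition module on the output reproduces the targets to numerical
    precision.
    """
    if recommendations is None:
        recommendations = static_recommendations()
    rec_nutrients = {r.nutrient for r in recommendations}
    missing = rec_nutrients - set(target_deviations)
    if missing:
        raise TableError(f"target deviations missing for: {sorted(missing)}")
    unknown = set(target_deviations) - rec_nutrients
    if unknown:
        raise TableError(f"targets for non-recommended nutrients: {sorted(unknown)}")
    amounts = dict(_BASE)
    for rec in recommendations:
        dev = float(target_deviations[rec.nutrient])
        intake = rec.daily_value * (1 + dev / 100.0)
        if intake < 0:
            raise TableError(
                f"infeasible target for {rec.nutrient}: deviation {dev}% implies "
                "negative intake"
            )
        amounts[rec.nutrient] = intake  # diet is 100 g/day, so per-100g == per-day
    # keep profile invariants satisfied for nutrients without recommendations
    fat_parts = (
        amounts["saturated_fat_g"] + amounts["mufa_g"] + amounts["pufa_g"] + amounts["trans_fat_g"]
    )
    amounts["fat_g"] = max(amounts["fat_g"], fat_parts)
    amounts["iron_mg"] = max(amounts["iron_mg"], amounts["heme_iron_mg"])
    food = FoodProduct(
        id="ka_food",
        name="known-answer synthetic food",
        category="other_diet_component",
        serving_g=100.0,
        profile=NutrientProfile(amounts),
        footprint=EnvironmentalFootprint.from_per_kg(1.0, 1.0, 1.0),
        price=PriceRecord(value=1.0, currency="USD", year=2020),
    )
    diet = DietaryIntake(region="KA", intakes={"ka_food": 100.0}, waste_adjusted=True)
    return diet, {"ka_food": food}, list(recommendations)


def default_scenarios(bundle: Bundle, basis: str = "calorie") -> Bundle:
    """Bundle copy with the full scenario matrix (meat and dairy pools)."""
    from .replacement import scenario_matrix, with_scenarios

    region = bundle.config.regions[0]
    scenarios = scenario_matrix(bundle, "meat", region=region, basis=basis)
    scenarios += scenario_matrix(bundle, "dairy", region=region, basis=basis)
    return with_scenarios(bundle, scenarios)
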
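"""Packaged default reference tables.

These tables are ILLUSTRATIVE: plausible, clearly-labeled stand-ins at the
order of magnitude of published population-average requirements and
meta-analysis relative risks, intended to make every stage of the pipeline
runnable and testable. They are plain data — replace them with your own
harmonized tables for real analyses. Absolute diet-level results (baseline
imbalance level, mortality change) depend on these choices; the comparative
structure does not.
"""

from __future__ import annotations

import pandas as pd

from .core_tables import NutrientRecommendation

SOURCE_TAG = "illustrative-default"


def default_recommendations() -> list[NutrientRecommendation]:
    """Population-average daily recommendations with direction.

    Calcium is intentionally absent (no recommendation in this analysis);
    zinc and iron carry diet-dependent handlers and their listed values are
    only fallbacks before adjustment.
    """
    minimums = {
        "protein_g": 50.0,
        "fiber_g": 30.0,
        "pufa_g": 13.0,
        "potassium_mg": 3500.0,
        "iron_mg": 8.0,
        "zinc_mg": 9.0,
        "magnesium_mg": 350.0,
        "phosphorus_mg": 550.0,
        "copper_mg": 1.0,
        "vitamin_c_mg": 80.0,
        "thiamine_mg": 1.0,
        "riboflavin_mg": 1.2,
        "niacin_mg": 14.0,
        "pantothenate_mg": 5.0,
        "vitamin_b6_mg": 1.4,
        "folate_ug": 330.0,
        "vitamin_b12_ug": 4.0,
        "vitamin_a_ug_rae": 650.0,
    }
    maximums = {
        "energy_kcal": 2100.0,
        "saturated_fat_g": 23.0,  # ~10% of energy
        "trans_fat_g": 2.3,  # ~1% of energy
        "sugar_g": 52.0,  # ~10% of energy
        "sodium_mg": 2000.0,
        "cholesterol_mg": 300.0,
    }
    handlers = {"zinc_mg": "zinc_phytate", "iron_mg": "iron_absorption"}
    recs = [
        NutrientRecommendation(n, "minimum", v, SOURCE_TAG, handlers.get(n, "none"))
        for n, v in minimums.items()
    ]
    recs += [
        NutrientRecommendation(n, "maximum", v, SOURCE_TAG, "none")
        for n, v in maximums.items()
    ]
    return recs


def static_recommendations() -> list[NutrientRecommendation]:
    """Defaults with diet-dependent handlers disabled (fixed daily values)."""
    return [
        NutrientRecommendation(r.nutrient, r.direction, r.daily_value, r.source, "none")
        for r in default_recommendations()
    ]


def default_rr_table() -> pd.DataFrame:
    """Relative risks per exposure increment by (factor, endpoint).

    All six factors map to CHD and stroke; heme iron and fiber additionally
    to cancer. Protective factors have RR < 1 per positive increment.
    """
    rows = [
        # factor, endpoint, RR per increment, increment, unit
        ("pufa", "CHD", 0.90, 5.0, "g/day"),
        ("pufa", "stroke", 0.96, 5.0, "g/day"),
        ("fiber", "CHD", 0.93, 10.0, "g/day"),
        ("fiber", "stroke", 0.93, 10.0, "g/day"),
        ("fiber", "cancer", 0.90, 10.0, "g/day"),
        ("potassium", "CHD", 0.96, 1000.0, "mg/day"),
        ("potassium", "stroke", 0.89, 1000.0, "mg/day"),
        ("cholesterol", "CHD", 1.10, 100.0, "mg/day"),
        ("cholesterol", "stroke", 1.04, 100.0, "mg/day"),
        ("sodium", "CHD", 1.06, 1000.0, "mg/day"),
        ("sodium", "stroke", 1.08, 1000.0, "mg/day"),
        ("heme_iron", "CHD", 1.07, 1.0, "mg/day"),
        ("heme_iron", "stroke", 1.03, 1.0, "mg/day"),
        ("heme_iron", "cancer", 1.08, 1.0, "mg/day"),
    ]
    return pd.DataFrame(rows, columns=["factor", "endpoint", "rr", "increment", "unit"])


def default_zinc_phytate_table() -> pd.DataFrame:
    """Phytate-dependent zinc requirement reference points (monotone)."""
    return pd.DataFrame(
        {
            "phytate_mg": [300.0, 600.0, 900.0, 1200.0],
            "zinc_mg": [6.2, 7.5, 8.9, 10.2],
        }
    )
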
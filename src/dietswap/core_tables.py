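"""Domain types, validation, and CSV/YAML readers and writers.

All tables are plain UTF-8 CSV with "." decimals. Per-mass quantities are
stored per 100 g internally; environmental footprints and prices are
reported per kg in files (the composition-table convention on one side,
the LCA/market convention on the other) and converted on load.

Column dictionaries are fixed: an unrecognized column in an input table is
an error, never silently ignored, because a misspelled nutrient column
would silently corrupt the imbalance indicator downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .nutrients import FAT_BALANCE_TOL, FAT_PARTS, NUTRIENTS

FOOD_CATEGORIES = (
    "meat",
    "dairy",
    "processed_alternative",
    "unprocessed_alternative",
    "other_diet_component",
)

RISK_FACTORS = ("pufa", "fiber", "potassium", "cholesterol", "sodium", "heme_iron")
ENDPOINTS = ("CHD", "stroke", "cancer")

#: Exposure cap (mg/day) above which additional potassium confers no
#: further risk reduction.
POTASSIUM_CAP_MG = 3500.0


class TableError(ValueError):
    """Raised for malformed or internally inconsistent input tables."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient amounts per 100 g edible food (see :mod:`dietswap.nutrients`)."""

    amounts: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.amounts) - set(NUTRIENTS)
        if unknown:
            raise TableError(f"unknown nutrient columns: {sorted(unknown)}")
        filled = {n: float(self.amounts.get(n, 0.0)) for n in NUTRIENTS}
        object.__setattr__(self, "amounts", filled)
        for n, v in filled.items():
            if v < 0 or not math.isfinite(v):
                raise TableError(f"nutrient {n} must be finite and >= 0, got {v}")
        if filled["heme_iron_mg"] > filled["iron_mg"] * (1 + 1e-9):
            raise TableError(
                f"heme iron ({filled['heme_iron_mg']} mg) exceeds total iron "
                f"({filled['iron_mg']} mg)"
            )
        parts = sum(filled[p] for p in FAT_PARTS)
        if parts > filled["fat_g"] * (1 + FAT_BALANCE_TOL) + 1e-12:
            raise TableError(
                f"fat components sum to {parts:.3f} g, exceeding total fat "
                f"{filled['fat_g']:.3f} g beyond tolerance"
            )

    def __getitem__(self, nutrient: str) -> float:
        return self.amounts[nutrient]

    @property
    def energy_kcal_per_100g(self) -> float:
        return self.amounts["energy_kcal"]


@dataclass(frozen=True)
class EnvironmentalFootprint:
    """Footprint per 100 g food: GHG (kg CO2eq), land (m2), water (L).

    ``processing_ghg`` is an optional additive GHG increment (e.g. cooking
    emissions) used by the processing-emissions sensitivity; it is kept
    separate so the main analysis can ignore it.
    """

    ghg: float
    land: float
    water: float
    processing_ghg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ghg", "land", "water", "processing_ghg"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise TableError(f"footprint {name} must be finite and >= 0, got {v}")

    @classmethod
    def from_per_kg(
        cls, ghg: float, land: float, water: float, processing_ghg: float = 0.0
    ) -> "EnvironmentalFootprint":
        return cls(ghg / 10.0, land / 10.0, water / 10.0, processing_ghg / 10.0)

    def per_kg(self, domain: str, include_processing: bool = False) -> float:
        value = getattr(self, domain) * 10.0
        if include_processing and domain == "ghg":
            value += self.processing_ghg * 10.0
        return value


@dataclass(frozen=True)
class PriceRecord:
    """One observed market price (per kg edible food)."""

    value: float
    currency: str
    year: int
    basis: str = "kg"

    def __post_init__(self) -> None:
        if self.value < 0 or not math.isfinite(self.value):
            raise TableError(f"price must be finite and >= 0, got {self.value}")
        if self.basis != "kg":
            raise TableError(f"unsupported price basis {self.basis!r}; use per-kg prices")


@dataclass(frozen=True)
class FoodProduct:
    id: str
    name: str
    category: str
    serving_g: float
    profile: NutrientProfile
    footprint: EnvironmentalFootprint
    price: PriceRecord
    variant: str | None = None

    def __post_init__(self) -> None:
        if self.category not in FOOD_CATEGORIES:
            raise TableError(f"{self.id}: unknown category {self.category!r}")
        if self.serving_g <= 0:
            raise TableError(f"{self.id}: serving size must be > 0")

    @property
    def kcal_per_serving(self) -> float:
        return self.profile.energy_kcal_per_100g * self.serving_g / 100.0

    @property
    def kcal_per_g(self) -> float:
        return self.profile.energy_kcal_per_100g / 100.0


@dataclass(frozen=True)
class DietaryIntake:
    """Region-level consumption, g/person/day per food id, waste-adjusted."""

    region: str
    intakes: Mapping[str, float]
    waste_adjusted: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "intakes", dict(self.intakes))
        for fid, g in self.intakes.items():
            if g < 0 or not math.isfinite(g):
                raise TableError(f"intake of {fid} must be finite and >= 0, got {g}")

    def total_energy_kcal(self, foods: Mapping[str, FoodProduct]) -> float:
        missing = set(self.intakes) - set(foods)
        if missing:
            raise TableError(f"diet references unknown foods: {sorted(missing)}")
        return sum(
            g / 100.0 * foods[f].profile.energy_kcal_per_100g
            for f, g in self.intakes.items()
        )


@dataclass(frozen=True)
class NutrientRecommendation:
    """Population-average daily recommendation with a direction.

    ``direction`` is ``minimum`` (shortfalls below ``daily_value`` count as
    violations) or ``maximum`` (excesses count). ``handler`` marks nutrients
    whose requirement is diet-dependent and resolved per scenario:
    ``zinc_phytate`` (phytate-dependent zinc requirement) or
    ``iron_absorption`` (absorption-adjusted iron requirement).
    """

    nutrient: str
    direction: str
    daily_value: float
    source: str = "illustrative"
    handler: str = "none"

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise TableError(f"recommendation for unknown nutrient {self.nutrient!r}")
        if self.nutrient == "calcium_mg":
            raise TableError("calcium carries no recommendation in this analysis")
        if self.direction not in ("minimum", "maximum"):
            raise TableError(f"direction must be minimum|maximum, got {self.direction!r}")
        if self.daily_value <= 0:
            raise TableError(f"{self.nutrient}: daily value must be > 0")
        if self.handler not in ("none", "zinc_phytate", "iron_absorption"):
            raise TableError(f"unknown handler {self.handler!r}")


@dataclass(frozen=True)
class RiskFactorDefinition:
    factor: str
    exposure_nutrient: str
    unit: str
    direction: str
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.factor not in RISK_FACTORS:
            raise TableError(f"unknown risk factor {self.factor!r}")
        if self.direction not in ("protective", "harmful"):
            raise TableError(f"direction must be protective|harmful, got {self.direction!r}")


@dataclass(frozen=True)
class MortalityData:
    region: str
    deaths: Mapping[str, float]  # keys: CHD, stroke, cancer, all_cause
    population: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "deaths", dict(self.deaths))
        required = set(ENDPOINTS) | {"all_cause"}
        missing = required - set(self.deaths)
        if missing:
            raise TableError(f"mortality data missing causes: {sorted(missing)}")
        for cause, d in self.deaths.items():
            if d < 0:
                raise TableError(f"deaths for {cause} must be >= 0")
        cause_sum = sum(self.deaths[c] for c in ENDPOINTS)
        if cause_sum > self.deaths["all_cause"] * (1 + 1e-9):
            raise TableError("cause-specific deaths exceed all-cause deaths")
        if self.population <= 0:
            raise TableError("population must be > 0")


@dataclass(frozen=True)
class SynthesisWeights:
    """Weighting tree for the 0-100 multicriteria score.

    Defaults: health, environment and cost weigh one third each; nutrition
    and mortality split the health domain equally; the environmental
    subweights follow the planetary-boundary scheme (GHG 0.65, land 0.17,
    water 0.18).
    """

    health: float = 1.0 / 3.0
    environment: float = 1.0 / 3.0
    cost: float = 1.0 / 3.0
    nutrition: float = 0.5
    mortality: float = 0.5
    ghg: float = 0.65
    land: float = 0.17
    water: float = 0.18

    def __post_init__(self) -> None:
        for label, total in (
            ("top-level", self.health + self.environment + self.cost),
            ("health", self.nutrition + self.mortality),
            ("environment", self.ghg + self.land + self.water),
        ):
            if abs(total - 1.0) > 1e-9:
                raise TableError(f"{label} weights sum to {total!r}, expected 1")

    @property
    def env_weights(self) -> dict[str, float]:
        return {"ghg": self.ghg, "land": self.land, "water": self.water}


EQUAL_ENV_WEIGHTS = {"ghg": 1 / 3, "land": 1 / 3, "water": 1 / 3}

DOMAINS = ("nutrition_pp", "mortality_pct", "ghg_pct", "land_pct", "water_pct", "cost_pct")


@dataclass(frozen=True)
class DomainChange:
    """Signed change in one assessment domain for one scenario.

    Nutrition is in percentage points of the imbalance indicator; the other
    domains are percent of the baseline-diet value.
    """

    scenario: str
    domain: str
    value: float

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise TableError(f"unknown domain {self.domain!r}")


# ---------------------------------------------------------------------------
# Food table I/O
# ---------------------------------------------------------------------------

_FOOD_META_COLUMNS = (
    "id",
    "name",
    "category",
    "serving_g",
    "variant",
    "ghg_kg_per_kg",
    "land_m2_per_kg",
    "water_l_per_kg",
    "processing_ghg_kg_per_kg",
    "price_value",
    "price_currency",
    "price_year",
)

FOOD_TABLE_COLUMNS: tuple[str, ...] = _FOOD_META_COLUMNS + NUTRIENTS


def read_food_table(path: str | Path) -> dict[str, FoodProduct]:
    """Read a food table CSV into validated :class:`FoodProduct` records."""
    df = pd.read_csv(
        path, dtype={"id": str, "name": str, "category": str},
        float_precision="round_trip",
    )
    missing = set(FOOD_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"food table missing columns: {sorted(missing)}")
    extra = set(df.columns) - set(FOOD_TABLE_COLUMNS)
    if extra:
        raise TableError(f"food table has unknown columns: {sorted(extra)}")
    foods: dict[str, FoodProduct] = {}
    for _, row in df.iterrows():
        fid = row["id"]
        if fid in foods:
            raise TableError(f"duplicate food id {fid!r}")
        try:
            profile = NutrientProfile({n: row[n] for n in NUTRIENTS})
            footprint = EnvironmentalFootprint.from_per_kg(
                row["ghg_kg_per_kg"],
                row["land_m2_per_kg"],
                row["water_l_per_kg"],
                row["processing_ghg_kg_per_kg"],
            )
            price = PriceRecord(
                value=float(row["price_value"]),
                currency=str(row["price_currency"]),
                year=int(row["price_year"]),
            )
            variant = row["variant"]
            foods[fid] = FoodProduct(
                id=fid,
                name=str(row["name"]),
                category=str(row["category"]),
                serving_g=float(row["serving_g"]),
                profile=profile,
                footprint=footprint,
                price=price,
                variant=None if pd.isna(variant) else str(variant),
            )
        except TableError as err:
            raise TableError(f"food {fid!r}: {err}") from err
    return foods


def write_food_table(foods: Mapping[str, FoodProduct], path: str | Path) -> None:
    rows = []
    for f in foods.values():
        row: dict[str, object] = {
            "id": f.id,
            "name": f.name,
            "category": f.category,
            "serving_g": f.serving_g,
            "variant": f.variant,
            "ghg_kg_per_kg": f.footprint.per_kg("ghg"),
            "land_m2_per_kg": f.footprint.per_kg("land"),
            "water_l_per_kg": f.footprint.per_kg("water"),
            "processing_ghg_kg_per_kg": f.footprint.processing_ghg * 10.0,
            "price_value": f.price.value,
            "price_currency": f.price.currency,
            "price_year": f.price.year,
        }
        row.update({n: f.profile[n] for n in NUTRIENTS})
        rows.append(row)
    pd.DataFrame(rows, columns=list(FOOD_TABLE_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Other table I/O
# ---------------------------------------------------------------------------


def read_diet_table(path: str | Path) -> dict[str, DietaryIntake]:
    df = _read_exact(path, ("region", "food_id", "intake_g_day", "waste_adjusted"))
    diets: dict[str, DietaryIntake] = {}
    for region, grp in df.groupby("region", sort=True):
        if grp["food_id"].duplicated().any():
            dup = grp.loc[grp["food_id"].duplicated(), "food_id"].iloc[0]
            raise TableError(f"region {region!r}: duplicate diet entry for {dup!r}")
        diets[str(region)] = DietaryIntake(
            region=str(region),
            intakes=dict(zip(grp["food_id"].astype(str), grp["intake_g_day"].astype(float))),
            waste_adjusted=bool(grp["waste_adjusted"].all()),
        )
    return diets


def write_diet_table(diets: Mapping[str, DietaryIntake], path: str | Path) -> None:
    rows = [
        {
            "region": d.region,
            "food_id": fid,
            "intake_g_day": g,
            "waste_adjusted": d.waste_adjusted,
        }
        for d in diets.values()
        for fid, g in sorted(d.intakes.items())
    ]
    pd.DataFrame(rows, columns=["region", "food_id", "intake_g_day", "waste_adjusted"]).to_csv(
        path, index=False
    )


def read_recommendation_table(path: str | Path) -> list[NutrientRecommendation]:
    df = _read_exact(path, ("nutrient", "direction", "daily_value", "source", "handler"))
    recs = [
        NutrientRecommendation(
            nutrient=str(r.nutrient),
            direction=str(r.direction),
            daily_value=float(r.daily_value),
            source=str(r.source),
            handler=str(r.handler),
        )
        for r in df.itertuples()
    ]
    seen: set[str] = set()
    for rec in recs:
        if rec.nutrient in seen:
            raise TableError(f"duplicate recommendation for {rec.nutrient}")
        seen.add(rec.nutrient)
    return recs


def write_recommendation_table(
    recs: Iterable[NutrientRecommendation], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "nutrient": r.nutrient,
                "direction": r.direction,
                "daily_value": r.daily_value,
                "source": r.source,
                "handler": r.handler,
            }
            for r in recs
        ],
        columns=["nutrient", "direction", "daily_value", "source", "handler"],
    ).to_csv(path, index=False)


def read_rr_table(path: str | Path) -> pd.DataFrame:
    """Relative risks per exposure increment, one row per (factor, endpoint)."""
    df = _read_exact(path, ("factor", "endpoint", "rr", "increment", "unit"))
    for r in df.itertuples():
        if r.factor not in RISK_FACTORS:
            raise TableError(f"unknown risk factor {r.factor!r}")
        if r.endpoint not in ENDPOINTS:
            raise TableError(f"unknown endpoint {r.endpoint!r}")
        if r.rr <= 0:
            raise TableError(f"RR must be > 0 for ({r.factor}, {r.endpoint})")
        if r.increment <= 0:
            raise TableError(f"increment must be > 0 for ({r.factor}, {r.endpoint})")
    if df.duplicated(subset=["factor", "endpoint"]).any():
        raise TableError("duplicate (factor, endpoint) rows in RR table")
    return df.reset_index(drop=True)


def read_mortality_table(path: str | Path) -> dict[str, MortalityData]:
    df = _read_exact(path, ("region", "cause", "deaths", "population"))
    out: dict[str, MortalityData] = {}
    for region, grp in df.groupby("region", sort=True):
        pops = grp["population"].unique()
        if len(pops) != 1:
            raise TableError(f"region {region!r}: inconsistent population values")
        out[str(region)] = MortalityData(
            region=str(region),
            deaths=dict(zip(grp["cause"].astype(str), grp["deaths"].astype(float))),
            population=float(pops[0]),
        )
    return out


def read_series_table(path: str | Path) -> pd.DataFrame:
    """Long-format (entity, year, value) series, e.g. CPI or PPP."""
    df = _read_exact(path, ("entity", "year", "value"))
    if df.duplicated(subset=["entity", "year"]).any():
        raise TableError("duplicate (entity, year) rows in series table")
    return df.reset_index(drop=True)


def _read_exact(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(columns) - set(df.columns)
    if missing:
        raise TableError(f"{Path(path).name}: missing columns {sorted(missing)}")
    extra = set(df.columns) - set(columns)
    if extra:
        raise TableError(f"{Path(path).name}: unknown columns {sorted(extra)}")
    return df


# ---------------------------------------------------------------------------
# Analysis configuration and bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """One replacement scenario from the configuration file."""

    id: str
    region: str
    replace: str  # meat | dairy | both
    alternatives: Mapping[str, str]  # replaced category -> alternative food id
    basis: str = "calorie"
    sodium_addon_mg_per_100g: float = 0.0
    processing_emissions: bool = False

    def __post_init__(self) -> None:
        if self.replace not in ("meat", "dairy", "both"):
            raise TableError(f"replace must be meat|dairy|both, got {self.replace!r}")
        if self.basis not in ("calorie", "serving"):
            raise TableError(f"basis must be calorie|serving, got {self.basis!r}")
        needed = {"meat", "dairy"} if self.replace == "both" else {self.replace}
        if set(self.alternatives) != needed:
            raise TableError(
                f"scenario {self.id!r}: alternatives must cover {sorted(needed)}"
            )
        object.__setattr__(self, "alternatives", dict(self.alternatives))


@dataclass(frozen=True)
class IronModelParams:
    """Absorption model behind the diet-dependent iron requirement.

    Heme iron is absorbed at a constant fraction; nonheme absorption is
    log-linear in dietary mediators (phytate, calcium, vitamin C, meat):
    ``a = exp(intercept + sum(coef * intake))``, clamped into (0, max].
    """

    target_absorbed_mg: float = 1.4
    heme_absorption: float = 0.25
    log_intercept: float = -2.0  # exp(-2.0) ~ 0.135 baseline nonheme absorption
    coef_phytate_per_mg: float = -4e-4
    coef_calcium_per_mg: float = -1e-4
    coef_vitamin_c_per_mg: float = 2e-3
    coef_meat_per_g: float = 1e-3
    max_absorption: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.heme_absorption <= 1:
            raise TableError("heme absorption must be in (0, 1]")
        if not 0 < self.max_absorption <= 1:
            raise TableError("max absorption must be in (0, 1]")
        if self.target_absorbed_mg <= 0:
            raise TableError("target absorbed iron must be > 0")


@dataclass(frozen=True)
class AnalysisConfig:
    regions: tuple[str, ...] = ("HIC",)
    weights: SynthesisWeights = field(default_factory=SynthesisWeights)
    scenarios: tuple[ScenarioSpec, ...] = ()
    basis: str = "calorie"
    seed: int = 0
    base_year: int = 2020
    iron_model: IronModelParams = field(default_factory=IronModelParams)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML analysis configuration, filling defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    w = raw.get("weights", {})
    weights = SynthesisWeights(
        health=float(w.get("health", 1 / 3)),
        environment=float(w.get("environment", 1 / 3)),
        cost=float(w.get("cost", 1 / 3)),
        nutrition=float(w.get("nutrition", 0.5)),
        mortality=float(w.get("mortality", 0.5)),
        ghg=float(w.get("ghg", 0.65)),
        land=float(w.get("land", 0.17)),
        water=float(w.get("water", 0.18)),
    )
    scenarios = tuple(
        ScenarioSpec(
            id=str(s["id"]),
            region=str(s.get("region", "HIC")),
            replace=str(s["replace"]),
            alternatives={str(k): str(v) for k, v in s["alternatives"].items()},
            basis=str(s.get("basis", raw.get("basis", "calorie"))),
            sodium_addon_mg_per_100g=float(s.get("sodium_addon_mg_per_100g", 0.0)),
            processing_emissions=bool(s.get("processing_emissions", False)),
        )
        for s in raw.get("scenarios", [])
    )
    iron_raw = raw.get("iron_model", {})
    iron = IronModelParams(**{k: float(v) for k, v in iron_raw.items()})
    return AnalysisConfig(
        regions=tuple(str(r) for r in raw.get("regions", ["HIC"])),
        weights=weights,
        scenarios=scenarios,
        basis=str(raw.get("basis", "calorie")),
        seed=int(raw.get("seed", 0)),
        base_year=int(raw.get("base_year", 2020)),
        iron_model=iron,
    )


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    w, im = config.weights, config.iron_model
    raw = {
        "regions": list(config.regions),
        "basis": config.basis,
        "seed": config.seed,
        "base_year": config.base_year,
        "weights": {
            "health": w.health,
            "environment": w.environment,
            "cost": w.cost,
            "nutrition": w.nutrition,
            "mortality": w.mortality,
            "ghg": w.ghg,
            "land": w.land,
            "water": w.water,
        },
        "iron_model": {
            "target_absorbed_mg": im.target_absorbed_mg,
            "heme_absorption": im.heme_absorption,
            "log_intercept": im.log_intercept,
            "coef_phytate_per_mg": im.coef_phytate_per_mg,
            "coef_calcium_per_mg": im.coef_calcium_per_mg,
            "coef_vitamin_c_per_mg": im.coef_vitamin_c_per_mg,
            "coef_meat_per_g": im.coef_meat_per_g,
            "max_absorption": im.max_absorption,
        },
        "scenarios": [
            {
                "id": s.id,
                "region": s.region,
                "replace": s.replace,
                "alternatives": dict(s.alternatives),
                "basis": s.basis,
                "sodium_addon_mg_per_100g": s.sodium_addon_mg_per_100g,
                "processing_emissions": s.processing_emissions,
            }
            for s in config.scenarios
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class Bundle:
    """A complete, cross-validated input bundle for the analysis."""

    foods: dict[str, FoodProduct]
    diets: dict[str, DietaryIntake]
    recommendations: list[NutrientRecommendation]
    rr_table: pd.DataFrame
    mortality: dict[str, MortalityData]
    zinc_phytate_table: pd.DataFrame  # columns: phytate_mg, zinc_mg
    cpi: pd.DataFrame
    ppp: pd.DataFrame
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> None:
        """Referential-integrity checks across tables."""
        for diet in self.diets.values():
            missing = set(diet.intakes) - set(self.foods)
            if missing:
                raise TableError(
                    f"diet {diet.region!r} references unknown foods: {sorted(missing)}"
                )
        for scenario in self.config.scenarios:
            if scenario.region not in self.diets:
                raise TableError(f"scenario {scenario.id!r}: unknown region {scenario.region!r}")
            for category, alt in scenario.alternatives.items():
                if alt not in self.foods:
                    raise TableError(f"scenario {scenario.id!r}: unknown food id {alt!r}")
        for region in self.diets:
            if region not in self.mortality:
                raise TableError(f"no mortality data for region {region!r}")
        zp = self.zinc_phytate_table
        if list(zp.columns) != ["phytate_mg", "zinc_mg"]:
            raise TableError("zinc-phytate table must have columns phytate_mg, zinc_mg")
        if len(zp) == 0:
            raise TableError("zinc-phytate table is empty")
        if not (zp["phytate_mg"].is_monotonic_increasing and zp["zinc_mg"].is_monotonic_increasing):
            raise TableError("zinc-phytate table must be monotone increasing")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_food_table(self.foods, d / "foods.csv")
        write_diet_table(self.diets, d / "diets.csv")
        write_recommendation_table(self.recommendations, d / "recommendations.csv")
        self.rr_table.to_csv(d / "relative_risks.csv", index=False)
        pd.DataFrame(
            [
                {"region": m.region, "cause": c, "deaths": v, "population": m.population}
                for m in self.mortality.values()
                for c, v in sorted(m.deaths.items())
            ],
            columns=["region", "cause", "deaths", "population"],
        ).to_csv(d / "mortality.csv", index=False)
        self.zinc_phytate_table.to_csv(d / "zinc_phytate.csv", index=False)
        self.cpi.to_csv(d / "cpi.csv", index=False)
        self.ppp.to_csv(d / "ppp.csv", index=False)
        write_config(self.config, d / "config.yaml")

    @classmethod
    def load(cls, directory: str | Path) -> "Bundle":
        d = Path(directory)
        if not d.is_dir():
            raise FileNotFoundError(
                f"bundle directory {d} not found; generate one with the synth "
                "command or dietswap.synthetic_data.generate_bundle"
            )
        zp = _read_exact(d / "zinc_phytate.csv", ("phytate_mg", "zinc_mg"))
        bundle = cls(
            foods=read_food_table(d / "foods.csv"),
            diets=read_diet_table(d / "diets.csv"),
            recommendations=read_recommendation_table(d / "recommendations.csv"),
            rr_table=read_rr_table(d / "relative_risks.csv"),
            mortality=read_mortality_table(d / "mortality.csv"),
            zinc_phytate_table=zp,
            cpi=read_series_table(d / "cpi.csv"),
            ppp=read_series_table(d / "ppp.csv"),
            config=load_config(d / "config.yaml"),
        )
        bundle.validate()
        return bundle


def with_sodium_addon(
    foods: Mapping[str, FoodProduct], food_ids: Iterable[str], addon_mg_per_100g: float
) -> dict[str, FoodProduct]:
    """Return a food map with extra sodium added to the named foods.

    Implements the added-salt sensitivity for unprocessed alternatives.
    """
    out = dict(foods)
    for fid in food_ids:
        food = out[fid]
        amounts = dict(food.profile.amounts)
        amounts["sodium_mg"] += addon_mg_per_100g
        out[fid] = replace(food, profile=NutrientProfile(amounts))
    return out
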
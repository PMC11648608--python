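"""Comparative risk assessment for six nutritional risk factors.

Six exposures drive chronic-disease risk here: polyunsaturated fatty acids
(PUFAs), fiber, and potassium are protective; cholesterol, sodium, and heme
iron are harmful. Dose-response is log-linear — the relative risk for an
exposure shift is ``RR_unit ** (delta / increment)`` — and factors combine
multiplicatively, the standard assumptions of comparative risk assessment.
Potassium benefits saturate: exposure above 3,500 mg/day confers no further
risk reduction (the cap is applied inside the risk computation only; raw
exposures are preserved).

Population impact fractions (PIFs) translate an exposure shift into the
proportion of cause-specific deaths avoided, and attributable deaths follow
by applying PIFs to cause-specific mortality envelopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .core_tables import (
    ENDPOINTS,
    POTASSIUM_CAP_MG,
    DietaryIntake,
    FoodProduct,
    MortalityData,
    TableError,
)
from .nutrition import nutrient_intake

#: risk factor id -> nutrient column carrying its exposure
FACTOR_NUTRIENTS: dict[str, str] = {
    "pufa": "pufa_g",
    "fiber": "fiber_g",
    "potassium": "potassium_mg",
    "cholesterol": "cholesterol_mg",
    "sodium": "sodium_mg",
    "heme_iron": "heme_iron_mg",
}


@dataclass(frozen=True)
class ExposureVector:
    """Daily intake of the six risk-factor nutrients."""

    pufa_g: float
    fiber_g: float
    potassium_mg: float
    cholesterol_mg: float
    sodium_mg: float
    heme_iron_mg: float

    def __post_init__(self) -> None:
        for f in FACTOR_NUTRIENTS:
            v = getattr(self, FACTOR_NUTRIENTS[f])
            if v < 0 or not math.isfinite(v):
                raise TableError(f"exposure {f} must be finite and >= 0, got {v}")

    def value(self, factor: str) -> float:
        return getattr(self, FACTOR_NUTRIENTS[factor])

    def capped_value(self, factor: str, potassium_cap: float = POTASSIUM_CAP_MG) -> float:
        v = self.value(factor)
        if factor == "potassium" and potassium_cap is not None:
            return min(v, potassium_cap)
        return v

    @classmethod
    def zero(cls) -> "ExposureVector":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def __add__(self, other: "ExposureVector") -> "ExposureVector":
        return ExposureVector(
            *(self.value(f) + other.value(f) for f in FACTOR_NUTRIENTS)
        )


def exposure_from_diet(
    diet: DietaryIntake, foods: Mapping[str, FoodProduct]
) -> ExposureVector:
    """Risk-factor exposures of a diet (raw; the potassium cap is applied later)."""
    intakes = nutrient_intake(diet, foods)
    return ExposureVector(*(float(intakes[FACTOR_NUTRIENTS[f]]) for f in FACTOR_NUTRIENTS))


def exposure_per_serving(food: FoodProduct, servings: float = 1.0) -> ExposureVector:
    scale = food.serving_g * servings / 100.0
    return ExposureVector(
        *(food.profile[FACTOR_NUTRIENTS[f]] * scale for f in FACTOR_NUTRIENTS)
    )


def _rr_entry(rr_table: pd.DataFrame, factor: str, endpoint: str) -> tuple[float, float] | None:
    rows = rr_table[(rr_table["factor"] == factor) & (rr_table["endpoint"] == endpoint)]
    if rows.empty:
        return None
    row = rows.iloc[0]
    return float(row["rr"]), float(row["increment"])


def relative_risk_for_shift(
    factor: str,
    endpoint: str,
    delta_exposure: float,
    rr_table: pd.DataFrame,
) -> float:
    """RR multiplier for an exposure shift: ``RR_unit ** (delta / increment)``.

    ``delta_exposure`` must already reflect any exposure cap.
    """
    entry = _rr_entry(rr_table, factor, endpoint)
    if entry is None:
        raise TableError(f"no relative risk for ({factor}, {endpoint})")
    rr_unit, increment = entry
    if increment == 0:
        raise TableError(f"zero increment for ({factor}, {endpoint})")
    return rr_unit ** (delta_exposure / increment)


def rr_shift_for_endpoint(
    baseline: ExposureVector,
    scenario: ExposureVector,
    rr_table: pd.DataFrame,
    endpoint: str,
    potassium_cap: float = POTASSIUM_CAP_MG,
) -> float:
    """Combined multiplicative RR of moving from baseline to scenario exposure.

    Normalized to the baseline (baseline RR = 1), which is exact because any
    common reference exposure cancels in RR ratios under the log-linear form.
    """
    rr = 1.0
    for factor in FACTOR_NUTRIENTS:
        entry = _rr_entry(rr_table, factor, endpoint)
        if entry is None:
            continue
        delta = scenario.capped_value(factor, potassium_cap) - baseline.capped_value(
            factor, potassium_cap
        )
        rr *= relative_risk_for_shift(factor, endpoint, delta, rr_table)
    if rr <= 0 or not math.isfinite(rr):
        raise TableError(f"nonpositive combined RR for endpoint {endpoint}")
    return rr


@dataclass(frozen=True)
class PIFResult:
    endpoint: str
    pif: float
    baseline_deaths: float
    averted_deaths: float


def pif(
    baseline: ExposureVector,
    scenario: ExposureVector,
    rr_table: pd.DataFrame,
    endpoint: str,
    potassium_cap: float = POTASSIUM_CAP_MG,
) -> float:
    """Population impact fraction: proportion of cases avoided by the shift.

    PIF = (RR_base - RR_scen) / RR_base; with RRs normalized to the baseline
    exposure this reduces to 1 - RR_scen. Positive PIF means deaths averted.
    """
    rr_scen = rr_shift_for_endpoint(baseline, scenario, rr_table, endpoint, potassium_cap)
    return 1.0 - rr_scen


def attributable_deaths(
    pif_by_endpoint: Mapping[str, float], mortality: MortalityData
) -> pd.DataFrame:
    """Deaths averted per cause plus a total row with the all-cause % change.

    The mortality change (negative = reduction) is total averted deaths as a
    percentage of all-cause deaths.
    """
    missing = set(pif_by_endpoint) - set(mortality.deaths)
    if missing:
        raise TableError(f"mortality data missing endpoints: {sorted(missing)}")
    rows = []
    total_averted = 0.0
    for endpoint, p in pif_by_endpoint.items():
        averted = p * mortality.deaths[endpoint]
        total_averted += averted
        rows.append(
            {
                "cause": endpoint,
                "pif": p,
                "baseline_deaths": mortality.deaths[endpoint],
                "averted_deaths": averted,
            }
        )
    all_cause = mortality.deaths["all_cause"]
    rows.append(
        {
            "cause": "total",
            "pif": float("nan"),
            "baseline_deaths": all_cause,
            "averted_deaths": total_averted,
        }
    )
    df = pd.DataFrame(rows, columns=["cause", "pif", "baseline_deaths", "averted_deaths"])
    df.attrs["mortality_change_pct"] = -100.0 * total_averted / all_cause if all_cause else 0.0
    return df


def mortality_change_pct(
    baseline: ExposureVector,
    scenario: ExposureVector,
    rr_table: pd.DataFrame,
    mortality: MortalityData,
    potassium_cap: float = POTASSIUM_CAP_MG,
) -> float:
    """All-cause mortality change (%) for an exposure shift (negative = fewer deaths)."""
    pifs = {
        e: pif(baseline, scenario, rr_table, e, potassium_cap) for e in ENDPOINTS
    }
    return attributable_deaths(pifs, mortality).attrs["mortality_change_pct"]


def endpoint_death_shares(mortality: MortalityData) -> dict[str, float]:
    total = sum(mortality.deaths[e] for e in ENDPOINTS)
    if total <= 0:
        raise TableError("no cause-specific deaths to weight endpoints by")
    return {e: mortality.deaths[e] / total for e in ENDPOINTS}


def per_serving_risk_change(
    food: FoodProduct,
    rr_table: pd.DataFrame,
    mortality: MortalityData,
    benchmark: FoodProduct | None = None,
    context: ExposureVector | None = None,
    endpoints: Sequence[str] = ENDPOINTS,
    potassium_cap: float = POTASSIUM_CAP_MG,
) -> float:
    """Overall disease-risk change (%) from one serving of a food.

    The exposure shift is one serving of ``food``, minus one serving of
    ``benchmark`` when given (swap mode) or added on top of ``context``
    (addition mode, default context = zero). Per-endpoint RR shifts are
    combined into one number by weighting endpoints with their shares of
    cause-specific deaths in the reference region.
    """
    base = context if context is not None else ExposureVector.zero()
    scen_add = exposure_per_serving(food)
    if benchmark is not None:
        bench_add = exposure_per_serving(benchmark)
        scenario_exp = base + scen_add
        baseline_exp = base + bench_add
    else:
        scenario_exp = base + scen_add
        baseline_exp = base
    shares = endpoint_death_shares(mortality)
    total_share = sum(shares[e] for e in endpoints)
    change = 0.0
    for e in endpoints:
        rr = rr_shift_for_endpoint(baseline_exp, scenario_exp, rr_table, e, potassium_cap)
        change += shares[e] / total_share * (rr - 1.0) * 100.0
    return change


def risk_change_decomposition(
    baseline: ExposureVector,
    scenario: ExposureVector,
    rr_table: pd.DataFrame,
    mortality: MortalityData | None = None,
    potassium_cap: float = POTASSIUM_CAP_MG,
) -> pd.DataFrame:
    """Share of the total log-risk change attributable to each risk factor.

    Per factor, the log-RR shifts across endpoints are combined (weighted by
    endpoint death shares when mortality data are given, unweighted
    otherwise); shares are ``|dlogRR_f| / sum |dlogRR|`` in percent and sum
    to 100.
    """
    if mortality is not None:
        weights = endpoint_death_shares(mortality)
    else:
        weights = {e: 1.0 / len(ENDPOINTS) for e in ENDPOINTS}
    dlog: dict[str, float] = {}
    for factor in FACTOR_NUTRIENTS:
        total = 0.0
        for endpoint in ENDPOINTS:
            entry = _rr_entry(rr_table, factor, endpoint)
            if entry is None:
                continue
            delta = scenario.capped_value(factor, potassium_cap) - baseline.capped_value(
                factor, potassium_cap
            )
            rr_unit, increment = entry
            total += weights[endpoint] * math.log(rr_unit) * delta / increment
        dlog[factor] = total
    denom = sum(abs(v) for v in dlog.values())
    if denom == 0:
        raise TableError("all exposure deltas are zero; nothing to decompose")
    return pd.DataFrame(
        [
            {"factor": f, "dlog_rr": v, "share_pct": abs(v) / denom * 100.0}
            for f, v in dlog.items()
        ],
        columns=["factor", "dlog_rr", "share_pct"],
    )


def with_sodium_exposure_addon(exposure: ExposureVector, addon_mg: float) -> ExposureVector:
    """Added-salt sensitivity: extra sodium on top of a diet's exposure."""
    return replace(exposure, sodium_mg=exposure.sodium_mg + addon_mg)
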
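from __future__ import annotations

import itertools
import math

import pandas as pd
import pytest

from dietswap import health_cra as cra
from dietswap._defaults import default_rr_table
from dietswap.core_tables import DietaryIntake, MortalityData, TableError

from conftest import make_food

RR = default_rr_table()
MORT = MortalityData(
    region="X",
    deaths={"CHD": 13500.0, "stroke": 7000.0, "cancer": 25000.0, "all_cause": 90000.0},
    population=1e7,
)


def vec(**kw) -> cra.ExposureVector:
    base = dict(pufa_g=0.0, fiber_g=0.0, potassium_mg=0.0, cholesterol_mg=0.0,
                sodium_mg=0.0, heme_iron_mg=0.0)
    base.update(kw)
    return cra.ExposureVector(**base)


class TestExposure:
    def test_empty_diet_zero_vector(self):
        assert cra.exposure_from_diet(DietaryIntake("r", {}), {}) == cra.ExposureVector.zero()

    def test_exposure_matches_hand_sum(self):
        foods = {"f": make_food("f", nutrients={"fiber_g": 4.0, "sodium_mg": 50.0})}
        exp = cra.exposure_from_diet(DietaryIntake("r", {"f": 200.0}), foods)
        assert exp.fiber_g == pytest.approx(8.0)
        assert exp.sodium_mg == pytest.approx(100.0)

    @pytest.mark.parametrize("raw,effective", [(4000.0, 3500.0), (3000.0, 3000.0)])
    def test_potassium_cap_inside_risk_only(self, raw, effective):
        v = vec(potassium_mg=raw)
        assert v.capped_value("potassium") == effective
        assert v.potassium_mg == raw  # raw exposure retained

    def test_negative_exposure_rejected(self):
        with pytest.raises(TableError):
            vec(fiber_g=-1.0)


class TestRelativeRiskForShift:
    def test_zero_delta_is_unity(self):
        assert cra.relative_risk_for_shift("sodium", "CHD", 0.0, RR) == 1.0

    def test_one_increment(self):
        table = pd.DataFrame(
            [("sodium", "CHD", 1.2, 50.0, "mg/day")],
            columns=["factor", "endpoint", "rr", "increment", "unit"],
        )
        assert cra.relative_risk_for_shift("sodium", "CHD", 50.0, table) == pytest.approx(1.2)
        assert cra.relative_risk_for_shift("sodium", "CHD", 25.0, table) == pytest.approx(
            1.2 ** 0.5
        )

    def test_missing_entry_raises(self):
        with pytest.raises(TableError, match="no relative risk"):
            cra.relative_risk_for_shift("pufa", "cancer", 1.0, RR)


class TestPIF:
    def test_identical_exposures_zero(self):
        v = vec(fiber_g=20.0, sodium_mg=3000.0)
        for endpoint in ("CHD", "stroke", "cancer"):
            assert cra.pif(v, v, RR, endpoint) == 0.0

    def test_single_factor_closed_form(self):
        """Baseline one increment above the reference of a harmful factor with
        RR 1.2: PIF of returning to reference is 0.2/1.2."""
        table = pd.DataFrame(
            [("sodium", "CHD", 1.2, 1000.0, "mg/day")],
            columns=["factor", "endpoint", "rr", "increment", "unit"],
        )
        p = cra.pif(vec(sodium_mg=1000.0), vec(sodium_mg=0.0), table, "CHD")
        assert p == pytest.approx(0.2 / 1.2)

    def test_potassium_benefit_saturates(self):
        base = vec(potassium_mg=2000.0)
        at_cap = vec(potassium_mg=3500.0)
        beyond = vec(potassium_mg=6000.0)
        for endpoint in ("CHD", "stroke"):
            assert cra.pif(base, at_cap, RR, endpoint) == pytest.approx(
                cra.pif(base, beyond, RR, endpoint)
            )

    def test_pif_monotone_in_protective_exposure(self):
        base = vec(fiber_g=10.0)
        pifs = [cra.pif(base, vec(fiber_g=f), RR, "CHD") for f in (10, 15, 20, 30)]
        assert all(a < b for a, b in zip(pifs, pifs[1:]))

    def test_multifactor_pif_matches_brute_force_oracle(self):
        """PIF from the package equals an independent recomputation that
        normalizes both exposures against an arbitrary common reference,
        over a 2-factor exposure grid."""
        table = pd.DataFrame(
            [
                ("fiber", "CHD", 0.9, 10.0, "g/day"),
                ("sodium", "CHD", 1.1, 1000.0, "mg/day"),
            ],
            columns=["factor", "endpoint", "rr", "increment", "unit"],
        )
        ref = {"fiber_g": 5.0, "sodium_mg": 500.0}  # arbitrary reference

        def rr_vs_ref(v: cra.ExposureVector) -> float:
            return (0.9 ** ((v.fiber_g - ref["fiber_g"]) / 10.0)) * (
                1.1 ** ((v.sodium_mg - ref["sodium_mg"]) / 1000.0)
            )

        grid = list(itertools.product([0.0, 10.0, 25.0], [0.0, 2000.0, 4000.0]))
        for (fb, sb), (fs, ss) in itertools.product(grid, grid):
            base, scen = vec(fiber_g=fb, sodium_mg=sb), vec(fiber_g=fs, sodium_mg=ss)
            expected = (rr_vs_ref(base) - rr_vs_ref(scen)) / rr_vs_ref(base)
            assert cra.pif(base, scen, table, "CHD") == pytest.approx(expected, abs=1e-12)


class TestAttributableDeaths:
    def test_simple_arithmetic(self):
        mort = MortalityData("X", {"CHD": 1000.0, "stroke": 0.0, "cancer": 0.0,
                                   "all_cause": 5000.0}, 1e6)
        df = cra.attributable_deaths({"CHD": 0.1}, mort)
        assert df.set_index("cause").loc["CHD", "averted_deaths"] == pytest.approx(100.0)
        assert df.attrs["mortality_change_pct"] == pytest.approx(-2.0)

    def test_zero_pifs_zero_change(self):
        df = cra.attributable_deaths({e: 0.0 for e in ("CHD", "stroke", "cancer")}, MORT)
        assert df.attrs["mortality_change_pct"] == 0.0

    def test_two_cause_toy_matches_hand_computation(self):
        mort = MortalityData("X", {"CHD": 2000.0, "stroke": 1000.0, "cancer": 0.0,
                                   "all_cause": 10000.0}, 1e6)
        df = cra.attributable_deaths({"CHD": 0.05, "stroke": 0.2}, mort)
        total = 0.05 * 2000 + 0.2 * 1000
        assert df.set_index("cause").loc["total", "averted_deaths"] == pytest.approx(total)
        assert df.attrs["mortality_change_pct"] == pytest.approx(-100 * total / 10000)

    def test_missing_endpoint_raises(self):
        mort = MortalityData("X", {"CHD": 1.0, "stroke": 1.0, "cancer": 1.0,
                                   "all_cause": 10.0}, 1e6)
        with pytest.raises(TableError, match="missing endpoints"):
            cra.attributable_deaths({"diabetes": 0.1}, mort)

    def test_averted_conserves_against_fixed_reference(self):
        """averted = baseline-attributable - scenario-attributable for any
        fixed reference exposure."""
        ref = vec()
        base = vec(fiber_g=10.0, sodium_mg=3000.0, heme_iron_mg=2.0)
        scen = vec(fiber_g=25.0, sodium_mg=2000.0, heme_iron_mg=0.5)
        for endpoint in ("CHD", "stroke", "cancer"):
            deaths = MORT.deaths[endpoint]
            rr_b = cra.rr_shift_for_endpoint(ref, base, RR, endpoint)
            rr_s = cra.rr_shift_for_endpoint(ref, scen, RR, endpoint)
            attrib_b = deaths * (rr_b - 1) / rr_b
            attrib_s = deaths / rr_b * (rr_s - 1)
            averted = cra.pif(base, scen, RR, endpoint) * deaths
            assert averted == pytest.approx(attrib_b - attrib_s, rel=1e-12)


class TestPerServingRiskChange:
    def test_food_identical_to_comparator_is_zero(self):
        f = make_food("f", nutrients={"fiber_g": 3.0, "sodium_mg": 100.0})
        assert cra.per_serving_risk_change(f, RR, MORT, benchmark=f) == pytest.approx(0.0)

    def test_fiber_only_food_reduces_risk(self):
        f = make_food("f", nutrients={"fiber_g": 5.0})
        assert cra.per_serving_risk_change(f, RR, MORT) < 0.0

    def test_single_endpoint_reduces_to_rr_minus_one(self):
        f = make_food("f", nutrients={"sodium_mg": 500.0})
        change = cra.per_serving_risk_change(f, RR, MORT, endpoints=("CHD",))
        rr = cra.relative_risk_for_shift("sodium", "CHD", 500.0, RR)
        assert change == pytest.approx((rr - 1) * 100.0)


class TestDecomposition:
    def test_single_active_factor_full_share(self):
        dec = cra.risk_change_decomposition(vec(), vec(fiber_g=10.0), RR)
        shares = dec.set_index("factor")["share_pct"]
        assert shares["fiber"] == pytest.approx(100.0)

    def test_equal_log_shifts_split_evenly(self):
        table = pd.DataFrame(
            [
                ("fiber", "CHD", 0.9, 10.0, "g/day"),
                ("sodium", "CHD", 1 / 0.9, 1000.0, "mg/day"),
            ],
            columns=["factor", "endpoint", "rr", "increment", "unit"],
        )
        dec = cra.risk_change_decomposition(
            vec(), vec(fiber_g=10.0, sodium_mg=1000.0), table
        )
        shares = dec.set_index("factor")["share_pct"]
        assert shares["fiber"] == pytest.approx(50.0)
        assert shares["sodium"] == pytest.approx(50.0)

    def test_three_factor_toy_matches_direct_log_rr(self):
        base = vec(fiber_g=10.0, sodium_mg=3000.0, heme_iron_mg=2.0)
        scen = vec(fiber_g=30.0, sodium_mg=2000.0, heme_iron_mg=0.5)
        dec = cra.risk_change_decomposition(base, scen, RR, mortality=MORT)
        shares = cra.endpoint_death_shares(MORT)
        expected = {}
        for factor, nutrient in (("fiber", "fiber_g"), ("sodium", "sodium_mg"),
                                 ("heme_iron", "heme_iron_mg")):
            total = 0.0
            for endpoint in ("CHD", "stroke", "cancer"):
                rows = RR[(RR["factor"] == factor) & (RR["endpoint"] == endpoint)]
                if rows.empty:
                    continue
                delta = getattr(scen, nutrient) - getattr(base, nutrient)
                total += shares[endpoint] * math.log(rows["rr"].iloc[0]) * delta / rows[
                    "increment"
                ].iloc[0]
            expected[factor] = total
        denom = sum(abs(v) for v in expected.values())
        got = dec.set_index("factor")["share_pct"]
        for factor, v in expected.items():
            assert got[factor] == pytest.approx(abs(v) / denom * 100.0)
        assert got.sum() == pytest.approx(100.0)

    def test_all_zero_deltas_rejected(self):
        with pytest.raises(TableError, match="zero"):
            cra.risk_change_decomposition(vec(), vec(), RR)
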
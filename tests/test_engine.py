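"""Costing engine: unit examples frozen from the published tables, plus
the engine's structural properties (ledger equivalence, linearity,
conservation, monotonicity, scale invariance)."""

from dataclasses import replace
from fractions import Fraction

import pytest

from tdabc import (
    CapitalItem,
    Horizon,
    PurchasedService,
    RecurringCost,
    Resource,
    Scenario,
    WorkflowStep,
    annual_operational_cost,
    annualized_capital,
    annualized_recurring,
    capacity_cost_rate,
    capital_charge,
    cost_breakdown,
    report_to_csv,
    report_to_json_dict,
    round_half_up,
    step_cost_per_patient,
    total_horizon_cost,
)
from conftest import ledger_oracle, random_scenario


class TestCapacityCostRate:
    def test_zero_salary_gives_zero_rate(self):
        assert capacity_cost_rate(Resource("r", 0, 100_000)) == 0

    def test_salary_division(self):
        assert capacity_cost_rate(Resource("r", 60_000, 96_000)) == Fraction(5, 8)

    def test_override_wins(self):
        rate = Fraction(7_236, 300 * 56)
        r = Resource("rtt", annual_salary_cost=99, annual_working_time=1,
                     ccr_override=rate)
        assert capacity_cost_rate(r) == rate

    def test_zero_working_time_without_override_raises(self):
        with pytest.raises(ZeroDivisionError):
            capacity_cost_rate(Resource("r", 50_000, 0))


class TestStepCost:
    def test_timed_step_from_table_rate(self, mri_only):
        acq = mri_only.steps[0]
        cost = step_cost_per_patient(acq, mri_only)
        assert cost == Fraction(7_236, 300)  # 24.12/patient -> 7,236/y at 300
        assert 300 * cost == 7_236

    def test_registration_step(self, ct_mri_320):
        reg = next(s for s in ct_mri_320.steps if "registration" in s.name)
        assert 300 * step_cost_per_patient(reg, ct_mri_320) == 735
        assert step_cost_per_patient(reg, ct_mri_320) == Fraction(245, 100)

    def test_zero_duration_step(self):
        s = Scenario("s", resources=(Resource("r", ccr_override=5),),
                     steps=(WorkflowStep("noop", resource="r", mean_duration=0),))
        assert step_cost_per_patient(s.steps[0], s) == 0

    def test_direct_cost_override(self):
        s = Scenario("s", steps=(WorkflowStep("buy", direct_cost_override=320),))
        assert step_cost_per_patient(s.steps[0], s) == 320


class TestAnnualization:
    def test_scanner_writeoff(self):
        item = CapitalItem("MRI", purchase_cost=1_409_513, writeoff_years=10)
        assert annualized_capital(item) == Fraction(1_409_513, 10)
        per_patient = annualized_capital(item) / 300
        assert round_half_up(per_patient) == 470

    def test_renovation_writeoff(self):
        item = CapitalItem("room", purchase_cost=200_000, writeoff_years=10)
        assert round_half_up(annualized_capital(item) / 300) == 67

    def test_zero_purchase(self):
        assert annualized_capital(CapitalItem("x", 0, 10)) == 0

    @pytest.mark.parametrize("writeoff, horizon, expected_fraction", [
        (10, 10, 1),
        (20, 10, Fraction(1, 2)),   # horizon shorter than write-off: pro rata
        (5, 10, 1),                 # fully written off inside the horizon
    ])
    def test_capital_charge_vs_horizon(self, writeoff, horizon, expected_fraction):
        item = CapitalItem("x", purchase_cost=1_000, writeoff_years=writeoff)
        assert capital_charge(item, Fraction(horizon)) == 1_000 * expected_fraction

    def test_allocation_fraction_scales_charge(self):
        item = CapitalItem("shared scanner", purchase_cost=1_000, writeoff_years=10,
                           allocation_fraction=Fraction(1, 4))
        assert capital_charge(item, Fraction(10)) == 250

    def test_tube_replacement_interval(self):
        tube = RecurringCost("tube", amount=97_500, interval_years=3)
        assert annualized_recurring(tube, 300) == 32_500
        assert round_half_up(Fraction(32_500, 300)) == 108

    def test_coil_replacement_annual(self):
        coil = RecurringCost("coil", amount=25_000, interval_years=1)
        assert annualized_recurring(coil, 300) == 25_000
        assert round_half_up(Fraction(25_000, 300)) == 83

    def test_per_patient_recurring_at_zero_volume(self):
        rc = RecurringCost("kit", amount=42, scaling="per_patient")
        assert annualized_recurring(rc, Fraction(0)) == 0


class TestOperationalAndTotals:
    def test_annual_operational_mri_only(self, mri_only):
        assert annual_operational_cost(mri_only, 300) == 109_869

    def test_annual_operational_ct_mri(self, ct_mri_320):
        assert annual_operational_cost(ct_mri_320, 300) == 217_689

    def test_mri_only_totals(self, mri_only, horizon):
        r = total_horizon_cost(mri_only, horizon)
        assert r.total_horizon_cost == 2_708_203
        assert r.capital_total == 1_609_513
        assert r.operational_total == 1_098_690
        assert r.per_patient_total == Fraction(2_708_203, 3_000)
        assert round_half_up(r.per_patient_total) == 903

    def test_ct_mri_totals(self, ct_mri_320, horizon):
        r = total_horizon_cost(ct_mri_320, horizon)
        assert r.total_horizon_cost == 2_766_747
        assert round_half_up(r.per_patient_total) == 922

    def test_report_identities(self, ct_mri_320, horizon):
        r = total_horizon_cost(ct_mri_320, horizon)
        assert r.capital_total + r.operational_total == r.total_horizon_cost
        assert r.per_patient_total * horizon.annual_patients * horizon.years \
            == r.total_horizon_cost
        assert sum(r.per_patient_by_component.values()) == r.per_patient_total
        assert r.personnel_share + r.equipment_share + r.services_share == 1

    def test_zero_patients_flagged(self, mri_only):
        r = total_horizon_cost(mri_only, Horizon(years=10, annual_patients=0))
        assert not r.per_patient_defined
        assert r.per_patient_total is None
        # fixed costs still accrue
        assert r.total_horizon_cost == 1_609_513 + 10 * (71_603 + 25_000)


class TestBreakdown:
    def test_capital_vs_operational_mri_only(self, mri_only, horizon):
        r = total_horizon_cost(mri_only, horizon)
        b = cost_breakdown(r, "capital_vs_operational")
        assert round_half_up(b["capital"]["per_patient"]) == 537
        assert round_half_up(b["operational"]["per_patient"]) == 366
        assert round(float(b["capital"]["share"]) * 100, 1) == 59.4
        assert round(float(b["operational"]["share"]) * 100, 1) == 40.6

    def test_personnel_vs_equipment_mri_only(self, mri_only, horizon):
        r = total_horizon_cost(mri_only, horizon)
        b = cost_breakdown(r, "personnel_vs_equipment")
        assert b["personnel"]["per_patient"] == Fraction(13_266, 300)  # 44.22
        assert round_half_up(b["personnel"]["per_patient"]) == 44
        assert round_half_up(b["space_equipment"]["per_patient"]) == 859
        assert round(float(b["personnel"]["share"]) * 100, 1) == 4.9
        assert round(float(b["space_equipment"]["share"]) * 100, 1) == 95.1

    def test_personnel_vs_equipment_ct_mri(self, ct_mri_320, horizon):
        r = total_horizon_cost(ct_mri_320, horizon)
        b = cost_breakdown(r, "personnel_vs_equipment")
        assert b["personnel"]["per_patient"] == Fraction(8_775, 300)  # 29.25
        assert round(float(b["personnel"]["share"]) * 100, 1) == 3.2
        # summed-before-rounding: cells print 173+23+268+108 = 572 but the
        # exact partition sum prints 573
        assert round_half_up(b["space_equipment"]["per_patient"]) == 573
        assert round_half_up(b["external_services"]["per_patient"]) == 320

    def test_single_component_is_whole(self):
        s = Scenario("solo", services=(PurchasedService("svc", unit_price=10),))
        r = total_horizon_cost(s, Horizon(years=2, annual_patients=5))
        b = cost_breakdown(r, "personnel_vs_equipment")
        assert b["external_services"]["share"] == 1
        assert b["personnel"]["share"] == 0

    def test_zero_total_flagged(self):
        r = total_horizon_cost(Scenario("empty"), Horizon(years=1, annual_patients=0))
        b = cost_breakdown(r, "capital_vs_operational")
        assert b["capital"]["share"] is None

    def test_unknown_partition_rejected(self, mri_only, horizon):
        with pytest.raises(ValueError):
            cost_breakdown(total_horizon_cost(mri_only, horizon), "nope")


class TestProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_ledger_oracle_equivalence(self, seed):
        scenario, _ = random_scenario(seed)
        h = Horizon(years=4 + seed % 5, annual_patients=seed % 37)
        engine = total_horizon_cost(scenario, h).total_horizon_cost
        assert abs(engine - ledger_oracle(scenario, h)) <= Fraction(1, 10**6)

    @pytest.mark.parametrize("seed", range(10))
    def test_linearity_in_volume(self, seed):
        """Totals at three volumes are collinear: affine in n."""
        scenario, _ = random_scenario(seed + 100)
        years = Fraction(7)
        t = [total_horizon_cost(scenario, Horizon(years, Fraction(n))).total_horizon_cost
             for n in (10, 20, 30)]
        assert t[2] - t[1] == t[1] - t[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_component_conservation(self, seed):
        scenario, _ = random_scenario(seed + 200)
        r = total_horizon_cost(scenario, Horizon(Fraction(6), Fraction(17)))
        assert sum(c.horizon_cost for c in r.components) == r.total_horizon_cost
        assert sum(r.per_patient_by_component.values()) == r.per_patient_total

    def test_monotonic_in_volume_years_and_unit_costs(self, ct_mri_320):
        base = total_horizon_cost(ct_mri_320, Horizon(10, 300)).total_horizon_cost
        more_patients = total_horizon_cost(ct_mri_320, Horizon(10, 400)).total_horizon_cost
        more_years = total_horizon_cost(ct_mri_320, Horizon(12, 300)).total_horizon_cost
        assert more_patients >= base and more_years >= base
        pricier = replace(ct_mri_320, services=(
            replace(ct_mri_320.services[0], unit_price=400),))
        assert total_horizon_cost(pricier, Horizon(10, 300)).total_horizon_cost >= base

    @pytest.mark.parametrize("k", [Fraction(2), Fraction(1, 3), Fraction(17, 5)])
    def test_scale_invariance_in_currency(self, mri_only, horizon, k):
        scaled = replace(
            mri_only,
            resources=tuple(replace(r, ccr_override=r.ccr_override * k)
                            for r in mri_only.resources),
            capital_items=tuple(replace(c, purchase_cost=c.purchase_cost * k)
                                for c in mri_only.capital_items),
            recurring_costs=tuple(replace(rc, amount=rc.amount * k)
                                  for rc in mri_only.recurring_costs),
        )
        base = total_horizon_cost(mri_only, horizon)
        scaled_report = total_horizon_cost(scaled, horizon)
        assert scaled_report.total_horizon_cost == k * base.total_horizon_cost
        assert scaled_report.per_patient_total == k * base.per_patient_total


class TestSerialization:
    def test_csv_reparses_to_full_precision(self, mri_only, horizon):
        import io
        import pandas as pd
        r = total_horizon_cost(mri_only, horizon)
        df = pd.read_csv(io.StringIO(report_to_csv(r)))
        assert len(df) == len(r.components)
        for row, comp in zip(df.itertuples(), r.components):
            assert row.horizon_cost == float(comp.horizon_cost)

    def test_json_mirrors_report(self, ct_mri_320, horizon):
        r = total_horizon_cost(ct_mri_320, horizon)
        d = report_to_json_dict(r)
        assert d["total_horizon_cost"] == float(r.total_horizon_cost)
        assert d["per_patient_total"] == float(r.per_patient_total)
        assert {c["name"] for c in d["components"]} == {c.name for c in r.components}
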
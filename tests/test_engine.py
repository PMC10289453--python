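"""Costing engine: line items, amortization, staffing, denominators,
aggregation partitions and the control-arm subset."""

import math

import pytest

import microcost as mc
from microcost.engine import DEFAULT_STAFFING_RATIO, DivisionGuardError
from microcost.ledger import ValidationError, table5_block_ledger, table5_package_ledger
from microcost.synthgen import GeneratorParams, generate_ledger

from conftest import make_item, make_ledger


class TestLineItemCost:
    def test_price_times_units_kenya_manual_printing(self):
        item = make_item(price=6.0, qty=341.0)
        assert mc.line_item_cost(item) == pytest.approx(2046.0)

    def test_price_times_units_uganda_checklist_printing(self):
        item = make_item(price=15.0, qty=507.0)
        assert mc.line_item_cost(item) == pytest.approx(7605.0)

    def test_zero_proration_annihilates(self):
        assert mc.line_item_cost(make_item(proration=0.0)) == 0.0

    def test_capital_item_routes_through_amortization(self):
        asset = mc.CapitalAsset(3.0, mc.AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT)
        item = make_item(
            price=998.0, qty=1.0, category=mc.InputCategory.CAPITAL, capital_spec=asset
        )
        plan = mc.ImplementationPlan(9, 15, 24)  # 48-month program, 3y life
        assert mc.line_item_cost(item, plan=plan) == pytest.approx(2 * 998.0)


class TestAmortization:
    plan36 = mc.ImplementationPlan(9, 15, 12)

    def test_point_purchase_single_acquisition_when_life_covers_horizon(self):
        asset = mc.CapitalAsset(3.0, mc.AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT)
        assert mc.amortization_units(asset, self.plan36) == 1

    def test_point_purchase_replacement_by_ceiling(self):
        asset = mc.CapitalAsset(3.0, mc.AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT)
        plan48 = mc.ImplementationPlan(9, 15, 24)
        assert mc.amortization_units(asset, plan48) == math.ceil(48 / 36)

    def test_straight_line_fractional_consumption(self):
        asset = mc.CapitalAsset(4.0, mc.AcquisitionMode.STRAIGHT_LINE_ANNUALIZED)
        assert mc.amortization_units(asset, self.plan36) == pytest.approx(0.75)


class TestStaffing:
    def _facs(self, n, size):
        return [
            mc.FacilityProfile(f"F{i}", mc.Country.KE, 50, size_class=size)
            for i in range(n)
        ]

    def test_minimum_one_specialist(self):
        assert mc.staffing_requirement(self._facs(1, mc.SizeClass.SMALL)) == 1

    def test_seventeen_small_facilities_need_two(self):
        assert mc.staffing_requirement(self._facs(17, mc.SizeClass.SMALL)) == 2

    def test_six_large_facilities_need_two(self):
        assert mc.staffing_requirement(self._facs(6, mc.SizeClass.LARGE)) == 2

    def test_mixed_caseload_combines_fractionally(self):
        facs = self._facs(8, mc.SizeClass.SMALL) + self._facs(4, mc.SizeClass.LARGE)
        small_per, large_per = DEFAULT_STAFFING_RATIO
        assert mc.staffing_requirement(facs) == math.ceil(8 / small_per + 4 / large_per)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            mc.staffing_requirement([])


class TestBirthsDenominator:
    def test_single_facility_default_plan(self):
        fac = [mc.FacilityProfile("F1", mc.Country.KE, 100)]
        assert mc.births_denominator(fac) == 2700

    def test_additivity(self):
        fac = [
            mc.FacilityProfile("F1", mc.Country.KE, 50),
            mc.FacilityProfile("F2", mc.Country.KE, 150),
        ]
        assert mc.births_denominator(fac) == 5400

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_facility_loop_oracle(self, seed):
        facs = generate_ledger(GeneratorParams(seed=seed)).facilities
        plan = mc.ImplementationPlan()
        expected = 0
        for f in facs:
            expected += f.monthly_deliveries * (plan.phase2_months + plan.phase3_months)
        assert mc.births_denominator(facs, plan) == expected


class TestAggregate:
    def test_empty_ledger_gives_zero_report(self):
        rep = mc.aggregate_costs(make_ledger([]))
        assert rep.total_usd_2020 == 0.0
        assert rep.per_birth == 0.0 and rep.per_facility == 0.0

    def test_zero_facilities_guarded(self):
        led = make_ledger([make_item()])
        led.facilities = []
        with pytest.raises(DivisionGuardError):
            mc.aggregate_costs(led)

    def test_partition_consistency(self, simple_ledger):
        rep = mc.aggregate_costs(simple_ledger)
        for part in (rep.by_phase, rep.by_component, rep.by_input_category):
            assert sum(part.values()) == pytest.approx(rep.total_usd_2020, rel=1e-9)

    def test_per_facility_times_count_recovers_total(self, simple_ledger):
        rep = mc.aggregate_costs(simple_ledger)
        assert rep.per_facility * rep.n_facilities == pytest.approx(rep.total_usd_2020)

    def test_homogeneity_under_price_scaling(self):
        led = generate_ledger(GeneratorParams(seed=7))
        rep = mc.aggregate_costs(led)
        scaled = led.copy()
        for it in scaled.items:
            it.unit_price = mc.MoneyAmount(
                it.unit_price.value * 3.0, normalized=True
            )
        rep3 = mc.aggregate_costs(scaled)
        assert rep3.total_usd_2020 == pytest.approx(3.0 * rep.total_usd_2020)
        assert rep3.per_birth == pytest.approx(3.0 * rep.per_birth)
        assert rep3.per_facility == pytest.approx(3.0 * rep.per_facility)
        assert rep3.component_shares_pct == rep.component_shares_pct

    def test_adding_a_facility_decreases_per_birth(self):
        items = [make_item()]
        one = make_ledger(items)
        two = make_ledger(
            items,
            facilities=[
                mc.FacilityProfile("F1", mc.Country.KE, 100),
                mc.FacilityProfile("F2", mc.Country.KE, 100),
            ],
        )
        assert mc.aggregate_costs(two).per_birth < mc.aggregate_costs(one).per_birth

    def test_additivity_vs_naive_sum_oracle(self):
        led = generate_ledger(GeneratorParams(seed=11))
        naive = sum(mc.line_item_cost(it, plan=led.config.plan) for it in led.items)
        assert mc.aggregate_costs(led).total_usd_2020 == pytest.approx(naive, rel=1e-12)


class TestPublishedSummaries:
    def test_moh_model_per_facility_division(self):
        ke = mc.aggregate_costs(table5_package_ledger(mc.Scenario.MOH_MODEL, mc.Country.KE))
        ug = mc.aggregate_costs(table5_package_ledger(mc.Scenario.MOH_MODEL, mc.Country.UG))
        assert mc.round_half_up(ke.per_facility) == 50497
        assert mc.round_half_up(ug.per_facility) == 46871

    def test_component_shares_match_published_percentages(self):
        rep = mc.aggregate_costs(table5_block_ledger(mc.Scenario.MOH_MODEL, mc.Country.KE, "component"))
        shares = {c.value: v for c, v in rep.component_shares_pct.items()}
        assert shares == {"GENERAL": 24, "DS": 10, "MSCC": 5, "PRONTO": 44, "QI": 17}
        rep = mc.aggregate_costs(table5_block_ledger(mc.Scenario.MOH_MODEL, mc.Country.UG, "component"))
        shares = {c.value: v for c, v in rep.component_shares_pct.items()}
        assert shares == {"GENERAL": 27, "DS": 10, "MSCC": 7, "PRONTO": 44, "QI": 13}

    def test_single_component_ledger_share_is_100(self):
        rep = mc.aggregate_costs(make_ledger([make_item(component=mc.Component.PRONTO)]))
        assert rep.component_shares_pct[mc.Component.PRONTO] == 100


class TestControlFilter:
    def test_pronto_only_ledger_gives_empty_control(self):
        led = make_ledger([make_item(component=mc.Component.PRONTO)])
        assert mc.control_filter(led).items == []

    def test_control_total_bounded_by_package_total(self, simple_ledger):
        package = mc.aggregate_costs(simple_ledger).total_usd_2020
        control = mc.aggregate_costs(mc.control_filter(simple_ledger)).total_usd_2020
        assert control <= package

    def test_shared_item_retained_at_control_proration(self):
        it = make_item(
            "g", price=100.0, qty=1.0, component=mc.Component.GENERAL,
            control_pertinent=True, meta={"control_proration": 0.5},
        )
        led = make_ledger([it, make_item("p", component=mc.Component.PRONTO)])
        ctrl = mc.control_filter(led)
        assert [i.item_id for i in ctrl.items] == ["g"]
        assert mc.line_item_cost(ctrl.items[0]) == pytest.approx(50.0)

    def test_unflagged_shared_items_are_dropped(self):
        it = make_item("g", component=mc.Component.GENERAL, control_pertinent=False)
        assert mc.control_filter(make_ledger([it])).items == []
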
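"""One-way sensitivity framework: perturbation semantics, percent
differences, and independence of perturbations."""

import math

import pytest

import microcost as mc
from microcost.ledger import ValidationError, table7_fixture
from microcost.sensitivity import Perturbation, PerturbationKind
from microcost.synthgen import GeneratorParams, generate_ledger

from conftest import make_item, make_ledger


@pytest.fixture(scope="module")
def ke_ledger():
    return generate_ledger(GeneratorParams(seed=5, country=mc.Country.KE))


@pytest.fixture(scope="module")
def ug_ledger():
    return generate_ledger(GeneratorParams(seed=5, country=mc.Country.UG))


class TestPercentDifference:
    @pytest.mark.parametrize(
        "base,alt,expected",
        [
            (23.91, 10.76, -55),
            (5.47, 6.68, 22),
            (23.91, 24.92, 4),
            (5.47, 6.02, 10),
            (10.0, 10.0, 0),
        ],
    )
    def test_signed_integer_percent(self, base, alt, expected):
        assert mc.percent_difference(base, alt) == expected

    def test_zero_base_rejected(self):
        with pytest.raises(ValidationError):
            mc.percent_difference(0.0, 5.0)


class TestTable7Reconstruction:
    def test_printed_pairs_reproduce_printed_percentages(self):
        """Every published base/alternative per-birth pair maps back to its
        published percent difference, except the Uganda facility-mix row."""
        df = table7_fixture()
        checked = 0
        for _, row in df.iterrows():
            for prefix in ("ke", "ug"):
                base, alt, printed = (
                    row[f"{prefix}_base"], row[f"{prefix}_alt"], row[f"{prefix}_pct_printed"]
                )
                if math.isnan(base):
                    continue
                if row["row"] == "facility_mix_ug" and prefix == "ug":
                    continue  # known documented discrepancy, asserted below
                assert mc.percent_difference(float(base), float(alt)) == int(printed), (
                    row["row"], prefix,
                )
                checked += 1
        assert checked == 9

    def test_uganda_facility_mix_known_difference(self):
        """The published +49% differs from the recomputed value: the printed
        dollar pair (5.47 -> 8.11) yields +48%."""
        assert mc.percent_difference(5.47, 8.11) == 48

    def test_study_scenario_kenya_per_facility_known_difference(self):
        """Dividing the printed study-scenario Kenya total by its 9 sites
        rounds to $123,230, one dollar above the printed $123,229 (the
        publication evidently divided an unrounded total)."""
        from microcost.ledger import table5_package_ledger
        rep = mc.aggregate_costs(
            table5_package_ledger(mc.Scenario.STUDY_OBSERVED, mc.Country.KE)
        )
        assert mc.round_half_up(rep.per_facility) == 123230 == 123229 + 1


class TestPerturbations:
    def test_base_ledger_never_modified(self, ke_ledger):
        before = mc.aggregate_costs(ke_ledger).total_usd_2020
        for kind in (
            PerturbationKind.NM_TRAVELLING,
            PerturbationKind.ADAPTATION_2X,
            PerturbationKind.MAINTENANCE_HIGH,
            PerturbationKind.EXCLUDE_FACILITY_WORKER_TIME,
        ):
            mc.apply_perturbation(ke_ledger, Perturbation(kind.value, kind))
        assert mc.aggregate_costs(ke_ledger).total_usd_2020 == before

    def test_adaptation_doubles_planning_adaptation_subtotal(self, ke_ledger):
        def subtotal(led):
            return sum(
                mc.line_item_cost(it, plan=led.config.plan)
                for it in led.items
                if it.has_tag("adaptation") and it.phase is mc.Phase.P1_PLANNING
            )

        alt = mc.apply_perturbation(
            ke_ledger, Perturbation("a2x", PerturbationKind.ADAPTATION_2X)
        )
        assert subtotal(alt) == pytest.approx(2.0 * subtotal(ke_ledger), rel=1e-12)

    def test_adaptation_falls_back_to_whole_planning_phase(self):
        items = [
            make_item("p1", price=10, qty=5, phase=mc.Phase.P1_PLANNING),
            make_item("p2", price=10, qty=5, phase=mc.Phase.P2_IMPLEMENTATION),
        ]
        led = make_ledger(items)
        alt = mc.apply_perturbation(led, Perturbation("a2x", PerturbationKind.ADAPTATION_2X))
        qty = {it.item_id: it.quantity for it in alt.items}
        assert qty == {"p1": 10, "p2": 5}

    def test_maintenance_high_doubles_p3_training_subtotal(self, ke_ledger):
        def subtotal(led):
            return sum(
                mc.line_item_cost(it, plan=led.config.plan)
                for it in led.items
                if it.phase is mc.Phase.P3_MAINTENANCE
                and it.component in (mc.Component.PRONTO, mc.Component.QI)
            )

        alt = mc.apply_perturbation(
            ke_ledger, Perturbation("mh", PerturbationKind.MAINTENANCE_HIGH)
        )
        assert subtotal(alt) == pytest.approx(2.0 * subtotal(ke_ledger), rel=1e-12)

    def test_nm_travelling_adds_one_to_two_mentors_for_six_facilities(self, ug_ledger):
        alt = mc.apply_perturbation(
            ug_ledger, Perturbation("nm", PerturbationKind.NM_TRAVELLING)
        )
        assert not any(it.has_tag("nm_embedded") for it in alt.items)
        salary_rows = [it for it in alt.items if it.item_id.startswith("nm-travelling-salary")]
        plan = alt.config.plan
        n_nm = salary_rows[0].quantity / plan.phase2_months
        assert 1 <= n_nm <= 2
        # mentor-training rows survive the swap
        assert any(it.has_tag("nm_training") for it in alt.items)

    def test_exclude_worker_time_is_noop_without_facility_personnel(self):
        led = make_ledger([make_item("x", category=mc.InputCategory.CONSUMABLES)])
        alt = mc.apply_perturbation(
            led, Perturbation("ex", PerturbationKind.EXCLUDE_FACILITY_WORKER_TIME)
        )
        assert [it.item_id for it in alt.items] == ["x"]

    def test_exclude_worker_time_never_increases_per_birth(self, ke_ledger, ug_ledger):
        for led in (ke_ledger, ug_ledger):
            base = mc.aggregate_costs(led).per_birth
            alt = mc.aggregate_costs(
                mc.apply_perturbation(
                    led, Perturbation("ex", PerturbationKind.EXCLUDE_FACILITY_WORKER_TIME)
                )
            ).per_birth
            assert alt <= base

    def test_facility_mix_swap_rescales_quantities(self, ke_ledger):
        big = [
            mc.FacilityProfile(f"B{i}", mc.Country.KE, 300, size_class=mc.SizeClass.LARGE)
            for i in range(6)
        ]
        alt = mc.apply_perturbation(
            ke_ledger,
            Perturbation("mix", PerturbationKind.FACILITY_MIX_SWAP, {"facilities": big}),
        )
        assert len(alt.facilities) == 6
        fac_factor = 6 / len(ke_ledger.facilities)
        base_by_id = {it.item_id: it for it in ke_ledger.items}
        for it in alt.items:
            scaling = it.meta.get("scaling", "fixed")
            if scaling == "per_facility":
                assert it.quantity == pytest.approx(
                    base_by_id[it.item_id].quantity * fac_factor
                )
            elif scaling == "fixed":
                assert it.quantity == base_by_id[it.item_id].quantity

    def test_high_volume_mix_lowers_per_birth_in_kenya(self, ke_ledger):
        """Concentrating delivery volume in fewer, larger facilities lowers
        the per-birth cost, as the study's sensitivity analysis found."""
        big = [
            mc.FacilityProfile(f"B{i}", mc.Country.KE, 300, size_class=mc.SizeClass.LARGE)
            for i in range(6)
        ]
        alt = mc.apply_perturbation(
            ke_ledger,
            Perturbation("mix", PerturbationKind.FACILITY_MIX_SWAP, {"facilities": big}),
        )
        assert mc.aggregate_costs(alt).per_birth < mc.aggregate_costs(ke_ledger).per_birth

    def test_custom_requires_params(self):
        with pytest.raises(ValidationError):
            Perturbation("c", PerturbationKind.CUSTOM)


class TestOneWayTable:
    def test_empty_list_gives_empty_table(self, ke_ledger):
        assert mc.one_way_table(ke_ledger, []) == []

    def test_noop_custom_gives_zero_percent(self, ke_ledger):
        res = mc.one_way_table(
            ke_ledger,
            [Perturbation("noop", PerturbationKind.CUSTOM, {"quantity_multiplier": 1.0})],
        )
        assert res[0].pct_diff == 0

    def test_results_independent_of_list_order(self, ke_ledger):
        perts = [
            Perturbation("a2x", PerturbationKind.ADAPTATION_2X),
            Perturbation("mh", PerturbationKind.MAINTENANCE_HIGH),
            Perturbation("ex", PerturbationKind.EXCLUDE_FACILITY_WORKER_TIME),
        ]
        forward = {r.name: r for r in mc.one_way_table(ke_ledger, perts)}
        backward = {r.name: r for r in mc.one_way_table(ke_ledger, perts[::-1])}
        solo = {
            p.name: mc.one_way_table(ke_ledger, [p])[0] for p in perts
        }
        for name in solo:
            assert forward[name] == backward[name] == solo[name]
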
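import pytest

from microcost import (
    Component,
    CostItem,
    Country,
    FacilityProfile,
    InputCategory,
    Ledger,
    MoneyAmount,
    Phase,
    Scenario,
    ScenarioConfig,
)


def make_item(
    item_id="i1",
    price=10.0,
    qty=2.0,
    component=Component.DS,
    category=InputCategory.CONSUMABLES,
    phase=Phase.P2_IMPLEMENTATION,
    country=Country.KE,
    proration=1.0,
    **kwargs,
):
    return CostItem(
        item_id=item_id,
        scenario=Scenario.MOH_MODEL,
        country=country,
        component=component,
        input_category=category,
        phase=phase,
        unit_price=MoneyAmount(price, normalized=True),
        quantity=qty,
        proration_fraction=proration,
        **kwargs,
    )


def make_ledger(items, facilities=None, country=Country.KE):
    if facilities is None:
        facilities = [FacilityProfile("F1", country, 100)]
    cfg = ScenarioConfig(scenario=Scenario.MOH_MODEL, facility_set=facilities)
    return Ledger(items=items, facilities=facilities, config=cfg)


@pytest.fixture
def simple_ledger():
    items = [
        make_item("a", price=6.0, qty=341.0, component=Component.PRONTO),
        make_item("b", price=18.0, qty=372.0, component=Component.MSCC),
        make_item(
            "c", price=100.0, qty=3.0, component=Component.GENERAL,
            category=InputCategory.PERSONNEL_PROGRAM, phase=Phase.P1_PLANNING,
            control_pertinent=True, meta={"control_proration": 0.5},
        ),
    ]
    return make_ledger(items)
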
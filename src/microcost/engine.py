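"""Core costing computation.

Cost of a line item = normalized unit price x quantity x proration fraction,
with capital rows first routed through the amortization rule.  Aggregation
produces a :class:`CostReport` with totals partitioned three ways (phase,
intervention component, input category) plus the study's unit-cost
denominators: per facility (total / facility count), per birth (total /
[sum of monthly delivery volumes x months of in-facility implementation,
27 by default]) and steady-state per birth (maintenance-phase cost over one
year of births).

All arithmetic is full precision; rounding happens only in the rendering
helpers (:meth:`CostReport.rounded`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .ledger import (
    AcquisitionMode,
    CapitalAsset,
    Component,
    CostItem,
    Country,
    FacilityProfile,
    ImplementationPlan,
    InputCategory,
    Ledger,
    Phase,
    Scenario,
    SizeClass,
    ValidationError,
)
from .monetary import RateTable, normalize
from .rounding import round_half_up

__all__ = [
    "CostReport",
    "line_item_cost",
    "amortization_units",
    "staffing_requirement",
    "births_denominator",
    "aggregate_costs",
    "component_shares",
    "control_filter",
    "DivisionGuardError",
]

#: facilities served per specialist, by facility size (small, large)
DEFAULT_STAFFING_RATIO = (8.5, 5.0)


class DivisionGuardError(ZeroDivisionError):
    """Unit cost requested with a zero facility or birth denominator."""


def amortization_units(asset: CapitalAsset, plan: ImplementationPlan) -> float:
    """Effective acquisition multiplier for a capital good over the program.

    Point purchase with replacement buys the good outright and again each
    time the useful life elapses within the program horizon:
    ceil(program months / life in months).  Straight-line annualization
    instead consumes the fractional share of the good's life the program
    uses: program months / life in months.
    """
    if asset.useful_life_years <= 0:
        raise ValidationError("useful_life_years must be > 0")
    life_months = 12.0 * asset.useful_life_years
    horizon = plan.total_program_months
    if asset.acquisition_mode is AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT:
        return float(math.ceil(horizon / life_months))
    return horizon / life_months


def line_item_cost(
    item: CostItem,
    rates: Optional[RateTable] = None,
    plan: Optional[ImplementationPlan] = None,
) -> float:
    """Normalized base-year USD cost of one ledger line."""
    rates = rates if rates is not None else RateTable()
    price = item.unit_price
    if not price.normalized:
        price = normalize(price, rates, item.country)
    mult = 1.0
    if item.input_category is InputCategory.CAPITAL and item.capital_spec is not None:
        mult = amortization_units(item.capital_spec, plan or ImplementationPlan())
    return price.value * item.quantity * item.proration_fraction * mult


def staffing_requirement(
    facilities: Iterable[FacilityProfile],
    ratio: tuple = DEFAULT_STAFFING_RATIO,
) -> int:
    """Specialists needed per new program role for a facility set.

    One specialist covers roughly 5-8 facilities depending on delivery
    volume; with the default ratio a specialist covers 8.5 small or 5 large
    facilities, and mixed caseloads combine fractionally before the ceiling.
    Minimum staffing is one specialist.
    """
    facilities = list(facilities)
    if not facilities:
        raise ValidationError("staffing_requirement needs a non-empty facility list")
    small_per, large_per = ratio
    n_small = sum(1 for f in facilities if f.size_class is SizeClass.SMALL)
    n_large = sum(1 for f in facilities if f.size_class is SizeClass.LARGE)
    need = math.ceil(n_small / small_per + n_large / large_per)
    return max(1, need)


def births_denominator(
    facilities: Iterable[FacilityProfile],
    plan: Optional[ImplementationPlan] = None,
) -> int:
    """Total facility births over the in-facility implementation months
    (phases 2 + 3; 27 months under the default plan)."""
    plan = plan or ImplementationPlan()
    months = plan.in_facility_months
    return sum(f.monthly_deliveries * months for f in facilities)


@dataclass
class CostReport:
    """Nested totals and unit costs for one scenario/country run."""

    scenario: Scenario
    country: Country
    total_usd_2020: float
    by_phase: dict
    by_component: dict
    by_input_category: dict
    n_facilities: int
    total_births: int
    per_facility: float
    per_birth: float
    per_birth_phase3: float
    component_shares_pct: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        """Presentation view: whole dollars / cents / integer percents,
        rounded half-up.  Keys follow enum declaration order."""
        return {
            "scenario": self.scenario.value,
            "country": self.country.value,
            "total_usd_2020": round_half_up(self.total_usd_2020),
            "per_facility": round_half_up(self.per_facility),
            "per_birth": round_half_up(self.per_birth, 2),
            "per_birth_phase3": round_half_up(self.per_birth_phase3, 2),
            "n_facilities": self.n_facilities,
            "total_births": self.total_births,
            "by_phase": {p.value: round_half_up(v) for p, v in self.by_phase.items()},
            "by_component": {c.value: round_half_up(v) for c, v in self.by_component.items()},
            "by_input_category": {c.value: round_half_up(v) for c, v in self.by_input_category.items()},
            "component_shares_pct": {c.value: v for c, v in self.component_shares_pct.items()},
        }

    def long_rows(self) -> list:
        """Long-format rows (scenario, country, dimension, key, value) with
        byte-stable ordering: summary first, then each partition in enum
        order.  Values are unrounded."""
        rows = []

        def add(dim, key, value):
            rows.append(
                {
                    "scenario": self.scenario.value,
                    "country": self.country.value,
                    "dimension": dim,
                    "key": key,
                    "value": value,
                }
            )

        add("summary", "total_usd_2020", self.total_usd_2020)
        add("summary", "n_facilities", self.n_facilities)
        add("summary", "total_births", self.total_births)
        add("summary", "per_facility", self.per_facility)
        add("summary", "per_birth", self.per_birth)
        add("summary", "per_birth_phase3", self.per_birth_phase3)
        for p in (Phase.P1_PLANNING, Phase.P2_IMPLEMENTATION, Phase.P3_MAINTENANCE):
            add("phase", p.value, self.by_phase.get(p, 0.0))
        for c in Component:
            add("component", c.value, self.by_component.get(c, 0.0))
        for c in InputCategory:
            add("input_category", c.value, self.by_input_category.get(c, 0.0))
        for c, v in self.component_shares_pct.items():
            add("component_share_pct", c.value, v)
        return rows


def aggregate_costs(ledger: Ledger, rates: Optional[RateTable] = None) -> CostReport:
    """Tabulate total normalized cost and its three partitions, plus the
    per-facility, per-birth and steady-state per-birth unit costs."""
    rates = rates if rates is not None else RateTable()
    plan = ledger.config.plan
    facilities = ledger.facilities
    n_fac = len(facilities)
    births = births_denominator(facilities, plan)
    if n_fac == 0 or births == 0:
        raise DivisionGuardError(
            f"unit costs undefined: {n_fac} facilities, {births} births"
        )

    by_phase = {p: 0.0 for p in (Phase.P1_PLANNING, Phase.P2_IMPLEMENTATION, Phase.P3_MAINTENANCE)}
    by_component = {c: 0.0 for c in Component}
    by_category = {c: 0.0 for c in InputCategory}
    total = 0.0
    for it in ledger.items:
        if it.phase is Phase.GENERAL:
            raise ValidationError(
                f"item {it.item_id!r} has unsplit GENERAL phase; "
                "split spread rows before aggregating"
            )
        cost = line_item_cost(it, rates, plan)
        total += cost
        by_phase[it.phase] += cost
        by_component[it.component] += cost
        by_category[it.input_category] += cost

    monthly_total = sum(f.monthly_deliveries for f in facilities)
    births_p3 = monthly_total * plan.phase3_months
    report = CostReport(
        scenario=ledger.config.scenario,
        country=ledger.items[0].country if ledger.items else facilities[0].country,
        total_usd_2020=total,
        by_phase=by_phase,
        by_component=by_component,
        by_input_category=by_category,
        n_facilities=n_fac,
        total_births=births,
        per_facility=total / n_fac,
        per_birth=total / births,
        per_birth_phase3=by_phase[Phase.P3_MAINTENANCE] / births_p3,
    )
    if total > 0:
        report.component_shares_pct = component_shares(report)
    return report


def component_shares(report: CostReport) -> dict:
    """Integer percent contribution of each component to the total,
    rounded half-up; shares may not sum to exactly 100."""
    if report.total_usd_2020 <= 0:
        raise ValidationError("component shares undefined for zero total")
    return {
        c: round_half_up(100.0 * report.by_component.get(c, 0.0) / report.total_usd_2020)
        for c in Component
    }


def control_filter(ledger: Ledger) -> Ledger:
    """Restrict a package ledger to the active-control arm.

    The control receives only data strengthening and the checklist, plus the
    share of shared (GENERAL-component) activity explicitly flagged as
    pertaining to the control; flagged items may carry a ``control_proration``
    in their metadata giving the control arm's (never larger) share of the
    item, which replaces the package proration.
    """
    kept = []
    for it in ledger.items:
        if it.component in (Component.DS, Component.MSCC):
            kept.append(replace(it, meta=dict(it.meta)))
        elif it.component is Component.GENERAL and it.control_pertinent:
            new = replace(it, meta=dict(it.meta))
            if "control_proration" in it.meta:
                cp = float(it.meta["control_proration"])
                if not 0.0 <= cp <= 1.0:
                    raise ValidationError(
                        f"item {it.item_id!r}: control_proration outside [0, 1]"
                    )
                # clamp so a control arm can never cost more than the package
                new.proration_fraction = min(cp, it.proration_fraction)
            kept.append(new)
    return Ledger(
        items=kept,
        facilities=list(ledger.facilities),
        config=ledger.config,
        provenance={**ledger.provenance, "arm": "CONTROL"},
    )
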
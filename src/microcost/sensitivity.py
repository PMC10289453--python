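"""One-way sensitivity analysis.

Each named perturbation rewrites a copy of the base ledger (the base is
never modified), the per-birth cost is recomputed, and the result is the
signed percent difference from base case, rounded half-up to an integer for
presentation with the raw decimal retained.  Perturbations are always
applied one at a time from the unperturbed base — never cumulatively.

Perturbation kinds:

``NM_TRAVELLING``
    Replace facility-embedded nurse-mentor effort (items tagged
    ``nm_embedded``) with hired travelling nurse mentors — one per 3-6
    facilities — plus their facility-visit travel.  Mentor-training rows
    (tag ``nm_training``) are kept.
``ADAPTATION_2X``
    Double planning-phase adaptation effort (items tagged ``adaptation``;
    if a ledger carries no such tags, all planning-phase items).
``MAINTENANCE_HIGH``
    Double the maintenance-phase frequency of simulation/team-training and
    QI-collaborative activity (maintenance items of those two components).
``FACILITY_MIX_SWAP``
    Replace the facility set; quantities rescale per each item's declared
    ``scaling``: ``per_facility`` with facility count, ``per_birth`` with
    total births, ``fixed`` not at all.
``EXCLUDE_FACILITY_WORKER_TIME``
    Drop facility-based personnel time except nurse-mentor training.
``CUSTOM``
    Explicit price/quantity multipliers, optionally filtered by component,
    input category or phase, and/or a list of categories to drop.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .engine import aggregate_costs, births_denominator
from .ledger import (
    Component,
    CostItem,
    InputCategory,
    Ledger,
    MoneyAmount,
    Phase,
    ValidationError,
)
from .monetary import RateTable
from .rounding import round_half_up

__all__ = [
    "PerturbationKind",
    "Perturbation",
    "SensitivityResult",
    "apply_perturbation",
    "percent_difference",
    "one_way_table",
]


class PerturbationKind(enum.Enum):
    NM_TRAVELLING = "NM_TRAVELLING"
    ADAPTATION_2X = "ADAPTATION_2X"
    MAINTENANCE_HIGH = "MAINTENANCE_HIGH"
    FACILITY_MIX_SWAP = "FACILITY_MIX_SWAP"
    EXCLUDE_FACILITY_WORKER_TIME = "EXCLUDE_FACILITY_WORKER_TIME"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class Perturbation:
    name: str
    kind: PerturbationKind
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind is PerturbationKind.CUSTOM and not self.params:
            raise ValidationError("CUSTOM perturbation requires explicit params")


@dataclass(frozen=True)
class SensitivityResult:
    name: str
    base_per_birth: float
    alt_per_birth: float
    pct_diff: int           # round-half-up integer percent, increase positive
    raw_pct_diff: float


def percent_difference(base: float, alt: float) -> int:
    """Signed integer percent change from ``base`` to ``alt`` (half-up)."""
    if base <= 0:
        raise ValidationError(f"percent difference undefined for base {base}")
    return round_half_up(100.0 * (alt - base) / base)


def _nm_travelling(ledger: Ledger, params: dict) -> Ledger:
    out = ledger.copy()
    removed = [it for it in out.items if it.has_tag("nm_embedded")]
    out.items = [it for it in out.items if not it.has_tag("nm_embedded")]
    n_fac = len(out.facilities)
    per_nm = float(params.get("facilities_per_nm", 4.5))  # midpoint of 3-6
    n_nm = max(1, math.ceil(n_fac / per_nm))

    if "nm_monthly_salary" in params:
        salary = float(params["nm_monthly_salary"])
    elif removed:
        salary = removed[0].unit_price.value
    else:
        raise ValidationError(
            "NM_TRAVELLING needs nm_monthly_salary when no embedded mentor rows exist"
        )
    proto = removed[0] if removed else out.items[0]
    plan = out.config.plan
    for ph in (Phase.P2_IMPLEMENTATION, Phase.P3_MAINTENANCE):
        out.items.append(
            CostItem(
                item_id=f"nm-travelling-salary@{ph.value}",
                scenario=proto.scenario,
                country=proto.country,
                component=Component.PRONTO,
                input_category=InputCategory.PERSONNEL_FACILITY,
                phase=ph,
                unit_price=MoneyAmount(salary, normalized=True),
                quantity=n_nm * plan.phase_months(ph),
                quantity_unit="months",
                meta={"tags": "nm_hired", "scaling": "per_facility"},
            )
        )
    petrol = next((it for it in ledger.items if it.has_tag("local_travel")), None)
    trip_price = float(params.get("trip_price", petrol.unit_price.value if petrol else 10.0))
    trips_per_fac_month = float(params.get("trips_per_facility_month", 2.0))
    for ph in (Phase.P2_IMPLEMENTATION, Phase.P3_MAINTENANCE):
        out.items.append(
            CostItem(
                item_id=f"nm-travelling-trips@{ph.value}",
                scenario=proto.scenario,
                country=proto.country,
                component=Component.PRONTO,
                input_category=InputCategory.TRAVEL,
                phase=ph,
                unit_price=MoneyAmount(trip_price, normalized=True),
                quantity=n_fac * plan.phase_months(ph) * trips_per_fac_month,
                quantity_unit="return trips",
                meta={"tags": "nm_hired,local_travel", "scaling": "per_facility"},
            )
        )
    return out


def _scale_items(items: Iterable[CostItem], predicate, factor: float) -> list:
    out = []
    for it in items:
        if predicate(it):
            out.append(replace(it, quantity=it.quantity * factor, meta=dict(it.meta)))
        else:
            out.append(it)
    return out


def _adaptation(ledger: Ledger, params: dict) -> Ledger:
    out = ledger.copy()
    factor = float(params.get("multiplier", 2.0))
    tagged = any(it.has_tag("adaptation") for it in out.items)
    if tagged:
        pred = lambda it: it.has_tag("adaptation") and it.phase is Phase.P1_PLANNING
    else:
        pred = lambda it: it.phase is Phase.P1_PLANNING
    out.items = _scale_items(out.items, pred, factor)
    return out


def _maintenance_high(ledger: Ledger, params: dict) -> Ledger:
    out = ledger.copy()
    factor = float(params.get("multiplier", 2.0))
    pred = lambda it: (
        it.phase is Phase.P3_MAINTENANCE
        and it.component in (Component.PRONTO, Component.QI)
    )
    out.items = _scale_items(out.items, pred, factor)
    return out


def _facility_mix_swap(ledger: Ledger, params: dict) -> Ledger:
    if "facilities" not in params:
        raise ValidationError("FACILITY_MIX_SWAP requires params['facilities']")
    new_fac = list(params["facilities"])
    if not new_fac:
        raise ValidationError("replacement facility set must be non-empty")
    out = ledger.copy()
    plan = out.config.plan
    fac_factor = len(new_fac) / len(ledger.facilities)
    birth_factor = births_denominator(new_fac, plan) / births_denominator(ledger.facilities, plan)
    items = []
    for it in out.items:
        scaling = str(it.meta.get("scaling", "fixed"))
        if scaling == "per_facility":
            items.append(replace(it, quantity=it.quantity * fac_factor, meta=dict(it.meta)))
        elif scaling == "per_birth":
            items.append(replace(it, quantity=it.quantity * birth_factor, meta=dict(it.meta)))
        else:
            items.append(it)
    out.items = items
    out.facilities = new_fac
    out.config = replace(out.config, facility_set=new_fac)
    return out


def _exclude_facility_worker_time(ledger: Ledger, params: dict) -> Ledger:
    out = ledger.copy()
    out.items = [
        it
        for it in out.items
        if it.input_category is not InputCategory.PERSONNEL_FACILITY
        or it.has_tag("nm_training")
    ]
    return out


def _custom(ledger: Ledger, params: dict) -> Ledger:
    out = ledger.copy()
    comp = Component(params["component"]) if "component" in params else None
    cat = InputCategory(params["input_category"]) if "input_category" in params else None
    phase = Phase(params["phase"]) if "phase" in params else None
    drop = {InputCategory(c) for c in params.get("drop_categories", [])}

    def selected(it: CostItem) -> bool:
        return (
            (comp is None or it.component is comp)
            and (cat is None or it.input_category is cat)
            and (phase is None or it.phase is phase)
        )

    qmult = float(params.get("quantity_multiplier", 1.0))
    pmult = float(params.get("price_multiplier", 1.0))
    items = []
    for it in out.items:
        if it.input_category in drop:
            continue
        if selected(it) and (qmult != 1.0 or pmult != 1.0):
            it = replace(
                it,
                quantity=it.quantity * qmult,
                unit_price=replace(it.unit_price, value=it.unit_price.value * pmult),
                meta=dict(it.meta),
            )
        items.append(it)
    out.items = items
    return out


_HANDLERS = {
    PerturbationKind.NM_TRAVELLING: _nm_travelling,
    PerturbationKind.ADAPTATION_2X: _adaptation,
    PerturbationKind.MAINTENANCE_HIGH: _maintenance_high,
    PerturbationKind.FACILITY_MIX_SWAP: _facility_mix_swap,
    PerturbationKind.EXCLUDE_FACILITY_WORKER_TIME: _exclude_facility_worker_time,
    PerturbationKind.CUSTOM: _custom,
}


def apply_perturbation(ledger: Ledger, p: Perturbation) -> Ledger:
    """Return a new ledger with the perturbation applied; base unmodified."""
    try:
        handler = _HANDLERS[p.kind]
    except KeyError:
        raise ValidationError(f"unknown perturbation kind {p.kind!r}") from None
    out = handler(ledger, p.params)
    out.provenance = {**out.provenance, "perturbation": p.name}
    return out


def one_way_table(
    ledger: Ledger,
    perturbations: Iterable[Perturbation],
    rates: Optional[RateTable] = None,
) -> list:
    """Run each perturbation independently from the same base and report
    per-birth cost against base case, in the order given."""
    rates = rates if rates is not None else RateTable()
    base = aggregate_costs(ledger, rates).per_birth
    results = []
    for p in perturbations:
        try:
            alt = aggregate_costs(apply_perturbation(ledger, p), rates).per_birth
        except Exception as exc:
            raise type(exc)(f"perturbation {p.name!r}: {exc}") from exc
        raw = 100.0 * (alt - base) / base
        results.append(
            SensitivityResult(
                name=p.name,
                base_per_birth=base,
                alt_per_birth=alt,
                pct_diff=percent_difference(base, alt),
                raw_pct_diff=raw,
            )
        )
    return results
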
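"""Seeded synthetic ledger and facility-set generator.

The generator emits ledgers with the statistical structure of the costed
study, so every pipeline stage is testable without external data:

* facility sets — 17 Kenyan sites at 30-360 deliveries/month (most under
  100) or 6 Ugandan sites at 90-585/month (most over 150), drawn from a
  two-component uniform mixture that enforces the majority rule;
* line items — the published unit-price skeleton with multiplicative price
  jitter, quantities derived from the generated facility set (staffing-rule
  specialists, uniform 8-15 trained workers per facility, per-facility and
  per-birth scalings), capital lives uniform in 3-5 years;
* calibration — per-category quantity rescaling so each ledger reproduces
  the study's input-category cost mix, which in particular keeps the
  personnel share of total cost at the study's observed level (>= 72%).

Each generated ledger records its own construction total (accumulated line
by line while building), used as an independent oracle for the engine's
aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import amortization_units, births_denominator, staffing_requirement
from .ledger import (
    AcquisitionMode,
    Arm,
    CapitalAsset,
    Component,
    CostItem,
    Country,
    FacilityProfile,
    ImplementationPlan,
    InputCategory,
    Ledger,
    MoneyAmount,
    Phase,
    Scenario,
    ScenarioConfig,
    SizeClass,
    ValidationError,
    table3_fixture,
    table5_fixture,
)

__all__ = ["GeneratorParams", "generate_facilities", "generate_ledger"]

#: delivery-volume threshold splitting small from large facilities
SIZE_THRESHOLD = {Country.KE: 100, Country.UG: 150}
#: which side of the threshold holds "most" facilities
MAJORITY_SIDE = {Country.KE: "below", Country.UG: "above"}
DEFAULT_N_FACILITIES = {Country.KE: 17, Country.UG: 6}
DEFAULT_VOLUME_BOUNDS = {Country.KE: (30, 360), Country.UG: (90, 585)}
#: probability a facility falls on the majority side of the threshold
MAJORITY_PROB = 0.7
#: midpoint of the 8-15 trained-workers-per-facility range
MEAN_TRAINED_WORKERS = 11.5
#: specialists per new role implied by the published effort months
BASELINE_SPECIALISTS = 2


@dataclass
class GeneratorParams:
    """Reproducible generator configuration; identical params + seed give an
    identical ledger."""

    seed: int = 0
    country: Country = Country.KE
    scenario: Scenario = Scenario.MOH_MODEL
    n_facilities: Optional[int] = None
    volume_bounds: Optional[tuple] = None
    price_jitter: float = 0.10
    trained_worker_range: tuple = (8, 15)
    capital_life_range: tuple = (3.0, 5.0)
    #: input-category cost proportions to calibrate each ledger to;
    #: None means the study's published mix for the chosen scenario/country
    category_mix_target: Optional[dict] = None
    calibrate_category_mix: bool = True
    #: private-sector salary premium applied to program/consultant personnel
    #: in study-observed ledgers (midpoint of the observed 2-5x range)
    private_salary_multiplier: float = 3.0
    #: consultant effort premium in study-observed ledgers
    consultant_intensity: float = 2.0
    plan: ImplementationPlan = field(default_factory=ImplementationPlan)

    def resolved_n(self) -> int:
        return self.n_facilities or DEFAULT_N_FACILITIES[self.country]

    def resolved_bounds(self) -> tuple:
        return self.volume_bounds or DEFAULT_VOLUME_BOUNDS[self.country]


def generate_facilities(params: GeneratorParams) -> list:
    """Draw a facility set honoring the volume bounds and majority rule.

    Volumes come from a two-component mixture: uniform on the majority side
    of the size threshold with probability 0.7, uniform on the other side
    with probability 0.3.  If a draw leaves the majority side short of a
    strict majority, minority facilities are re-drawn onto it.
    """
    rng = np.random.default_rng(params.seed)
    n = params.resolved_n()
    lo, hi = params.resolved_bounds()
    if not 0 < lo < hi:
        raise ValidationError(f"invalid volume bounds ({lo}, {hi})")
    thr = SIZE_THRESHOLD[params.country]
    if not lo < thr <= hi:
        raise ValidationError(
            f"majority rule infeasible: threshold {thr} outside bounds ({lo}, {hi})"
        )
    majority_below = MAJORITY_SIDE[params.country] == "below"

    on_major = rng.random(n) < MAJORITY_PROB
    need = n // 2 + 1
    short = need - int(on_major.sum())
    if short > 0:
        flip = rng.choice(np.flatnonzero(~on_major), size=short, replace=False)
        on_major[flip] = True

    facilities = []
    for i in range(n):
        below = on_major[i] if majority_below else not on_major[i]
        if below:
            vol = int(rng.integers(lo, thr))
        else:
            vol = int(rng.integers(thr, hi + 1))
        facilities.append(
            FacilityProfile(
                facility_id=f"{params.country.value}-F{i + 1:02d}",
                country=params.country,
                monthly_deliveries=vol,
                arm=Arm.INTERVENTION,
                size_class=SizeClass.SMALL if vol < thr else SizeClass.LARGE,
            )
        )
    return facilities


# ---------------------------------------------------------------------------
# Line-item skeleton: component/phase allocation, tags and quantity scaling
# for every row of the published price table.  Fractions in `components` and
# `phases` each sum to 1 so splits stay exactly additive.

def _row(cat, components, phases, scaling="fixed", control=None,
         control_proration=None, capital=False, tags=""):
    return {
        "category": cat,
        "components": components,
        "phases": phases,
        "scaling": scaling,
        "control_pertinent": control,
        "control_proration": control_proration,
        "capital": capital,
        "tags": tags,
    }


P1, P2, P3 = Phase.P1_PLANNING, Phase.P2_IMPLEMENTATION, Phase.P3_MAINTENANCE
_C = Component
_I = InputCategory

ROW_PLAN = {
    "County or regional/district MNCH coordinator": _row(
        _I.PERSONNEL_PROGRAM, [(_C.GENERAL, 1.0)],
        [(P1, 0.40, ""), (P2, 0.35, ""), (P3, 0.25, "")],
        control=True, control_proration=0.5),
    "Sub-county or associate MNCH coordinator": _row(
        _I.PERSONNEL_PROGRAM, [(_C.GENERAL, 1.0)],
        [(P1, 0.30, ""), (P2, 0.40, ""), (P3, 0.30, "")],
        control=True, control_proration=0.5),
    "Senior obstetrician": _row(
        _I.PERSONNEL_CONSULTANT, [(_C.PRONTO, 1.0)], [(P1, 1.0, "adaptation")]),
    "Senior pediatrician": _row(
        _I.PERSONNEL_CONSULTANT, [(_C.PRONTO, 1.0)], [(P1, 1.0, "adaptation")]),
    "Statistician/biostatistician": _row(
        _I.PERSONNEL_PROGRAM, [(_C.DS, 1.0)],
        [(P1, 0.50, "adaptation"), (P2, 0.50, "")]),
    "Data quality/mSCC specialist": _row(
        _I.PERSONNEL_PROGRAM, [(_C.DS, 0.5), (_C.MSCC, 0.5)],
        [(P1, 0.20, "adaptation"), (P2, 0.50, ""), (P3, 0.30, "")],
        scaling="specialists"),
    "DHIS/HMIS specialist": _row(
        _I.PERSONNEL_PROGRAM, [(_C.DS, 1.0)],
        [(P1, 0.30, "adaptation"), (P2, 0.70, "")]),
    "PRONTO/QI specialist": _row(
        _I.PERSONNEL_PROGRAM, [(_C.PRONTO, 0.6), (_C.QI, 0.4)],
        [(P1, 0.15, "adaptation"), (P2, 0.50, ""), (P3, 0.35, "")],
        scaling="specialists"),
    "Principal medical officer": _row(
        _I.PERSONNEL_FACILITY, [(_C.GENERAL, 1.0)],
        [(P2, 0.60, ""), (P3, 0.40, "")],
        scaling="per_facility", control=True, control_proration=0.5),
    "Maternity/newborn unit in-charge": _row(
        _I.PERSONNEL_FACILITY, [(_C.QI, 0.6), (_C.MSCC, 0.4)],
        [(P2, 0.60, ""), (P3, 0.40, "")], scaling="per_facility"),
    "PRONTO Nurse Mentor": _row(
        _I.PERSONNEL_FACILITY, [(_C.PRONTO, 1.0)],
        [(P1, 0.10, "nm_training"), (P2, 0.55, "nm_embedded"),
         (P3, 0.35, "nm_embedded")],
        scaling="per_facility"),
    "Registered nurse or midwife": _row(
        _I.PERSONNEL_FACILITY,
        [(_C.DS, 0.15), (_C.MSCC, 0.25), (_C.PRONTO, 0.40), (_C.QI, 0.20)],
        [(P2, 0.60, ""), (P3, 0.40, "")], scaling="trained_workers"),
    "Health records clerk": _row(
        _I.PERSONNEL_FACILITY, [(_C.DS, 1.0)],
        [(P2, 0.60, ""), (P3, 0.40, "")], scaling="per_facility"),
    "PRONTO Manuals - Professional printing": _row(
        _I.CONSUMABLES, [(_C.PRONTO, 1.0)], [(P1, 1.0, "")]),
    "PRONTO Manuals - Local printing": _row(
        _I.CONSUMABLES, [(_C.PRONTO, 1.0)],
        [(P2, 0.70, ""), (P3, 0.30, "")], scaling="trained_workers"),
    "DS, mSCC, and QI training packets": _row(
        _I.CONSUMABLES, [(_C.DS, 0.4), (_C.MSCC, 0.3), (_C.QI, 0.3)],
        [(P2, 0.70, ""), (P3, 0.30, "")], scaling="trained_workers"),
    "mSCC paper and printing": _row(
        _I.CONSUMABLES, [(_C.MSCC, 1.0)],
        [(P2, 15 / 27, ""), (P3, 12 / 27, "")], scaling="per_birth"),
    "Single-use PRONTO supplies": _row(
        _I.CONSUMABLES, [(_C.PRONTO, 1.0)],
        [(P2, 15 / 27, ""), (P3, 12 / 27, "")], scaling="per_facility"),
    "Computer": _row(
        _I.CAPITAL, [(_C.GENERAL, 1.0)], [(P1, 1.0, "")],
        scaling="specialists", control=True, control_proration=0.5, capital=True),
    "Office desk and chair": _row(
        _I.CAPITAL, [(_C.GENERAL, 1.0)], [(P1, 1.0, "")],
        scaling="specialists", control=True, control_proration=0.5, capital=True),
    "Projector": _row(
        _I.CAPITAL, [(_C.PRONTO, 0.5), (_C.QI, 0.5)], [(P1, 1.0, "")], capital=True),
    "Neonatal resuscitation mannequin": _row(
        _I.CAPITAL, [(_C.PRONTO, 1.0)], [(P2, 1.0, "")],
        scaling="per_facility", capital=True),
    "Bag-valve masks (neonatal/preterm)": _row(
        _I.CAPITAL, [(_C.PRONTO, 1.0)], [(P2, 1.0, "")],
        scaling="per_facility", capital=True),
    "Hotel conference room": _row(
        _I.OFFICE_CONF_SPACE, [(_C.GENERAL, 1.0)],
        [(P1, 0.50, "adaptation"), (P2, 0.25, ""), (P3, 0.25, "")],
        control=True, control_proration=0.5),
    "Food/beverage - offsite meetings": _row(
        _I.OFFICE_CONF_SPACE, [(_C.GENERAL, 1.0)],
        [(P1, 0.50, "adaptation"), (P2, 0.25, ""), (P3, 0.25, "")],
        control=True, control_proration=0.5),
    "Value of office space for specialists": _row(
        _I.OFFICE_CONF_SPACE, [(_C.GENERAL, 1.0)],
        [(P1, 0.25, ""), (P2, 0.42, ""), (P3, 0.33, "")],
        scaling="specialists", control=True, control_proration=0.5),
    "Airfare: US to in-country": _row(
        _I.TRAVEL, [(_C.PRONTO, 1.0)], [(P1, 1.0, "adaptation")]),
    "Airfare: Within East Africa": _row(
        _I.TRAVEL, [(_C.GENERAL, 1.0)],
        [(P1, 0.40, ""), (P2, 0.40, ""), (P3, 0.20, "")],
        control=True, control_proration=0.5),
    "Hotel accommodation and food": _row(
        _I.TRAVEL, [(_C.GENERAL, 1.0)],
        [(P1, 0.40, ""), (P2, 0.40, ""), (P3, 0.20, "")],
        control=True, control_proration=0.5),
    "Petrol/vehicle expenses - local travel": _row(
        _I.TRAVEL, [(_C.GENERAL, 1.0)],
        [(P2, 0.60, ""), (P3, 0.40, "")],
        scaling="per_facility", control=True, control_proration=0.5,
        tags="local_travel"),
}


def _published_mix(scenario: Scenario, country: Country) -> dict:
    df = table5_fixture()
    sel = df[
        (df["scenario"] == scenario.value)
        & (df["country"] == country.value)
        & (df["block"] == "input_type")
    ]
    totals = dict(zip(sel["key"], sel["value"].astype(float)))
    grand = sum(totals.values())
    return {InputCategory(k): v / grand for k, v in totals.items()}


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in name.lower()).strip("-")


def generate_ledger(params: GeneratorParams) -> Ledger:
    """Generate a full synthetic ledger for one scenario and country.

    The returned ledger's ``provenance`` carries the generator's own
    construction bookkeeping (``construction_total`` and per-category
    totals), accumulated line by line while the items were built, for use as
    an independent aggregation oracle.
    """
    # independent stream from the facility draw, still fully seed-determined
    rng = np.random.default_rng([params.seed, 1])
    facilities = generate_facilities(params)
    plan = params.plan
    n_fac = len(facilities)
    n_default = DEFAULT_N_FACILITIES[params.country]
    births = births_denominator(facilities, plan)

    lo_w, hi_w = params.trained_worker_range
    workers = rng.integers(lo_w, hi_w + 1, size=n_fac)
    total_workers = int(workers.sum())
    n_spec = staffing_requirement(facilities)

    scale_for = {
        "fixed": 1.0,
        "per_facility": n_fac / n_default,
        "trained_workers": total_workers / (n_default * MEAN_TRAINED_WORKERS),
        "specialists": n_spec / BASELINE_SPECIALISTS,
    }
    study = params.scenario is Scenario.STUDY_OBSERVED

    table = table3_fixture(params.country)
    raw_items = []
    idx = 0
    for _, trow in table.iterrows():
        name = trow["item"]
        plan_row = ROW_PLAN[name]
        cat = plan_row["category"]

        price = float(trow["unit_price"])
        if params.price_jitter > 0:
            z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
            price *= math.exp(params.price_jitter * z)
        if study and cat in (_I.PERSONNEL_PROGRAM, _I.PERSONNEL_CONSULTANT):
            price *= params.private_salary_multiplier

        if plan_row["scaling"] == "per_birth":
            base_qty = births / 100.0  # checklist bundles of 100
        else:
            base_qty = float(trow["units"]) * scale_for[plan_row["scaling"]]
        if study and cat is _I.PERSONNEL_CONSULTANT:
            base_qty *= params.consultant_intensity

        capital = None
        if plan_row["capital"]:
            life = float(rng.uniform(*params.capital_life_range))
            capital = CapitalAsset(life, AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT)

        for comp, cfrac in plan_row["components"]:
            for phase, pfrac, ptags in plan_row["phases"]:
                tags = ",".join(t for t in (plan_row["tags"], ptags) if t)
                meta = {"scaling": plan_row["scaling"]
                        if plan_row["scaling"] in ("per_facility", "per_birth")
                        else ("per_facility" if plan_row["scaling"] == "trained_workers" else "fixed"),
                        "table_item": name}
                if tags:
                    meta["tags"] = tags
                if plan_row["control_proration"] is not None:
                    meta["control_proration"] = plan_row["control_proration"]
                raw_items.append(
                    CostItem(
                        item_id=f"{params.country.value}-{idx:03d}-{_slug(name)}"
                                f"-{comp.value}-{phase.value}",
                        scenario=params.scenario,
                        country=params.country,
                        component=comp,
                        input_category=cat,
                        phase=phase,
                        unit_price=MoneyAmount(price, normalized=True),
                        quantity=base_qty * cfrac * pfrac,
                        quantity_unit=str(trow["unit_label"]),
                        proration_fraction=1.0,
                        capital_spec=capital,
                        control_pertinent=plan_row["control_pertinent"],
                        meta=meta,
                    )
                )
                idx += 1

    def item_cost(it: CostItem) -> float:
        mult = amortization_units(it.capital_spec, plan) if it.capital_spec else 1.0
        return it.unit_price.value * it.quantity * it.proration_fraction * mult

    if params.calibrate_category_mix:
        target = params.category_mix_target or _published_mix(params.scenario, params.country)
        raw_cat = {c: 0.0 for c in InputCategory}
        for it in raw_items:
            raw_cat[it.input_category] += item_cost(it)
        raw_total = sum(raw_cat.values())
        for it in raw_items:
            share = target.get(it.input_category, 0.0)
            cat_total = raw_cat[it.input_category]
            if cat_total > 0:
                it.quantity *= share * raw_total / cat_total

    construction_total = 0.0
    construction_by_cat = {c: 0.0 for c in InputCategory}
    for it in raw_items:
        c = item_cost(it)
        construction_total += c
        construction_by_cat[it.input_category] += c

    config = ScenarioConfig(
        scenario=params.scenario,
        facility_set=facilities,
        plan=plan,
    )
    return Ledger(
        items=raw_items,
        facilities=facilities,
        config=config,
        provenance={
            "seed": params.seed,
            "country": params.country.value,
            "scenario": params.scenario.value,
            "n_facilities": n_fac,
            "total_births": births,
            "n_specialists_per_role": n_spec,
            "total_trained_workers": total_workers,
            "construction_total": construction_total,
            "construction_by_category": {
                c.value: v for c, v in construction_by_cat.items()
            },
        },
    )
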
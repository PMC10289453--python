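"""Domain model for activity-based cost ledgers.

A ledger is a flat collection of priced, quantified, prorated line items
(:class:`CostItem`), each assigned to a costing scenario, country, program
phase, intervention component and input category, together with the set of
delivery facilities (:class:`FacilityProfile`) that provides the unit-cost
denominators, and a :class:`ScenarioConfig` bundle of run assumptions.

The module also houses packaged fixtures transcribing the printed unit-price,
cost-summary and sensitivity tables of the underlying study, loadable with
:func:`load_fixture`.
"""

from __future__ import annotations

import enum
import io
import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

__all__ = [
    "Scenario",
    "Country",
    "Component",
    "InputCategory",
    "Phase",
    "AcquisitionMode",
    "Arm",
    "SizeClass",
    "MoneyAmount",
    "CapitalAsset",
    "CostItem",
    "FacilityProfile",
    "ImplementationPlan",
    "ScenarioConfig",
    "Ledger",
    "Diagnostic",
    "SchemaError",
    "ValidationError",
    "load_ledger",
    "write_ledger",
    "load_facilities",
    "write_facilities",
    "load_config",
    "validate_ledger",
    "load_fixture",
    "table3_fixture",
    "table5_fixture",
    "table7_fixture",
    "table5_package_ledger",
    "table5_block_ledger",
]


# ---------------------------------------------------------------------------
# Enumerations

class Scenario(enum.Enum):
    STUDY_OBSERVED = "STUDY_OBSERVED"
    MOH_MODEL = "MOH_MODEL"


class Country(enum.Enum):
    KE = "KE"
    UG = "UG"


class Component(enum.Enum):
    """Intervention components; GENERAL holds shared, non-allocable activity."""

    GENERAL = "GENERAL"
    DS = "DS"
    MSCC = "MSCC"
    PRONTO = "PRONTO"
    QI = "QI"


class InputCategory(enum.Enum):
    PERSONNEL_PROGRAM = "PERSONNEL_PROGRAM"
    PERSONNEL_CONSULTANT = "PERSONNEL_CONSULTANT"
    PERSONNEL_FACILITY = "PERSONNEL_FACILITY"
    CONSUMABLES = "CONSUMABLES"
    CAPITAL = "CAPITAL"
    OFFICE_CONF_SPACE = "OFFICE_CONF_SPACE"
    TRAVEL = "TRAVEL"


class Phase(enum.Enum):
    """Program phases.  GENERAL marks an item spread across all phases;
    such rows are split into single-phase rows at load time so that phase
    breakdowns stay exactly additive."""

    P1_PLANNING = "P1_PLANNING"
    P2_IMPLEMENTATION = "P2_IMPLEMENTATION"
    P3_MAINTENANCE = "P3_MAINTENANCE"
    GENERAL = "GENERAL"


class AcquisitionMode(enum.Enum):
    POINT_PURCHASE_WITH_REPLACEMENT = "POINT_PURCHASE_WITH_REPLACEMENT"
    STRAIGHT_LINE_ANNUALIZED = "STRAIGHT_LINE_ANNUALIZED"


class Arm(enum.Enum):
    INTERVENTION = "INTERVENTION"
    CONTROL = "CONTROL"


class SizeClass(enum.Enum):
    SMALL = "SMALL"
    LARGE = "LARGE"


class SchemaError(ValueError):
    """A file does not conform to the documented column schema."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True)
class MoneyAmount:
    """A non-negative amount of money in a nominal currency and year.

    ``normalized`` marks an amount already expressed in base-year USD;
    normalizing twice is rejected by the monetary module.
    """

    value: float
    currency: str = "USD"
    nominal_year: int = 2020
    nominal_month: Optional[int] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"money value must be >= 0, got {self.value}")
        if self.nominal_month is not None and not 1 <= self.nominal_month <= 12:
            raise ValidationError(
                f"nominal_month must be in 1..12, got {self.nominal_month}"
            )


@dataclass(frozen=True)
class CapitalAsset:
    """Durable good with a useful life and an acquisition/replacement mode."""

    useful_life_years: float = 4.0
    acquisition_mode: AcquisitionMode = AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT

    def __post_init__(self) -> None:
        if self.useful_life_years <= 0:
            raise ValidationError(
                f"useful_life_years must be > 0, got {self.useful_life_years}"
            )


@dataclass
class CostItem:
    """One priced, quantified, prorated activity or resource line.

    ``meta`` preserves unknown ledger columns and carries optional free-form
    tags used by the sensitivity framework:

    * ``tags`` – comma-separated labels (``adaptation``, ``nm_embedded``,
      ``nm_training``, ``local_travel``);
    * ``scaling`` – ``fixed`` | ``per_facility`` | ``per_birth``, how the
      quantity scales when the facility set is swapped;
    * ``control_proration`` – proration applied when the item is carried into
      a control-arm ledger.
    """

    item_id: str
    scenario: Scenario
    country: Country
    component: Component
    input_category: InputCategory
    phase: Phase
    unit_price: MoneyAmount
    quantity: float
    quantity_unit: str = "units"
    proration_fraction: float = 1.0
    capital_spec: Optional[CapitalAsset] = None
    control_pertinent: Optional[bool] = None
    meta: dict = field(default_factory=dict)

    def tags(self) -> set:
        raw = self.meta.get("tags", "")
        if not raw or (isinstance(raw, float) and math.isnan(raw)):
            return set()
        return {t.strip() for t in str(raw).split(",") if t.strip()}

    def has_tag(self, tag: str) -> bool:
        return tag in self.tags()


@dataclass(frozen=True)
class FacilityProfile:
    """A delivery site; ``monthly_deliveries`` feeds the per-birth denominator."""

    facility_id: str
    country: Country
    monthly_deliveries: int
    arm: Arm = Arm.INTERVENTION
    size_class: SizeClass = SizeClass.SMALL

    def __post_init__(self) -> None:
        if self.monthly_deliveries <= 0:
            raise ValidationError(
                f"monthly_deliveries must be > 0 ({self.facility_id})"
            )


@dataclass(frozen=True)
class ImplementationPlan:
    """Phase durations in months.

    Defaults: 9 months design/planning, 15 months high-intensity in-facility
    implementation, 12 months annual maintenance, giving 27 months of
    in-facility activity for the per-birth denominator.
    """

    phase1_months: int = 9
    phase2_months: int = 15
    phase3_months: int = 12

    def __post_init__(self) -> None:
        for name in ("phase1_months", "phase2_months", "phase3_months"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def in_facility_months(self) -> int:
        return self.phase2_months + self.phase3_months

    @property
    def total_program_months(self) -> int:
        return self.phase1_months + self.phase2_months + self.phase3_months

    def phase_months(self, phase: Phase) -> int:
        return {
            Phase.P1_PLANNING: self.phase1_months,
            Phase.P2_IMPLEMENTATION: self.phase2_months,
            Phase.P3_MAINTENANCE: self.phase3_months,
        }[phase]


#: default plausible facility volume bounds by country (deliveries/month)
DEFAULT_VOLUME_BOUNDS = {Country.KE: (30, 360), Country.UG: (90, 585)}


@dataclass
class ScenarioConfig:
    """Assumption bundle parameterizing a costing run."""

    scenario: Scenario = Scenario.MOH_MODEL
    facility_set: list = field(default_factory=list)
    plan: ImplementationPlan = field(default_factory=ImplementationPlan)
    nm_model: str = "EMBEDDED_PER_FACILITY"  # or TRAVELLING
    adaptation_intensity: float = 1.0
    maintenance_intensity: str = "BASE"  # or HIGH
    specialist_ratio: tuple = (5, 8)
    trained_workers_per_facility: tuple = (8, 15)
    base_year: int = 2020
    currency_set: tuple = ("KES", "UGX", "USD")
    volume_bounds: dict = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.adaptation_intensity <= 0:
            raise ValidationError("adaptation_intensity must be > 0")


@dataclass
class Ledger:
    """A scenario-specific collection of cost items plus facilities/config."""

    items: list
    facilities: list
    config: ScenarioConfig
    provenance: dict = field(default_factory=dict)

    def copy(self) -> "Ledger":
        return Ledger(
            items=[replace(it, meta=dict(it.meta)) for it in self.items],
            facilities=list(self.facilities),
            config=self.config,
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class Diagnostic:
    item_id: str
    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.item_id}] {self.field}: {self.rule} -- {self.message}"


# ---------------------------------------------------------------------------
# Ledger I/O

LEDGER_COLUMNS = [
    "item_id", "scenario", "country", "component", "input_category", "phase",
    "currency", "nominal_year", "nominal_month", "unit_price", "quantity",
    "quantity_unit", "proration_fraction", "useful_life_years",
    "acquisition_mode", "control_pertinent",
]

REQUIRED_COLUMNS = [
    "item_id", "scenario", "country", "component", "input_category", "phase",
    "currency", "nominal_year", "unit_price", "quantity",
]

FACILITY_COLUMNS = ["facility_id", "country", "monthly_deliveries", "arm", "size_class"]


def _parse_enum(enum_cls, raw, item_id: str, column: str):
    try:
        return enum_cls(str(raw).strip())
    except ValueError:
        raise ValidationError(
            f"item {item_id!r}: unknown {column} value {raw!r} "
            f"(expected one of {[e.value for e in enum_cls]})"
        ) from None


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def _row_to_item(row: dict, normalized_default: bool) -> CostItem:
    item_id = str(row["item_id"])
    price = float(row["unit_price"])
    qty = float(row["quantity"])
    if price < 0:
        raise ValidationError(f"item {item_id!r}: unit_price must be >= 0, got {price}")
    if qty < 0:
        raise ValidationError(f"item {item_id!r}: quantity must be >= 0, got {qty}")
    month = None if _is_blank(row.get("nominal_month")) else int(float(row["nominal_month"]))
    currency = str(row["currency"]).strip()
    year = int(float(row["nominal_year"]))
    proration = 1.0 if _is_blank(row.get("proration_fraction")) else float(row["proration_fraction"])
    if not 0.0 <= proration <= 1.0:
        raise ValidationError(
            f"item {item_id!r}: proration_fraction must be in [0, 1], got {proration}"
        )
    capital = None
    if not _is_blank(row.get("useful_life_years")):
        mode = (
            AcquisitionMode.POINT_PURCHASE_WITH_REPLACEMENT
            if _is_blank(row.get("acquisition_mode"))
            else _parse_enum(AcquisitionMode, row["acquisition_mode"], item_id, "acquisition_mode")
        )
        capital = CapitalAsset(float(row["useful_life_years"]), mode)
    cp = row.get("control_pertinent")
    if _is_blank(cp):
        control_pertinent = None
    else:
        control_pertinent = str(cp).strip().lower() in ("true", "1", "yes")
    meta = {k: v for k, v in row.items() if k not in LEDGER_COLUMNS and not _is_blank(v)}
    normalized = currency == "USD" and normalized_default
    return CostItem(
        item_id=item_id,
        scenario=_parse_enum(Scenario, row["scenario"], item_id, "scenario"),
        country=_parse_enum(Country, row["country"], item_id, "country"),
        component=_parse_enum(Component, row["component"], item_id, "component"),
        input_category=_parse_enum(InputCategory, row["input_category"], item_id, "input_category"),
        phase=_parse_enum(Phase, row["phase"], item_id, "phase"),
        unit_price=MoneyAmount(price, currency, year, month, normalized=normalized),
        quantity=qty,
        quantity_unit="units" if _is_blank(row.get("quantity_unit")) else str(row["quantity_unit"]),
        proration_fraction=proration,
        capital_spec=capital,
        control_pertinent=control_pertinent,
        meta=meta,
    )


def split_spread_items(items: Iterable[CostItem], plan: ImplementationPlan) -> list:
    """Split phase-GENERAL rows into one row per phase, weighted by phase
    duration, so phase totals remain exactly additive."""
    out = []
    total = plan.total_program_months
    for it in items:
        if it.phase is not Phase.GENERAL:
            out.append(it)
            continue
        for ph in (Phase.P1_PLANNING, Phase.P2_IMPLEMENTATION, Phase.P3_MAINTENANCE):
            frac = plan.phase_months(ph) / total
            out.append(
                replace(
                    it,
                    item_id=f"{it.item_id}@{ph.value}",
                    phase=ph,
                    quantity=it.quantity * frac,
                    meta=dict(it.meta),
                )
            )
    return out


def load_ledger(
    path: Union[str, Path],
    config: ScenarioConfig,
    facilities: Optional[Union[str, Path, list]] = None,
) -> Ledger:
    """Read a ledger CSV/JSON into a validated :class:`Ledger`.

    USD amounts dated to ``config.base_year`` are flagged as already
    normalized.  Rows with phase ``GENERAL`` are split across phases.
    Unknown columns are preserved in ``CostItem.meta``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path, dtype={"item_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ledger file {path} missing required column(s): {missing}")

    items = []
    for row in df.to_dict(orient="records"):
        it = _row_to_item(row, normalized_default=True)
        if it.unit_price.currency == "USD" and it.unit_price.nominal_year != config.base_year:
            it.unit_price = replace(it.unit_price, normalized=False)
        items.append(it)
    items = split_spread_items(items, config.plan)

    if isinstance(facilities, (str, Path)):
        fac = load_facilities(facilities)
    elif facilities is not None:
        fac = list(facilities)
    else:
        fac = list(config.facility_set)

    ledger = Ledger(items=items, facilities=fac, config=config)
    diags = validate_ledger(ledger)
    errors = [d for d in diags if d.rule != "volume_bounds"]
    if errors:
        raise ValidationError(
            "ledger failed validation: " + "; ".join(str(d) for d in errors)
        )
    return ledger


def ledger_to_frame(ledger: Ledger) -> pd.DataFrame:
    """Flatten a ledger to the documented CSV column layout (canonical order)."""
    rows = []
    meta_cols = sorted({k for it in ledger.items for k in it.meta})
    for it in ledger.items:
        row = {
            "item_id": it.item_id,
            "scenario": it.scenario.value,
            "country": it.country.value,
            "component": it.component.value,
            "input_category": it.input_category.value,
            "phase": it.phase.value,
            "currency": it.unit_price.currency,
            "nominal_year": it.unit_price.nominal_year,
            "nominal_month": it.unit_price.nominal_month,
            "unit_price": it.unit_price.value,
            "quantity": it.quantity,
            "quantity_unit": it.quantity_unit,
            "proration_fraction": it.proration_fraction,
            "useful_life_years": it.capital_spec.useful_life_years if it.capital_spec else None,
            "acquisition_mode": it.capital_spec.acquisition_mode.value if it.capital_spec else None,
            "control_pertinent": it.control_pertinent,
        }
        for k in meta_cols:
            row[k] = it.meta.get(k)
        rows.append(row)
    df = pd.DataFrame(rows, columns=LEDGER_COLUMNS + meta_cols)
    return df.sort_values("item_id", kind="stable").reset_index(drop=True)


def write_ledger(ledger: Ledger, path: Union[str, Path]) -> None:
    """Write a ledger to CSV in canonical (item_id-sorted) order."""
    ledger_to_frame(ledger).to_csv(path, index=False)


def load_facilities(path: Union[str, Path]) -> list:
    df = pd.read_csv(path, dtype={"facility_id": str})
    missing = [c for c in ("facility_id", "country", "monthly_deliveries") if c not in df.columns]
    if missing:
        raise SchemaError(f"facilities file {path} missing column(s): {missing}")
    out = []
    for row in df.to_dict(orient="records"):
        out.append(
            FacilityProfile(
                facility_id=str(row["facility_id"]),
                country=_parse_enum(Country, row["country"], row["facility_id"], "country"),
                monthly_deliveries=int(row["monthly_deliveries"]),
                arm=Arm.INTERVENTION if _is_blank(row.get("arm"))
                else _parse_enum(Arm, row["arm"], row["facility_id"], "arm"),
                size_class=SizeClass.SMALL if _is_blank(row.get("size_class"))
                else _parse_enum(SizeClass, row["size_class"], row["facility_id"], "size_class"),
            )
        )
    return out


def write_facilities(facilities: Iterable[FacilityProfile], path: Union[str, Path]) -> None:
    rows = [
        {
            "facility_id": f.facility_id,
            "country": f.country.value,
            "monthly_deliveries": f.monthly_deliveries,
            "arm": f.arm.value,
            "size_class": f.size_class.value,
        }
        for f in facilities
    ]
    pd.DataFrame(rows, columns=FACILITY_COLUMNS).to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Read a ScenarioConfig from YAML or JSON.

    Facilities may be embedded under ``facilities`` (list of mappings) or
    referenced via ``facilities_csv`` (path relative to the config file).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    fac = []
    if "facilities" in raw:
        for f in raw.pop("facilities"):
            fac.append(
                FacilityProfile(
                    facility_id=str(f["facility_id"]),
                    country=Country(f["country"]),
                    monthly_deliveries=int(f["monthly_deliveries"]),
                    arm=Arm(f.get("arm", "INTERVENTION")),
                    size_class=SizeClass(f.get("size_class", "SMALL")),
                )
            )
    if "facilities_csv" in raw:
        fac.extend(load_facilities(path.parent / raw.pop("facilities_csv")))
    plan = ImplementationPlan(**raw.pop("plan")) if "plan" in raw else ImplementationPlan()
    cfg = ScenarioConfig(
        scenario=Scenario(raw.get("scenario", "MOH_MODEL")),
        facility_set=fac,
        plan=plan,
        nm_model=raw.get("nm_model", "EMBEDDED_PER_FACILITY"),
        adaptation_intensity=float(raw.get("adaptation_intensity", 1.0)),
        maintenance_intensity=raw.get("maintenance_intensity", "BASE"),
        specialist_ratio=tuple(raw.get("specialist_ratio", (5, 8))),
        trained_workers_per_facility=tuple(raw.get("trained_workers_per_facility", (8, 15))),
        base_year=int(raw.get("base_year", 2020)),
        currency_set=tuple(raw.get("currency_set", ("KES", "UGX", "USD"))),
    )
    return cfg


# ---------------------------------------------------------------------------
# Validation (diagnostics, not exceptions)

def validate_ledger(ledger: Ledger) -> list:
    """Check every domain-type invariant; return one diagnostic per breach."""
    diags = []
    seen = set()
    countries_with_fac = {f.country for f in ledger.facilities}
    for it in ledger.items:
        if it.item_id in seen:
            diags.append(Diagnostic(it.item_id, "item_id", "unique", "duplicate item_id"))
        seen.add(it.item_id)
        if it.quantity < 0:
            diags.append(Diagnostic(it.item_id, "quantity", "non_negative", f"{it.quantity} < 0"))
        if not 0.0 <= it.proration_fraction <= 1.0:
            diags.append(
                Diagnostic(it.item_id, "proration_fraction", "unit_interval",
                           f"{it.proration_fraction} outside [0, 1]")
            )
        if it.unit_price.value < 0:
            diags.append(Diagnostic(it.item_id, "unit_price", "non_negative",
                                    f"{it.unit_price.value} < 0"))
        if it.unit_price.currency not in ledger.config.currency_set:
            diags.append(
                Diagnostic(it.item_id, "currency", "currency_set",
                           f"{it.unit_price.currency!r} not in {ledger.config.currency_set}")
            )
        if it.component is Component.GENERAL and it.control_pertinent is None:
            diags.append(
                Diagnostic(it.item_id, "control_pertinent", "general_requires_flag",
                           "GENERAL-component items must state control pertinence")
            )
        if it.capital_spec is not None and it.capital_spec.useful_life_years <= 0:
            diags.append(
                Diagnostic(it.item_id, "useful_life_years", "positive",
                           f"{it.capital_spec.useful_life_years} <= 0")
            )
        if it.country not in countries_with_fac:
            diags.append(
                Diagnostic(it.item_id, "country", "facility_coverage",
                           f"no facility for country {it.country.value}")
            )
    fac_seen = set()
    for f in ledger.facilities:
        if f.facility_id in fac_seen:
            diags.append(Diagnostic(f.facility_id, "facility_id", "unique", "duplicate facility_id"))
        fac_seen.add(f.facility_id)
        lo, hi = ledger.config.volume_bounds.get(f.country, (1, math.inf))
        if not lo <= f.monthly_deliveries <= hi:
            diags.append(
                Diagnostic(f.facility_id, "monthly_deliveries", "volume_bounds",
                           f"{f.monthly_deliveries} outside [{lo}, {hi}] for {f.country.value}")
            )
    return diags


# ---------------------------------------------------------------------------
# Packaged fixtures

@lru_cache(maxsize=None)
def _fixture_frame_cached(name: str) -> pd.DataFrame:
    text = resources.files("microcost.fixtures").joinpath(f"{name}.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def _fixture_frame(name: str) -> pd.DataFrame:
    return _fixture_frame_cached(name).copy()


def table3_fixture(country: Country) -> pd.DataFrame:
    """Published unit prices and units for the ministry-of-health scenario."""
    df = _fixture_frame("table3")
    return df[df["country"] == country.value].reset_index(drop=True)


def table5_fixture() -> pd.DataFrame:
    """Published cost summary: totals by input type and component, per
    scenario and country, plus package summary rows (as printed)."""
    return _fixture_frame("table5")


def table7_fixture() -> pd.DataFrame:
    """Published one-way sensitivity results: per-birth base/alternative cost
    pairs and printed percent differences."""
    return _fixture_frame("table7")


def _placeholder_facilities(country: Country, n: int) -> list:
    lo, hi = DEFAULT_VOLUME_BOUNDS[country]
    vol = (lo + hi) // 2
    return [
        FacilityProfile(f"{country.value}-F{i + 1:02d}", country, vol)
        for i in range(n)
    ]


def _table5_cells(scenario: Scenario, country: Country, block: str) -> pd.DataFrame:
    df = table5_fixture()
    sel = df[
        (df["scenario"] == scenario.value)
        & (df["country"] == country.value)
        & (df["block"] == block)
    ]
    if sel.empty:
        raise KeyError(f"no table5 block {block!r} for {scenario.value}/{country.value}")
    return sel


def table5_summary(scenario: Scenario, country: Country) -> dict:
    sel = _table5_cells(scenario, country, "summary")
    return dict(zip(sel["key"], sel["value"]))


def _table5_config(scenario: Scenario, country: Country) -> ScenarioConfig:
    n_fac = int(table5_summary(scenario, country)["n_facilities"])
    return ScenarioConfig(
        scenario=scenario,
        facility_set=_placeholder_facilities(country, n_fac),
    )


def table5_package_ledger(scenario: Scenario, country: Country) -> Ledger:
    """One-item ledger carrying the printed package total, for unit-cost
    division against the printed facility count.  Facility volumes are
    unpublished; placeholder mid-range volumes stand in, so only totals and
    per-facility figures are meaningful for this ledger."""
    summary = table5_summary(scenario, country)
    cfg = _table5_config(scenario, country)
    item = CostItem(
        item_id=f"{scenario.value}-{country.value}-package-total",
        scenario=scenario,
        country=country,
        component=Component.GENERAL,
        input_category=InputCategory.PERSONNEL_PROGRAM,
        phase=Phase.P2_IMPLEMENTATION,
        unit_price=MoneyAmount(float(summary["package_total"]), normalized=True),
        quantity=1.0,
        control_pertinent=False,
    )
    return Ledger(items=[item], facilities=cfg.facility_set, config=cfg,
                  provenance={"fixture": "table5", "block": "package_total"})


def table5_block_ledger(scenario: Scenario, country: Country, block: str) -> Ledger:
    """Ledger with one pre-aggregated item per printed row of the input-type
    or component block of the published cost summary."""
    if block not in ("input_type", "component"):
        raise KeyError(f"unknown table5 block {block!r}")
    sel = _table5_cells(scenario, country, block)
    cfg = _table5_config(scenario, country)
    items = []
    for _, row in sel.iterrows():
        comp = Component(row["key"]) if block == "component" else Component.GENERAL
        cat = (
            InputCategory(row["key"])
            if block == "input_type"
            else InputCategory.PERSONNEL_PROGRAM
        )
        items.append(
            CostItem(
                item_id=f"{scenario.value}-{country.value}-{block}-{row['key']}",
                scenario=scenario,
                country=country,
                component=comp,
                input_category=cat,
                phase=Phase.P2_IMPLEMENTATION,
                unit_price=MoneyAmount(float(row["value"]), normalized=True),
                quantity=1.0,
                control_pertinent=False,
            )
        )
    return Ledger(items=items, facilities=cfg.facility_set, config=cfg,
                  provenance={"fixture": "table5", "block": block})


def _table3_ledger(country: Country) -> Ledger:
    """The published unit-price table as a flat ledger (prices are already
    2020 USD; every row enters as a GENERAL/P2 line so arithmetic such as
    price x units can be exercised without invented allocations)."""
    section_to_cat = {
        "program_based": InputCategory.PERSONNEL_PROGRAM,
        "facility_based": InputCategory.PERSONNEL_FACILITY,
        "office_supplies": InputCategory.CONSUMABLES,
        "clinic_goods": InputCategory.CONSUMABLES,
        "capital": InputCategory.CAPITAL,
        "office_conf": InputCategory.OFFICE_CONF_SPACE,
        "travel": InputCategory.TRAVEL,
    }
    df = table3_fixture(country)
    cfg = ScenarioConfig(
        scenario=Scenario.MOH_MODEL,
        facility_set=_placeholder_facilities(country, 17 if country is Country.KE else 6),
    )
    items = []
    for i, row in df.iterrows():
        cat = section_to_cat[row["section"]]
        items.append(
            CostItem(
                item_id=f"t3-{country.value}-{i:02d}-{row['item']}",
                scenario=Scenario.MOH_MODEL,
                country=country,
                component=Component.GENERAL,
                input_category=cat,
                phase=Phase.P2_IMPLEMENTATION,
                unit_price=MoneyAmount(float(row["unit_price"]), normalized=True),
                quantity=float(row["units"]),
                quantity_unit=str(row["unit_label"]),
                control_pertinent=False,
                meta={"section": row["section"], "table_item": row["item"]},
            )
        )
    return Ledger(items=items, facilities=cfg.facility_set, config=cfg,
                  provenance={"fixture": "table3", "country": country.value})


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``table3_ke`` / ``table3_ug`` return the unit-price table as a Ledger;
    ``table5`` and ``table7`` return the printed summary tables as DataFrames.
    """
    if name == "table3_ke":
        return _table3_ledger(Country.KE)
    if name == "table3_ug":
        return _table3_ledger(Country.UG)
    if name == "table5":
        return table5_fixture()
    if name == "table7":
        return table7_fixture()
    raise KeyError(f"unknown fixture {name!r}")
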
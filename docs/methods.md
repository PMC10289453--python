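# Methods

## Costing model

The engine implements bottom-up, activity-based micro-costing of an
intrapartum quality-improvement package from a healthcare-system
perspective. Costs are *incremental*: they cover planning, implementing and
maintaining the program on top of existing intrapartum care, and exclude
downstream changes in medical care, patient/community costs, and new
clinical staff (facility workers are existing employees whose program time
is an opportunity cost).

Every resource or activity is one ledger line with a unit price, a quantity
(months of effort, units printed, return trips, person-days, bundles of 100
checklists — the unit label is free text, arithmetic uses the number as-is),
and a proration fraction for shared resources (share of office time, share
of facilities lacking a good, share of a meeting spent on the program).
Lines are keyed to a scenario (study-observed vs hypothetical
ministry-of-health model), country (Kenya/Uganda), phase, intervention
component (data strengthening, checklist, simulation training, QI
collaboratives, or general/non-allocable) and input category (three
personnel classes, consumables, capital, office/conference space, travel).

### Money normalization

Nominal amounts are converted to USD at the exchange rate of the invoice
date — monthly rate when the ledger records a month, annual average
otherwise — then inflated to base-year (2020) terms by compounding annual
within-country inflation over the years strictly after the nominal year
through the base year. No half-year conventions, no PPP adjustment, no
discounting (the horizon is ~3 years). Amounts carry a `normalized` flag
and a second normalization is an error, so no total can be double-adjusted.
USD-denominated lines follow the program country's inflation chain by
default (the country whose ledger they sit in); a US chain can be supplied
via a custom rate table. The package ships only a clearly-labelled synthetic
test rate table; the packaged price table is already in 2020 USD, so the
headline paths need no rates at all.

### Capital goods

Durables carry a useful life drawn from the 3–5-year replacement cycle.
Two acquisition modes: *point purchase with replacement* buys
`ceil(program months / life months)` units over the horizon (the default;
with the default 36-month program and any life ≥ 3 years this is exactly
one acquisition); *straight-line annualization* instead charges the
fractional share of the asset's life the program consumes. Non-positive
lives are rejected.

### Phases and denominators

Default plan: 9 months design/planning (range 6–9), 15 months
high-intensity implementation (12–18), 12 months maintenance; phases 2 + 3
give the 27 in-facility months behind the per-birth denominator. Items
spanning all phases may be entered with phase `GENERAL` and are split at
load time into three single-phase rows weighted by phase months, keeping
every partition exactly additive. Unit costs:

* per facility = total / facility count;
* per birth = total / Σ(monthly deliveries × 27) — all deliveries from 28
  weeks gestation, live or stillborn; the facility volume field is assumed
  to already reflect that inclusion rule;
* steady-state per birth = maintenance-phase cost / Σ(monthly deliveries ×
  12), the recurring annual cost once high-intensity implementation ends.

Zero facilities or zero births is a guarded error, not an infinity. An
empty item list with a valid facility set yields an all-zero report.

### Staffing rule

The ministry model adds two specialist roles (data/checklist oversight;
simulation/QI oversight). Requirement per role:
`max(1, ceil(n_small/8.5 + n_large/5))` — one specialist per ~8–9 small or
4–6 large facilities, combined fractionally before rounding up. Size
classes split at 100 deliveries/month in Kenya and 150 in Uganda.

### Control arm

The active control receives data strengthening and the checklist only.
`control_filter` keeps those two components plus general/non-allocable items
explicitly flagged control-pertinent, at their `control_proration` (clamped
to never exceed the package proration, so a control arm can never cost more
than the package). The flag is explicit because no apportioning rule for
shared activity between arms is published; the generator flags shared rows
at 0.5, i.e. half of the shared activity would still occur for the control.

### Sensitivity framework

One-way only: each named perturbation rewrites a copy of the base ledger,
and the per-birth cost difference is reported as a half-up signed integer
percent (raw decimals retained in JSON). Perturbations never compound.
Interpretations chosen where the published description is qualitative:

* *travelling nurse mentors* — embedded-mentor effort rows (tag
  `nm_embedded`) are removed and replaced by hired mentors at one per 3–6
  facilities (default midpoint 4.5), salaried over the 27 in-facility
  months, plus facility-visit travel at the ledger's local-trip price
  (default 2 trips/facility/month); mentor-training rows stay, since hired
  mentors also need training;
* *doubled adaptation* — planning-phase rows tagged `adaptation` double in
  quantity (fallback: all planning-phase rows, for untagged user ledgers);
* *high-intensity maintenance* — maintenance-phase simulation-training and
  QI rows double, reading "2 days/month instead of 1" and "quarterly
  instead of semi-annual" as a ×2 frequency on those components;
* *facility-mix swap* — the facility set is replaced and quantities rescale
  by each row's declared scaling law: `per_facility` rows with the facility
  count, `per_birth` rows (e.g. checklist printing) with total births,
  `fixed` rows not at all — a linear scaling chosen because no empirical
  scaling law is published;
* *exclude facility worker time* — drops facility-personnel rows except
  mentor training, quantifying how much of the total is opportunity cost of
  salaried staff rather than new outlay.

## Packaged reference tables

The published unit-price table (ministry scenario, both countries), the
cost-summary table and the sensitivity table are transcribed verbatim as
CSV fixtures. Known internal inconsistencies of the printed summary are
preserved, not repaired: input-type and component columns do not re-sum
exactly to the printed package totals (Kenya ministry model: 858,428 and
858,427 vs 858,445; the study-observed columns differ by more), so
per-facility figures are computed from the printed package totals (the
published division) and component shares from the printed component rows
(which reproduce the published percentages exactly). Two reconstructions
disagree with print by one unit and are asserted as documented differences:
the study-scenario Kenya per-facility division ($123,230 vs printed
$123,229 — the publication divided an unrounded total) and the Uganda
facility-mix row (+48% recomputed from $5.47 → $8.11 vs printed +49%).
Likewise the Uganda ministry-model personnel share computes to 73% from the
printed rows while the text states 72%; the engine reports the computed
value and tests assert the published "at least 72%" bound.

## Synthetic generator

The generator makes every stage testable without external data (the
study-observed unit prices are unpublished, as are facility-level volumes).
What it emulates:

* **Facility sets** — 17 Kenyan facilities with 30–360 deliveries/month,
  most under 100; 6 Ugandan with 90–585, most over 150. Volumes come from a
  two-component uniform mixture (probability 0.7 on the majority side of
  the size threshold, 0.3 on the other), with minority flips re-drawn when
  a draw would break the strict majority. The mixture is the simplest
  distribution honoring "most facilities" without inventing shape.
* **Quantities** — the published effort/unit skeleton, re-derived from the
  generated facility set: specialist months scale with the staffing rule
  (baseline two specialists per role); trained-worker-driven rows
  (nurse/midwife time, manuals, training packets) scale with uniform
  integer 8–15 trained workers per facility; per-facility rows with
  facility count; checklist printing with total births (one bundle per 100
  births). Capital lives are uniform on [3, 5] years.
* **Prices** — published unit prices with multiplicative lognormal jitter
  (±10% default, truncated at 3σ to stay positive). Study-observed ledgers
  apply a ×3 private-salary premium to program/consultant personnel
  (midpoint of the observed two-to-five-fold public/private gap) and double
  consultant effort.
* **Calibration** — after generation, quantities are rescaled uniformly
  within each input category so the ledger's category cost mix equals the
  published mix for its scenario/country (leaving the grand total at its
  pre-calibration value). This pins the structural feature the analysis
  turns on — personnel at ≥ 72% of total (88% Kenya, 73% Uganda in the
  ministry model) — for every seed, while volumes, staffing, worker counts
  and within-category composition still vary.
* **Bookkeeping oracle** — each ledger records its construction total,
  accumulated line-by-line while being built, which tests compare against
  the engine's aggregation exactly.

Phase/component splits and tags for each skeleton row (who does adaptation,
which rows are embedded-mentor effort, what scales with births) are not
published at row level; `synthgen.ROW_PLAN` encodes one fixed, documented
allocation consistent with the published phase structure and component
descriptions. Consequently generated ledgers match the study's input-
category mix exactly but its component mix and phase mix only loosely
(e.g. the synthetic Uganda simulation-training share runs ~10 points above
the published 44%), and per-birth dollar levels depend on the unpublished
facility volumes — so passing tests demonstrate the engine's arithmetic,
invariances and perturbation semantics, not agreement of synthetic dollar
levels with the published per-birth costs ($23.91 Kenya, $5.47 Uganda),
which cannot be recomputed from published inputs.

## Numerical choices

* Full float precision throughout; dollars to whole dollars, per-birth to
  cents, percents to integers only at presentation, ties away from zero
  (matching the published tables' rounding; component shares may not sum
  to 100).
* Ledger item identity is the `item_id`; loaders raise on schema errors
  (missing column, bad enum, negative price/quantity, proration outside
  [0, 1]) naming the item, while `validate_ledger` returns diagnostics
  (item, field, rule) without raising so a file's problems are reported
  together. Out-of-range facility volumes are advisory diagnostics, not
  load errors, since the bounds are generator defaults and overridable.
* Determinism: all generator randomness flows from one integer seed through
  two independent, seed-derived streams (facilities; prices/quantities);
  machine outputs are byte-stable and the run manifest hashes configuration
  and inputs with the timestamp excluded.
* Test sizes: the additivity/partition/control property suite runs on
  1,000 seeded ledgers and the facility-constraint suite on 100 seeds per
  country — sizes at which the whole suite stays in seconds while covering
  both countries and scenarios.

## Limitations

* One scenario per ledger; cross-scenario comparison happens at the report
  level (the two scenarios' price sets are never guaranteed co-resident).
* No probabilistic sensitivity analysis, multi-way grids, overhead
  step-down allocation, discounting, or cost-effectiveness ratios
  (effectiveness is out of scope).
* The currency set defaults to KES/UGX/USD and the rate table ships empty;
  users supply their own series for real nominal-ledger work.
* Synthetic study-observed ledgers are structural stand-ins only; no
  attempt is made to match the withheld study-observed price list.
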
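# microcost

Activity-based micro-costing for facility-level maternal and newborn health
programs, built around the cost analysis of a four-component intrapartum
quality-improvement package (data strengthening, a modified WHO Safe
Childbirth Checklist, PRONTO simulation/team training, and Quality
Improvement collaboratives) implemented in 17 Kenyan and 6 Ugandan delivery
facilities, with a minimal active control (data strengthening + checklist).

The package is for health economists and program planners who need to turn a
line-item cost ledger — every priced, quantified, prorated activity and
resource — into incremental program costs from a healthcare-system
perspective: totals in base-year (2020) US dollars, broken down by country,
implementation phase, intervention component and input category, with unit
costs per facility and per birth, control-arm comparison, and one-way
sensitivity analysis.

## Model

For line item *i* with nominal unit price *p_i* (KES, UGX or USD, dated),
quantity *q_i*, proration fraction *f_i* ∈ [0, 1] and capital acquisition
multiplier *a_i*:

```
cost_i = N(p_i) · q_i · f_i · a_i
```

where the normalization `N` converts at the invoice-dated exchange rate
(monthly when known, else the annual average) and compounds annual
within-country inflation up to the base year:

```
N(p) = p · fx(currency, date) · Π_{y = year+1 .. 2020} (1 + π_country(y))
```

Capital goods (laptops, projectors, simulation kits, mannequins) carry a
3–5-year useful life; under point purchase with replacement
`a = ceil(program months / life months)`, under straight-line annualization
`a = program months / life months`.

The program runs in three phases — design/planning (9 months),
high-intensity implementation (15 months), annual maintenance (12 months) —
and unit costs use:

```
per facility        = total / n_facilities
per birth           = total / Σ_facilities (monthly deliveries × 27)
per birth, phase 3  = phase-3 cost / Σ_facilities (monthly deliveries × 12)
```

27 months = phases 2 + 3 of in-facility activity. Staffing for the two new
specialist roles follows the rule of one specialist per 5–8 facilities
depending on volume (fractional combination of ~8.5 small or 5 large
facilities per specialist, rounded up, minimum one).

## Worked example

Generate a synthetic Ugandan ministry-model ledger (seeded, with the study's
facility-volume structure and input-category cost mix), cost it with the
control arm, and run the standard one-way sensitivity set:

```
microcost synth --country UG --seed 7 --out demo
microcost cost --ledger demo/ledger.csv --facilities demo/facilities.csv \
    --out demo/cost --control
```

prints (abridged):

```
Package cost report
===================

Number of facilities                   6
Total births (phases 2-3)         35,505
Package total (2020 $US)    $    157,418
Per facility                $     26,236
Per birth (all phases)      $       4.43
Per birth (maintenance)     $       1.97

Cost by input type
  PERSONNEL_PROGRAM         $     26,173
  PERSONNEL_CONSULTANT      $     52,390
  PERSONNEL_FACILITY        $     36,704
  ...

Control arm (DS & mSCC)
=======================
Package total (2020 $US)    $     46,494
Per birth (all phases)      $       1.31
```

The six facilities deliver 35,505 births over the 27 in-facility months; the
package costs $4.43 per birth ($1.97 per birth at steady state), and
personnel make up 73% of total cost — the calibrated study-level mix. The
minimal control arm (data strengthening + checklist, plus its flagged share
of general activity) costs $1.31 per birth.

```
microcost sensitivity --ledger demo/ledger.csv --facilities demo/facilities.csv \
    --perturbations perts.yaml --out demo/sens
```

```
One-way sensitivity (cost per birth)
------------------------------------------------------------
nm_travelling                    $   4.43 -> $   4.98  +12%
adaptation_2x                    $   4.43 -> $   6.22  +40%
maintenance_high                 $   4.43 -> $   4.80  +8%
exclude_worker_time              $   4.43 -> $   3.42  -23%
```

Each row perturbs the unperturbed base independently: hiring travelling
nurse mentors instead of facility-embedded ones raises per-birth cost 12%;
doubling planning-phase adaptation effort raises it 40%; excluding
facility-based health-worker time (an opportunity cost, not a new outlay)
lowers it 23%.

The same operations run from Python:

```python
import microcost as mc
from microcost.synthgen import GeneratorParams, generate_ledger

ledger = generate_ledger(GeneratorParams(seed=7, country=mc.Country.UG))
report = mc.aggregate_costs(ledger)
print(report.rounded()["per_birth"])   # 4.43
```

## Layout

- `microcost.ledger` — domain types, CSV/JSON ledger I/O, validation
  diagnostics, packaged transcriptions of the published tables
- `microcost.monetary` — exchange-rate/inflation normalization to 2020 USD
- `microcost.engine` — line-item costing, amortization, staffing rule,
  birth denominators, aggregation, control-arm filter
- `microcost.sensitivity` — named perturbations and the one-way table
- `microcost.synthgen` — seeded synthetic ledger/facility generator
- `microcost.cli` — `microcost cost|sensitivity|synth|validate`
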
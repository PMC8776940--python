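# fpkpi

Family-planning service-statistics KPIs for governorate-level management
information systems (MIS), modelled on Egypt's Ministry of Health and
Population family-planning reporting chain.

National family-planning programmes collect quarterly counts per
governorate — clients by age band and parity, current users by
contraceptive method, visit and client types, reasons for the visit, and
contraceptive quantities dispensed — but often publish them as raw
spreadsheets of counts. `fpkpi` turns those counts into decision-ready
indicators: couple-years of protection (CYP), the contraceptive coverage
rate (CCR), fifteen key performance indicators plus three contextual
input indicators, fixed-order regional rollups, traffic-light governorate
league tables, and a three-page annual report with policy-brief
scaffolds. It is aimed at programme analysts and M&E staff working with
DHIS2-style aggregate service statistics.

## The statistics at the core

**Couple-years of protection** converts dispensed quantities into the
number of couples protected from pregnancy for one year. Resupply
methods divide units by annual consumption; long-acting methods multiply
units by average years of protection:

| method | conversion (Egypt registry) |
|---|---|
| pills (cycles) | ÷ 13 |
| condoms (units) | ÷ 100 |
| IUD (units) | × 3.2 |
| three-month injectable (vials) | ÷ 4 |
| monthly injectable (vials) | ÷ 13 |
| implant (units) | × 2 |
| sterilization (procedures) | × 10 |

So four three-month injectable vials are one CYP; one IUD is 3.2 CYP.
Any country's factors can be swapped in from a CSV.

**Contraceptive coverage rate** is a service-statistics proxy for
contraceptive prevalence:

```
CCR = 100 × CYP dispensed in the period / MWRA in the catchment area
```

where MWRA is the number of married women of reproductive age. It can
exceed 100 where long-acting methods dominate.

**League tables.** Each governorate holds a fixed position (1–27, urban →
lower Egypt → upper Egypt → frontier) in every report. For an indicator,
governorates are sorted best-first with competition ranking (ties share
the best rank) and split into three traffic-light groups — best (green),
prospective (yellow), unfavorable (red) — at configurable percentile
cut-points of the value distribution (tertiles by default, nearest-rank
percentiles computed on values so ties never straddle a boundary).

The package also ships a transcription of the published 2014 national
tables (15,799,805 MWRA, 6,038 clinics, 13,670,104 method users) and a
seeded synthetic generator calibrated to that profile, so the whole
pipeline runs and is tested without any external data.

## Worked example

```python
from fpkpi import *
from fpkpi.aggregate import merge_quarters
from fpkpi.report import build_rank_tables, compute_profiles
from fpkpi.synthetic import default_egypt_config, generate_quarter

rules = egypt_2014_rules()
print("CYP(4 three-month vials) =", cyp_for_method(MethodCategory.INJECTABLE_3M, 4, rules))
print("CYP(1 IUD)               =", cyp_for_method(MethodCategory.IUD, 1, rules))

config = default_egypt_config(seed=7)          # 2014 national conditions
sheets = [generate_quarter(config, Period(2014, q)) for q in (1, 2, 3, 4)]
annual = merge_quarters(sheets)
profiles = compute_profiles(annual, config.reference())
nat = profiles.national
print(f"national clients        = {annual.national_row.total_clients:,}")
print(f"national OC share       = {nat.method_mix[0]:.1f}%")
print(f"national CCR            = {nat.ccr:.1f}%")
top = build_rank_tables(profiles.governorates)["ccr"].entries[0]
print(f"CCR league leader       = {top.governorate.name} ({top.value:.1f}%, {top.category})")
```

prints

```
CYP(4 three-month vials) = 1.0
CYP(1 IUD)               = 3.2
national clients        = 13,852,043
national OC share       = 54.0%
national CCR            = 32.8%
CCR league leader       = Luxor (72.9%, green)
```

One simulated year produces ~13.85 M clinic visits, an oral-contraceptive
share of 54% of current users (the configured national method mix), and
a national CCR of ~33% implied by the default dispensing rates. The
league leader is whichever governorate's dispensed CYP is largest
relative to its MWRA — here Luxor, whose simulated client volume is
large for its small denominator.

The same pipeline is available from a shell:

```sh
fpkpi simulate --seed 7 --out data/
fpkpi report --quarters data/quarter_2014Q1.csv --quarters data/quarter_2014Q2.csv \
             --quarters data/quarter_2014Q3.csv --quarters data/quarter_2014Q4.csv \
             --ref data/reference.csv --out report/
```

which writes the two page tables (CSV), the four colour-ranked charts
(SVG), the assembled report (HTML), per-governorate policy-brief
scaffolds, and a resolved-config snapshot. `fpkpi compute --fixture-2014`
exports the published 2014 indicator values in the same table shape.

## Layout

| module | role |
|---|---|
| `fpkpi.schema` | governorate/region registry, method categories, count bundles, validation |
| `fpkpi.ingest` | strict CSV dialect for sheets and the MWRA reference |
| `fpkpi.cyp` | CYP conversion rules and the CCR |
| `fpkpi.kpi` | the 18-indicator catalog and profile computation |
| `fpkpi.aggregate` | quarter merging and exact regional/national rollups |
| `fpkpi.ranking` | competition ranking and traffic-light categorisation |
| `fpkpi.report` | three-page annual report and policy-brief scaffolds |
| `fpkpi.synthetic` | seeded generator + the packaged 2014 fixture |
| `fpkpi.cli` | `fpkpi` subcommands: simulate, ingest, compute, rank, report |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
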
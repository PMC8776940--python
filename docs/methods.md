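# Methods

## The data model

The unit of analysis is the governorate-period aggregate. A
`ServiceCounts` bundle records, for one governorate and one quarter (or
year), five partitions of the same client total — age band (<20, 20–24,
25–29, 30–34, 35+), parity (0, 1, 2, 3, 4+), visit type (first/return),
client type (new/continuing) and reason for visit (get method,
counseling, reproductive-health services, side-effect management) —
plus current users of the six recorded method groups and dispensed
quantities per method. Validation enforces non-negativity, equality of
the partition sums, and that method users never exceed total clients
(they may fall short: non-users attend for counseling and other
services; in the 2014 national tables 13,846,714 clients vs 13,670,104
users).

Sterilization is dispensable — it enters couple-years arithmetic with a
×10 factor — but carries no current-user count, mirroring the source
sheets, which list six current-method groups only.

The 27 governorates hold fixed positions 1–27 ordered urban (4), lower
Egypt (9), upper Egypt (9), frontier (5), with the within-region order
of the published 2014 tables. Name handling is table-driven: the
spelling variants seen in circulating tables ("Menofeya",
"Kafr-Elshieikh", "Mynia", "N Saini", …) are canonicalised explicitly;
anything else is a hard error, never a fuzzy match, because a silent
mis-assignment would corrupt league tables.

## CYP and CCR

Couple-years of protection divides resupply quantities by annual
consumption (pills 13 cycles, condoms 100 units, three-month injectable
4 vials, monthly injectable 13 vials — kept exactly as the packaged
registry prints it) and multiplies long-acting units by average years of
protection (IUD 3.2, implant 2, sterilization 10). CCR is
100 × CYP / MWRA. Two deliberate conventions:

- **Sub-annual CCR** uses the CYP dispensed in the period against the
  *annual* MWRA denominator with no annualisation. CYP is already in
  couple-year units, so quarterly CCRs sum approximately to the annual
  CCR, which is the property an MIS report needs.
- **As-reported CCR.** Sheets may carry a precomputed CCR instead of
  dispensed quantities. When only the reported value exists it is used
  and flagged `ccr_as_reported`; when both exist the recomputed value
  wins and a disagreement beyond 0.5 percentage points is logged.

MWRA and clinic counts are stocks: rollups sum them across governorates
but never across quarters.

## Indicators

Eighteen indicators: eight client-profile indicators (% aged 35+, %
with fewer than three children, and the six-way method mix of current
users), seven performance indicators (% first-visit, % new clients, the
four reason shares, CCR), and three contextual input indicators (share
of national MWRA, share of national clinics, clinics per 10,000 MWRA).
Every share is a ratio of summed counts; percentages are never
averaged, so a region's profile from summed counts equals the profile
of summed numerators and denominators exactly (asserted to 1e-9 in the
tests). Zero-denominator shares are NaN — "undefined", deliberately
distinct from a true zero — and refuse to be ranked.

Choices made where the design was open:

- The parity headline is stored as *% with fewer than three children*
  (the complement, % with 3+, is derivable); the age headline % aged 35+
  is computed but left direction-neutral for ranking, since a high value
  marks a priority group rather than good or bad performance.
- The method-mix denominator defaults to current users (the published
  per-governorate table convention); a switch recomputes it over all
  clients (the published national summary convention). The two
  denominators are what separates a 54% from a 53.1% oral-contraceptive
  share on the same 2014 data.
- Display rounding is half-up to integers at ≥10 and one decimal below
  10, matching the published tables; full precision is retained
  internally and in `export_profiles_csv`.

## Ranking and traffic-light categories

Sorting is best-first by the indicator's direction with competition
ranking (tied values share the best rank; display order among ties
follows fixed position). Categories come from nearest-rank percentile
cut-points of the value distribution — tertiles (33.3/66.7) by default,
fully configurable. For higher-is-better indicators, values at or above
the upper cut are green and at or below the lower cut are red; for
lower-is-better the comparisons flip while the data do not. Cut-points
are computed on values rather than ranks so tied governorates always
share a category, which also gives monotone consistency (a strictly
better value never receives a worse category). A degenerate all-equal
distribution is all green by convention. The published charts never
state their cut-points (one of them even shows a two-group 10/17
split), so no attempt is made to reproduce exact published group
memberships; the scheme is a parameter.

## The three-page report

Page 1: 32 rows (27 governorates, 4 region rows, national) × the eight
profile indicators. Page 2: the same rows × the seven performance
indicators. Page 3: four horizontal bar charts (first visit, new
clients, get-method, CCR), bars ordered best-first and coloured by
category. Artifacts are CSV, SVG and HTML only; rendering is
deterministic (fixed SVG hash salt, no timestamps) so identical inputs
give byte-identical files. Policy briefs are scaffolds — Title phrased
as a suggested recommendation, Introduction, Major Results listing the
unit's red-category indicators, Recommendation — with the free text
left as placeholders: interpretation belongs to programme staff, and
the report itself carries no narrative.

## The synthetic generator

Per governorate and quarter: client total N ~ Poisson(expected volume);
each categorical partition multinomial(N, simplex); current users
Binomial(N, p_user) allocated over the six-method mix; dispensed
quantities Poisson(users × rate) per method. One numpy `default_rng`
seeded from (seed, year, quarter) drives the draws in registry order,
so a given seed/config/period is bit-reproducible.

Defaults encode the 2014 national profile: volumes proportional to each
governorate's published user total (13.85 M annual clients), method mix
from the published national counts (OC 54.0%, three-month injectable
30.9%, …), p_user = 0.987, first-visit 21%, new-client 11%. Where only
margins are published the interior is interpolated once: age bands
(0.032, 0.19, 0.28, 0.224, 0.274) match the published 3.2% under-20 and
27.4% aged 35+; parity (0.04, 0.20, 0.344, 0.24, 0.176) matches 41.6%
with 3+ children. The published reason shares exceed 100 when summed
(83 + 14.4 + 5.6 + 19.9); the generator keeps the 83% get-method
headline and renormalises the other three into the remaining 17%.
Dispensing rates per current user per quarter (OC 4 cycles, condoms 30,
IUD 0.5 insertions, three-month injectable 1 vial, monthly injectable
4, implant 0.5; sterilization 0.0002 per method user, as it has no user
count) are free parameters the source never states; they were fixed
once so the implied national CCR (~33%) falls mid-band in the plausible
25–60% range of the published governorate coverage table.

What the generator does *not* emulate: quarter-to-quarter seasonality
or serial correlation, governorate-specific method mixes and visit
behaviour (all governorates share the national simplices),
client-level structure, and reporting errors. Passing tests therefore
demonstrate correctness of the accounting, aggregation, ranking and
rendering machinery under the stated sampling model — not robustness to
the messiness of real MIS submissions beyond what validation rejects.

## The packaged 2014 fixture

Three CSVs transcribe the published annual tables cell-for-cell:
coverage/denominators, method users, visits/reasons — counts where
counts were printed, shares where only shares were printed (share-only
cells carry no count invariants). Quirks handled explicitly: the
S. Sinai MWRA share printed as "o.1" is recorded as 0.1 with a note;
Cairo's get-method/counseling cells are ambiguous in the printed layout
and are left unparsed rather than guessed, so the get-method league
table built from the fixture has 26 entries. Per-governorate MWRA and
clinic counts are not printed; `paper_fixture_2014()` reconstructs them
by largest-remainder apportionment of the printed shares against the
printed national totals (15,799,805 and 6,038), which reproduces those
totals exactly while tracking each printed share to within one unit of
rounding. The national CCR of 37% cannot be recomputed from first
principles — the dispensed quantities behind it were never published —
so it is carried as-reported.

## Problem sizes and numerics

The test suite runs the generator at pilot volume (volume_scale ≈ 0.002,
~28,000 clients/year) for speed, and the acceptance script runs one
full-scale year (~13.8 M clients) plus 200 replicates at ~100,000
clients for parameter recovery; both finish in seconds. Counts are
exact integers throughout — conservation checks use equality, not
tolerances. Dispensed quantities are floats; quarter merging sorts
sheets into canonical quarter order before summation so the merge is
independent of input order. CSV round-trips write floats with `repr`,
which is lossless for IEEE doubles.

## Known limitations

- League tables with configurable centiles cannot reproduce the exact
  published colour groupings (cut-points unstated at source).
- The generator's shared national simplices understate between-
  governorate heterogeneity; governorate-level rankings on synthetic
  data mostly reflect volume and denominator differences.
- No district- or clinic-level modelling; the governorate aggregate is
  the smallest unit.
- No trend analysis across years; each annual report stands alone.
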
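# Methods

This note documents the models, conventions, and design choices behind
`peddose`, in the spirit of a package methods appendix: what each component
computes, which knobs matter, and what the synthetic fixtures do and do not
establish about real clinical data.

## The dosing-region model

A *dosing region* maps a constellation of patient criteria to a single dose
prescription. Criteria are axis-aligned: numeric intervals over
chronological age (days), post-conceptual age (days), and dosing weight
(kg), each bound carrying its own inclusivity flag, plus set-valued criteria
over care areas and indications and a three-valued renal-status field
(`any`/`impaired`/`not_impaired`). Unconstrained set criteria are stored as
an explicit `ANY` token, never as an absent field, so "unconstrained" can
never be conflated with "not yet entered". All masses are normalized to mg
and all weights to kg at load time; a rule authored as "1 g" and one
authored as "1000 mg" are identical objects after loading. Calendar-free
conversions are fixed at 1 year = 365.25 days, 1 month = 30.4375 days.

Boundary semantics are clinically material (a "< 8 kg" row and a "≥ 8 kg"
row meet at exactly 8 kg) and are preserved exactly as authored. Where the
source table leaves a boundary ambiguous (e.g., an "8 days–14 yrs" band
adjacent to a "14–18 yrs" band), the bundled fixture closes the lower bound
and opens the upper so the bands partition the axis.

### Overlap validation

`validate_kb` reports any pair of same-drug regions that some synthetic
patient satisfies simultaneously. Detection uses grid sampling rather than
symbolic interval algebra: ages 0–18 y at a 5-day stride, weights
0.4–100 kg at 0.1 kg, with categorical criteria checked by set
intersection. At clinical KB scale (thousands of regions, criteria authored
on coarse clinical lattices) this is exact in practice and trivially
testable against an independent point-enumeration oracle. The bundled
fixture deliberately keeps one authored ambiguity — two ICU neonate rows
that both admit a ≥ 8 kg neonate — and the validator flags it instead of
inventing a precedence rule.

## Resolution

Given a drug and a patient, the resolver filters the drug's regions by every
parameter whose value is known. Age, dosing weight, and care area are
always known (resolution refuses to start without a dosing weight on file —
the mandatory-prompt contract). Indication, gestational age, and renal
status filter only when supplied. An order-set identifier maps to its
indication before filtering, so order-set-driven regions resolve without a
prompt; the order-set context field on a region is the anchor for that
injection and is deliberately not an extra filter, so that an unknown
indication leaves those regions in play and triggers a prompt rather than
silently dropping them.

After filtering: one survivor is presented; zero survivors exit to manual
entry; several survivors trigger a prompt for any unknown parameter on
which the survivors *differ* (knowing it could shrink the set), in the fixed
order indication → gestational age → renal status. If no unknown parameter
separates the survivors, the outcome is ambiguous and likewise exits to
manual entry — no precedence heuristic is applied.

## Dose computation and rounding

`dose_raw = rate × dosing_weight` for per-kg rules, the flat amount
otherwise; `dose_capped = min(dose_raw, max_single_dose)` when the region
carries a cap. Rounding then snaps the capped dose to the nearest value in
the region's dispensable-dose table **only if** that value lies within the
table's tolerance fraction of the computed dose (10% for the general table,
5% for tight-control tables, per-table for custom ones); otherwise the dose
is left untouched and marked unrounded. A dose already in the table is
"rounded" at distance zero; equidistant ties break toward the smaller
value (the conservative direction). Rounding is idempotent.

## Manual-dose bounds and the double-entry override

A manually entered dose is checked against per-drug bounds: every region
whose **weight criterion admits the current dosing weight** is evaluated at
that weight (caps applied), and the extremes of those evaluations are the
permitted band, inclusive at both ends (a dose exactly at a sanctioned
region dose must not alert). Restricting to weight-admissible regions is a
deliberate design choice: evaluating *all* regions would let a flat
adolescent dose (e.g., 2 g for ≥ 27 kg) dominate the ceiling applied to a
3 kg neonate, and a ten-fold slip on a neonatal 75 mg/kg dose would then
pass unchallenged. With the restriction, the fixture's max/min band ratio
stays below 9 at every weight, so a ten-fold slip on any sanctioned dose —
even after a −10% rounding snap — always exceeds the ceiling.

An out-of-bounds dose is accepted only through double entry: the user must
retype the exact aberrant value, compared as whitespace-trimmed strings
with no numeric coercion ("1200.0" does not confirm "1200"). The intent is
retyping, not re-asserting: numeric coercion would accept coincidental
re-entries. Drugs with no regions (or none admitting the weight) have no
derivable bounds; the check abstains rather than guessing. Every accepted
manual order — gap, no-region, or override — emits an append-only audit
record with a patient-parameter snapshot, for KB-gap review.

## Alerts

All alert functions are pure over (patient, configuration); thresholds are
per care area with hospital-wide defaults:

| knob | default | meaning |
| --- | --- | --- |
| `weight_change_fraction` | 0.10 | popup when a new weight differs from the previous same-kind value by **more than** 10% |
| `actual_dosing_variance_fraction` | 0.10 | popup when dosing vs actual weight diverge by more than 10% (denominator: actual) |
| `stale_days_actual` | 1 day | text tag when the actual weight is older (actual weights are expected daily) |
| `stale_days_dosing` | 3 days | text tag for dosing weight (cadence follows unit protocol; 3 days is the neutral default) |
| `percentile_low/high` | 3 / 97 | popup when a weight falls outside this growth-percentile band |

Threshold comparisons are strict: a change of exactly 10% does not alert.
The wording "a change of 10%" is ambiguous at equality, and strictness is
the alert-fatigue-minimizing reading. Change alerts compare within a weight
kind only (new dosing vs previous dosing); cross-kind discrepancy is the
variance alert's job. A missing record is *missing* (mandatory-prompt
territory), never *stale*.

Population guards use the pediatric definition — age < 14 years, or
age < 18 years and weight < 45 kg, both inequalities strict, reading the
dosing weight when present and the actual weight otherwise. A patient aged
14–18 with no weight on file classifies as not pediatric and raises a
"weight needed" flag to the caller rather than guessing. Adult dosing
content is withheld from pediatric patients unless the medication carries
the explicit both-populations exemption flag; advisor redirection maps an
adult advisor id to its registered pediatric counterpart and is idempotent.

## Pre/post safety statistics

Inputs are per-unit, per-period counts: reports filed, reports scored as
harmful ADEs, and patient days. Conventions, chosen to match how such
tables are conventionally computed and reported:

* proportions: `100·k/n` with Wald (normal-approximation) 95% intervals,
  `p ± z₀.₉₇₅·√(p(1−p)/n)`, lower bound clipped at 0;
* rates: `1000·k/patient_days`, intervals analogous with each patient day
  treated as a Bernoulli trial;
* percent change: `100·(post − pre)/pre` of the unrounded point estimates;
* significance: Pearson chi-square without continuity correction, df = 1 —
  on the (ADE, non-ADE report) 2×2 for the proportion comparison and the
  (ADE, ADE-free patient day) 2×2 for the rate comparison;
* display: half-up rounding, one decimal for percents/rates, three for
  p-values.

The patient-day Bernoulli treatment is an approximation (events per
exposure time is Poisson-like, and a published table computed with an
unstated rate test can differ in the last digit of its p-value); the rate
point estimates, intervals, and percent changes are unaffected by that
choice.

## Synthetic data

The growth model is an age-conditional normal: median weight interpolated
log-linearly between fixed knots (birth ≈ 3.5 kg to 18 y ≈ 67/57 kg for
males/females), SD rising from 11% to 16% of the median. The seed applies a
small (±2%) per-sex global scale, emulating reference-table variation
without breaking monotonicity. This is **not** real anthropometry: no LMS
skewness, no preterm curves, no secular trends. Percentile computations are
exact under the model by construction (`percentile(median) = 50`), so
passing percentile tests validates the plumbing, not the curves.

Cohorts draw a care area from a bed-count mix over six pediatric units
(general 61, transitional 16, PICU 16, BMT 16, NICU 65, cardiac ICU 13 —
the NICU-heavy mix of a tertiary children's hospital), an age from a
per-area span (NICU 0–28 days, up to 17 y on the wards), and a growth
channel z uniform in [−2, 2] (≈ 2nd–98th percentile, i.e., children who
track a normal channel; outliers enter only via injected errors). Daily
weights follow the channel with a bounded AR(1) wobble, keeping
day-over-day changes under ~2% — well inside the 5% bound the generator
guarantees. Actual weights are recorded daily, dosing weights every 3 days,
by authorized roles only.

Order streams draw 1000 events by default against the bundled KB, resolve
each (supplying an indication or order set), and take the capped, rounded
proposal as ground truth; events that fall in authored region gaps follow
the manual path with a mid-range 75 mg/kg ground truth. Errors are injected
at 5% per mode, at most one per event so interception attribution is
unambiguous: weights multiplied by 2.20462 (pound-for-kilogram miskey),
doses multiplied by 10, or an order pinned to a superseded dosing weight.
Replay scores each mode by the safeguard that should catch it: weight-entry
alerts, the bounds check, and weight-adjust reminders respectively. The
pound-for-kilogram interception guarantee needs only a prior weight on file
(a 120% change clears any sane threshold); the ten-fold guarantee follows
from the weight-admissible bounds band being narrower than 9:1 (see above).

Determinism: one master seed; each stage (curves, cohort, stream) derives
its own child seed, so any stage reproduces bit-identically in isolation.

## Problem sizes and limitations

Bundled problem sizes — one drug, 18 regions, 150 patients, 1000 events —
are chosen so the full suite and the acceptance script run in seconds while
still exercising every code path; the engine itself is O(regions) per
resolution and has no scale-dependent logic. What the synthetic results do
*not* show: real alert burden (which depends on true weight-entry error
rates), real ADE dynamics (voluntary reporting is biased and seasonal, and
the pre/post design has no concurrent control), or the content quality of a
production knowledge base. Frequency-level checking (total daily dose
limits such as "≈ 300 mg/kg/day") is annotated in guidance text but not
enforced; severity scoring of event narratives is upstream of this package
and taken as given.
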
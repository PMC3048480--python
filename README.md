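# peddose

Pediatric weight-based dosing decision support, built as a standalone
library and CLI for medication-safety informatics work: prototyping dosing
rules, stress-testing alert thresholds against simulated ordering errors,
and analyzing pre/post safety-event data.

Dosing children is unlike dosing adults: most doses are computed from a
rapidly changing body weight (mg/kg), modulated by chronological and
post-conceptual age, care intensity, indication, and renal function — and
the classic failure modes (ten-fold dose slips, weights keyed in pounds
instead of kilograms, stale weights) are dangerous precisely because
pediatric physiologic reserve is small. `peddose` packages the machinery a
computerized order-entry system uses to defend against these errors:

* **Dosing-region knowledge base** — the unit of clinical knowledge is a
  *dosing region*: a set of patient criteria (age, weight, care area,
  indication, renal status, order-set context) mapped to one dose rule
  (per-kg or flat amount with an optional single-dose cap) and a
  dispensable-dose rounding table. KBs live in a versioned, schema-checked
  YAML format; `validate_kb` reports duplicate and overlapping regions by
  brute-force sampling of the patient-parameter space.
* **Resolution engine** — filters a drug's regions by every parameter whose
  value is known, prompts for what would narrow the set (indication →
  gestational age → renal status), and presents exactly one region or exits
  to guarded manual entry. Doses are computed as
  `dose = rate × dosing_weight` (or a flat amount), capped at the region's
  maximum single dose, then snapped to the nearest dispensable value within
  the table's tolerance (10%, 5%, or custom).
* **Guard rails** — a mandatory dosing-weight prompt; growth-percentile
  screening (warn outside the 3rd–97th percentile band); extreme
  weight-change and actual-vs-dosing variance popups (strict 10% default
  thresholds, configurable per care area); stale-parameter tags;
  weight-adjust reminders and automatic re-resolution of live orders after
  weight updates; per-drug min/max manual-dose bounds with an
  exact-retype double-entry override; adult-content suppression and advisor
  redirection for patients meeting the pediatric definition
  (age < 14 y, or < 18 y and < 45 kg); an append-only audit trail of every
  manual dose.
* **Safety statistics** — pre/post analysis of voluntarily reported adverse
  drug events (ADEs): ADE proportion of reports with Wald binomial 95% CIs,
  ADE rate per 1000 patient days, percent changes, and Pearson chi-square
  tests (no continuity correction) of both comparisons.
* **Synthetic fixtures** — deterministic growth curves, patient cohorts with
  daily weight trajectories, and error-injected order streams, so the whole
  pipeline is exercisable without any clinical data.

## Worked example

```python
from peddose import compute_dose, resolve
from peddose.synthetic import load_fixture_kb
from peddose.patients import Patient, WeightRecord
from datetime import datetime

kb = load_fixture_kb()  # bundled single-drug (ampicillin) knowledge base

baby = Patient(patient_id="demo", chronological_age_days=5, care_area="nicu", sex="F")
baby.add_weight(WeightRecord(3.2, datetime(2008, 3, 1, 8), "dosing", "physician"))

outcome = resolve(kb, baby, "ampicillin")
print(outcome.status, outcome.missing_inputs)
# needs_input ('indication',)

outcome = resolve(kb, baby, "ampicillin", {"indication": "meningitis"})
proposal = compute_dose(kb, outcome.region, baby.current_weight("dosing"))
print(outcome.region.region_id, proposal.raw_dose_mg, proposal.final_dose_mg)
# amp-men-nicu-le7d 320.0 300.0
```

The resolver first asks for the missing indication (a 5-day-old in the NICU
falls under both the meningitis rows and the order-set-driven liver
transplant rows). With the indication supplied, the 100 mg/kg q8h IV/IM
region applies: 100 mg/kg × 3.2 kg = 320 mg, snapped to the 300 mg
dispensable amount (within the 10% rounding table's tolerance).

The same flow from the shell:

```bash
adm order --kb <kb.yaml> --patient <roster.yaml> --drug ampicillin --indication meningitis
adm kb validate <kb.yaml>      # flags the deliberately overlapping ICU neonate rows
adm stats --counts <counts.csv>
adm simulate --kb <kb.yaml> --seed 1 --out scratch/sim
```

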
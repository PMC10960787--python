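# renalrx

A rule-based prescription audit engine for patients who have **both chronic
kidney disease (CKD) and type 2 diabetes (T2DM)**. Renally excreted drugs
must be dose-adjusted as kidney function declines, several antihypertensive
class combinations are unsafe together, and a number of common CKD drugs
raise serum potassium. `renalrx` encodes that clinical knowledge as a
declarative, versioned knowledge base and derives, for each patient profile:

- the **CKD stage** (G1–G5) from the estimated glomerular filtration rate
  (eGFR, mL/min/1.73 m²), using half-open intervals
  G1 [90, ∞), G2 [60, 90), G3a [45, 60), G3b [30, 45), G4 [15, 30), G5 [0, 15);
- the **diabetes status** from HbA1c (%): Normal < 5.7, Prediabetes
  [5.7, 6.4), Diabetes ≥ 6.4;
- **GFR-banded dose recommendations** for CKD drugs — each drug carries a
  normal starting/maximum dose and a percent-of-normal-dose (or absolute
  replacement dose, or *avoid*) for the bands eGFR > 50, 10–50 and < 10 —
  gated on explicit `has_ckd = Yes` and `has_dialysis = No` flags;
- **percent dose reductions** for diabetes drugs (25% in the mid band, 50%
  in the low band), gated on `has_t2dm = Yes`;
- **drug–drug interaction warnings** for the two unsafe class-pair families
  (ACE inhibitors × angiotensin-II receptor antagonists, and beta blockers
  × {Diltiazem, Verapamil});
- **potassium-raising warnings** for ACE inhibitors, ARAs, beta blockers and
  Spironolactone.

Reports can be scored against physician rater panels (3-rater majority
voting, accuracy / sensitivity / specificity / precision / MSE) and exported
as RDF (Turtle, RDF/XML, N-Triples) with one type assertion plus one property
assertion per non-missing cohort column, and rule-head predicates such as
`recommendedKidneyDrugDosage` and `hasDrugDrugInteractionWarning`.

The intended users are clinical-informatics researchers and decision-support
developers; a synthetic-cohort generator makes the whole pipeline runnable
without access to any real patient data.

## Worked example

```python
from renalrx import PatientProfile, generate_report, load_knowledge_base

kb = load_knowledge_base()
patient = PatientProfile(
    patient_id="M001", gfr=30.0, hba1c=7.0,
    has_ckd="Yes", has_t2dm="Yes", has_dialysis="No",
    prescription=frozenset({"Acarbose", "Candesartan", "Ramipril"}))
report = generate_report(patient, kb)

print(report.stage, report.t2dm_status)
for rec in report.ckd_dose_recs + report.t2dm_dose_recs:
    print(" ", rec.drug, "->", rec.display())
for warning in report.warnings:
    print(" ", warning.kind, warning.drugs)
```

prints

```
G3b Diabetes
  Acarbose -> 50 mg t.i.d
  Candesartan -> 32 mg per-day
  lispro_mix -> reduce dose by 25%
  ddi ('Candesartan', 'Ramipril')
  k_raising ('Candesartan',)
  k_raising ('Ramipril',)
```

eGFR 30 falls in stage G3b and the mid dose band (10–50 mL/min), so
Acarbose is cut to 50% of its 100 mg t.i.d maximum, Candesartan is unchanged
(100% in the mid band), the lispro mix insulin is reduced by 25%, the
ACE-i + ARA pair triggers an interaction warning, and both drugs of that
pair raise potassium.

The same workflow is available from the shell:

```sh
renalrx simulate --n 249 --seed 1 --out cohort.csv --panel-out panel.csv
renalrx recommend --cohort cohort.csv --out reports/
renalrx evaluate  --cohort cohort.csv --panel panel.csv --out metrics.json
renalrx export    --cohort cohort.csv --out graph.ttl --fmt Turtle
renalrx kb-report
```

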
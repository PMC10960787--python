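# Methods

## The model

`renalrx` is a deterministic forward-chaining rule engine over a declarative
clinical knowledge base. Every rule it evaluates has one of four shapes:

1. **Interval classification.** CKD staging maps eGFR to one of six stages
   through half-open intervals, and dose-band selection maps eGFR to one of
   three bands (high (50, ∞), mid [10, 50], low [0, 10) mL/min). The
   published staging criteria are stated over integer eGFR ("60 < eGFR < 89"
   next to a rule reading "> 59 and < 90"), which leaves non-integer values
   such as 89.5 ambiguous; storing the stages as half-open real intervals
   [lower, upper) agrees with both phrasings at integers and restores
   totality and mutual exclusion over all positive reals. The same
   convention puts an HbA1c of exactly 5.7% in Prediabetes and 6.4% in
   Diabetes.
2. **Gated band lookup.** A CKD dose rule fires only when the patient has
   explicit `has_ckd = Yes` **and** `has_dialysis = No`; it then resolves the
   drug's cell at the patient's band. Fraction cells scale both the starting
   and the maximum dose (rounded to 2 decimals); range fractions (e.g.
   25–50%) produce dose ranges and are never collapsed to a single number;
   *avoid* cells become contraindication warnings, missing cells become
   no-data warnings, and dialysis patients get a referral warning instead of
   any dose. Diabetes dose rules are gated on `has_t2dm = Yes` and reduce
   the current dose by 25% (mid band) or 50% (low band).
3. **Set joins.** Interaction warnings are the intersection of the patient's
   prescription with a closed symmetric pair relation, which by construction
   equals (ACE inhibitors × ARAs) ∪ (beta blockers × {Diltiazem, Verapamil}).
   Interaction rules are stored one-per-subject-drug, as published, and the
   engine always applies the symmetric closure. Potassium warnings are a
   class/drug membership test against four rules (three whole classes plus
   Spironolactone).
4. **Report assembly**, which is a pure composition of the above with
   canonical (drug name, rule id) ordering, so reports are deterministic
   functions of (profile, knowledge base).

A general OWL reasoner is deliberately not used: every rule in scope has one
of these shapes, and direct evaluation is deterministic, dependency-light
and unit-testable. RDF is an *export* format (rdflib), not the storage
format; the knowledge base ships as versioned YAML so it is diffable and
users can append drugs or rules without code changes.

## Closed-world flags

Flags (`has_ckd`, `has_t2dm`, `has_dialysis`) are tri-valued: Yes, No, or
missing. Missing is never coerced to No, and no dose rule fires on a missing
flag — absence of evidence must not trigger a dose recommendation. The
interaction and potassium checks are intentionally unconditional on the
disease flags, matching the published rules, which test only the
prescription.

## Knowledge-base curation notes

- The published dose table is explicitly abbreviated; the bundled KB carries
  every drug named anywhere in the source material (45 drugs in 7 classes,
  22 dose entries). Class membership beyond the printed rows is filled only
  from drugs named elsewhere (e.g. the full ACE-inhibitor and beta-blocker
  interaction lists).
- Betaxolol's printed row is garbled ("20 mg q. 24 h / 80–90%"); it is
  stored as printed, with the non-numeric maximum-dose cell carrying no
  amount, so no adjusted dose is ever computed for it.
- Acebutolol has no printed normal-dose row; only its low-band absolute
  dose (180–300 mg once daily or b.i.d) is known, so its other bands are
  `no_data`.
- Labetalol's mid-band absolute dose (400 mg b.i.d) comes from a worked
  rule example; other bands are `no_data`.
- Troglitazone is excluded (withdrawn from the market).
- Two diabetes dose-reduction rules are shipped (lispro mix −25% mid band,
  Aspart/NovoRapid −50% low band); the published list is abbreviated and the
  schema accepts additional rows.

## Evaluation protocol

Rater panels mirror the independent-specialist protocol: each item is a
system assertion (or a deliberate non-assertion), each of an odd number of
raters marks it True/False, and ground truth is either one rater's column or
the majority vote. Items are tallied into TP/FP/TN/FN by comparing the
system flag to the derived truth, giving

- accuracy = (TN + TP) / (TN + TP + FN + FP)
- specificity = TN / (TN + FP)
- sensitivity = TP / (TP + FN)
- precision = TP / (TP + FP)
- MSE = (1/n) Σ (Aᵢ − Pᵢ)²

The MSE operands are not defined in the source protocol for dose items; here
Aᵢ/Pᵢ are **binary correctness indicators** (derived truth vs. system flag),
which makes MSE = 1 − accuracy an exact identity — asserted in the tests —
and keeps the statistic on the small magnitude reported for such systems.
Undefined metrics (zero denominators) raise instead of returning 0, so
degenerate per-patient curves cannot silently look perfect.

True negatives need representable non-assertions: the panel builder emits
one negative item per KB dose-entry drug the system did *not* mention for a
patient. How negatives were enumerated in the original protocol is unstated;
scoring is restricted to items present in the rater file, so any alternative
enumeration can be supplied externally.

## Synthetic cohort

The generator emulates the *shape* of the study data — 249 patients with
both diseases, 41 columns, CKD at any stage with end-stage disease excluded
(dialysis rate defaults to 0, overridable to exercise the referral path) —
not its joint distribution, which is unpublished. eGFR is drawn uniformly
inside the sampled stage's interval (so stage membership holds by
construction), HbA1c uniformly in (6.5, 11) for diabetic patients and
(4.5, 6.3) otherwise, and the remaining features uniformly within clinically
plausible ranges. Serum creatinine is a noisy inverse function of eGFR for
plausibility only. Prescriptions are 1–5 drugs sampled without replacement
from the KB.

Consequences: passing tests demonstrate rule correctness, determinism and
protocol behaviour, **not** real-world predictive performance — the
headline agreement rates of the original physician study (≈96–98%) require
the on-request patient data and real expert ratings and are out of scope
here. Simulated raters err independently and uniformly at a configured flip
rate, which ignores correlated expert disagreement.

## Numerical and design choices

- Adjusted doses are reported to 2 decimal places; fraction ranges multiply
  range endpoints pairwise (low×low, high×high).
- Band and stage boundary ties resolve by the half-open convention above;
  dose bands place eGFR exactly 10 and 50 in the mid band.
- Two recommendation scopes: audit mode (default) resolves only prescribed
  drugs; formulary mode resolves every KB dose entry.
- Unknown prescription drugs are logged and skipped rather than failing a
  whole report; profile validation reports them separately.
- Two co-prescribed drugs of the *same* class (e.g. two ACE inhibitors)
  produce no interaction warning: the pair relation covers only the two
  published cross-class families, and within-class duplication is
  deliberately not guessed at.
- Problem sizes in the test suite (staging totality over 10⁵ random eGFRs,
  interaction checks over all 990 drug pairs, panels of ≥2000 ratings for
  error-rate recovery, 249-patient smoke runs) were chosen to exercise every
  rule path and keep statistical checks well-powered while remaining
  desk-scale.

## Known limitations

- No pharmacokinetic modelling, titration over time, or interactions beyond
  the two published class-pair families.
- The bundled dose table cannot reproduce the original system's full rule
  census (hundreds of per-drug SWRL rules enumerated from an unabridged
  table); rule counts report what is actually shipped.
- RDF export targets SPARQL-queryable plain RDF; OWL-DL completeness and
  reasoning over the export are non-goals.
- The real cohort's 41-column data dictionary is unpublished; columns beyond
  the named clinical fields are untyped `extras`.
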
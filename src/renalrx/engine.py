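"""The rule engine: CKD staging, diabetes status, GFR-banded dose
resolution, drug-drug interaction and potassium warnings, and per-patient
report assembly.

The engine evaluates a fixed rule schema directly (interval lookup plus set
joins) rather than running a general OWL reasoner: every shipped rule is of
that shape, which keeps inference deterministic and testable. CKD dose rules
are gated on explicit ``has_ckd == "Yes"`` and ``has_dialysis == "No"``;
diabetes dose rules on explicit ``has_t2dm == "Yes"``. A missing flag never
fires a rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .kb import (BAND_LABELS, DoseAdjustment, DrugDoseEntry, KnowledgeBase,
                 StagingRule)
from .patients import PatientProfile

logger = logging.getLogger(__name__)

T2DM_STATUSES = ("Normal", "Prediabetes", "Diabetes", "unknown")
WARNING_KINDS = ("ddi", "k_raising", "contraindicated", "no_data",
                 "dialysis_referral")


class DomainError(ValueError):
    """Input outside the domain a rule is defined on (e.g. eGFR <= 0)."""


class UnknownDrugError(KeyError):
    """Drug not present in the knowledge base."""


@dataclass(frozen=True)
class DoseRecommendation:
    """A resolved dose for one drug at the patient's GFR band.

    Adjusted doses (mg, rounded to 2 decimals) are present only when the
    base dose is numeric and the band cell is a fraction; ranges are kept
    as (low, high) and never collapsed to one number.
    """

    drug: str
    band: str
    resolved: DoseAdjustment
    adjusted_starting_dose: Optional[tuple[float, float]] = None
    adjusted_maximum_dose: Optional[tuple[float, float]] = None
    rule_id: str = ""
    reduce_pct: Optional[float] = None  # set for T2DM percent-reduction rules

    def display(self) -> str:
        if self.reduce_pct is not None:
            return f"reduce dose by {self.reduce_pct:g}%"
        if self.resolved.kind == "absolute":
            return self.resolved.dose_text or ""
        if self.adjusted_maximum_dose is not None:
            low, high = self.adjusted_maximum_dose
            amount = f"{low:g}" if low == high else f"{low:g}-{high:g}"
            freq = self.resolved.frequency or ""
            return f"{amount} mg {freq}".strip()
        if self.resolved.kind == "fraction":
            lo, hi = self.resolved.fraction_low, self.resolved.fraction_high
            pct = f"{lo:g}%" if lo == hi else f"{lo:g}-{hi:g}%"
            return f"{pct} of normal dose"
        return self.resolved.kind


@dataclass(frozen=True)
class Warning:
    """A typed alert with provenance rule id.

    ddi warnings carry exactly two drugs in sorted order; k_raising exactly
    one.
    """

    kind: str
    drugs: tuple[str, ...]
    rule_id: str
    message: str


@dataclass
class PatientReport:
    patient_id: str
    stage: Optional[str]
    t2dm_status: str
    ckd_dose_recs: list[Union[DoseRecommendation, Warning]]
    t2dm_dose_recs: list[DoseRecommendation]
    warnings: list[Warning]

    def to_dict(self) -> dict:
        def rec_dict(rec):
            if isinstance(rec, Warning):
                return {"type": "warning", "kind": rec.kind,
                        "drugs": list(rec.drugs), "rule_id": rec.rule_id,
                        "message": rec.message}
            return {"type": "dose", "drug": rec.drug, "band": rec.band,
                    "kind": rec.resolved.kind, "value": rec.display(),
                    "adjusted_starting_dose": rec.adjusted_starting_dose,
                    "adjusted_maximum_dose": rec.adjusted_maximum_dose,
                    "reduce_pct": rec.reduce_pct, "rule_id": rec.rule_id}

        return {
            "patient_id": self.patient_id,
            "stage": self.stage,
            "t2dm_status": self.t2dm_status,
            "ckd_dose_recs": [rec_dict(r) for r in self.ckd_dose_recs],
            "t2dm_dose_recs": [rec_dict(r) for r in self.t2dm_dose_recs],
            "warnings": [rec_dict(w) for w in self.warnings],
        }

    def flat_rows(self) -> list[dict]:
        """Flat CSV rows (patient_id, item_type, drug, value, rule_id)."""
        rows = []
        for rec in self.ckd_dose_recs:
            if isinstance(rec, Warning):
                rows.append({"patient_id": self.patient_id,
                             "item_type": rec.kind,
                             "drug": ";".join(rec.drugs),
                             "value": rec.message, "rule_id": rec.rule_id})
            else:
                rows.append({"patient_id": self.patient_id,
                             "item_type": "ckd_dose", "drug": rec.drug,
                             "value": rec.display(), "rule_id": rec.rule_id})
        for rec in self.t2dm_dose_recs:
            rows.append({"patient_id": self.patient_id,
                         "item_type": "t2dm_dose", "drug": rec.drug,
                         "value": rec.display(), "rule_id": rec.rule_id})
        for w in self.warnings:
            rows.append({"patient_id": self.patient_id, "item_type": w.kind,
                         "drug": ";".join(w.drugs), "value": w.message,
                         "rule_id": w.rule_id})
        return rows


def classify_ckd_stage(gfr: float,
                       rules: Sequence[StagingRule]) -> str:
    """Map an eGFR (mL/min/1.73 m^2) to its CKD stage label.

    Stages are half-open intervals [lower, upper): G1 [90, inf), G2 [60, 90),
    G3a [45, 60), G3b [30, 45), G4 [15, 30), G5 [0, 15).
    """
    if gfr is None or gfr <= 0:
        raise DomainError(f"eGFR must be positive, got {gfr!r}")
    for rule in rules:
        if rule.contains(gfr):
            return rule.stage
    raise DomainError(f"no staging rule matches eGFR {gfr}")  # unreachable


def classify_t2dm_status(hba1c: Optional[float],
                         thresholds: Optional[dict] = None) -> str:
    """Diabetes status from HbA1c (%): Normal < 5.7, Prediabetes [5.7, 6.4),
    Diabetes >= 6.4; missing HbA1c yields "unknown"."""
    if hba1c is None:
        return "unknown"
    thr = thresholds or {"normal_upper": 5.7, "diabetes_lower": 6.4}
    if hba1c < thr["normal_upper"]:
        return "Normal"
    if hba1c < thr["diabetes_lower"]:
        return "Prediabetes"
    return "Diabetes"


def band_for_gfr(gfr: float) -> str:
    """Dose band for a real-valued eGFR: low [0, 10), mid [10, 50],
    high (50, inf)."""
    if gfr is None or gfr <= 0:
        raise DomainError(f"eGFR must be positive, got {gfr!r}")
    if gfr < 10:
        return "low"
    if gfr <= 50:
        return "mid"
    return "high"


def _scaled(dose, adj: DoseAdjustment) -> Optional[tuple[float, float]]:
    if not dose.numeric:
        return None
    low = round(dose.amount_low * adj.fraction_low / 100.0, 2)
    high = round(dose.amount_high * adj.fraction_high / 100.0, 2)
    return (low, high)


def resolve_ckd_dose(drug: str, profile: PatientProfile,
                     kb: KnowledgeBase
                     ) -> Optional[Union[DoseRecommendation, Warning]]:
    """Resolve the CKD dose rule for one drug against one patient.

    Fires only for explicit ``has_ckd == "Yes"``; ``has_dialysis == "Yes"``
    yields a dialysis-referral warning instead of a dose; band cells of kind
    avoid / no_data yield contraindication / no-data warnings. Returns
    ``None`` when the rule preconditions are unmet.
    """
    entry = kb.dose_entry(drug)
    if entry is None:
        raise UnknownDrugError(drug)
    if profile.has_ckd != "Yes":
        return None
    if profile.has_dialysis == "Yes":
        return Warning(
            kind="dialysis_referral", drugs=(drug,), rule_id=entry.rule_id,
            message=f"{drug}: patient on dialysis - refer for specialist "
                    f"dosing, GFR-band adjustment does not apply")
    if profile.has_dialysis != "No":
        return None  # dialysis status unknown: closed predicate, rule silent
    if profile.gfr is None:
        return None
    band = band_for_gfr(profile.gfr)
    adj = entry.band_adjustments[band]
    if adj.kind == "avoid":
        return Warning(
            kind="contraindicated", drugs=(drug,), rule_id=entry.rule_id,
            message=f"{drug}: avoid at eGFR band {band!r}")
    if adj.kind == "no_data":
        return Warning(
            kind="no_data", drugs=(drug,), rule_id=entry.rule_id,
            message=f"{drug}: no dosing data for eGFR band {band!r}")
    if adj.kind == "absolute":
        return DoseRecommendation(drug=drug, band=band, resolved=adj,
                                  rule_id=entry.rule_id)
    # carry the base dose frequency so displays/exports read "50 mg t.i.d"
    adj = replace(adj, frequency=(entry.maximum_dose.frequency
                                  or entry.starting_dose.frequency))
    return DoseRecommendation(
        drug=drug, band=band, resolved=adj,
        adjusted_starting_dose=_scaled(entry.starting_dose, adj),
        adjusted_maximum_dose=_scaled(entry.maximum_dose, adj),
        rule_id=entry.rule_id)


def recommend_ckd_doses(profile: PatientProfile, kb: KnowledgeBase,
                        restrict_to_prescription: bool = True
                        ) -> list[Union[DoseRecommendation, Warning]]:
    """CKD dose recommendations for one patient, canonically ordered.

    In the default audit mode only drugs on the patient's prescription are
    resolved; formulary mode (``restrict_to_prescription=False``) resolves
    every KB dose entry. Unknown prescription drugs are skipped with a log
    line, never a failure.
    """
    if restrict_to_prescription:
        drugs = []
        with_entries = {e.drug for e in kb.dose_entries}
        known = kb.all_drugs()
        for drug in sorted(profile.prescription):
            if drug not in known:
                logger.warning("patient %s: skipping unknown drug %r",
                               profile.patient_id, drug)
            elif drug in with_entries:
                drugs.append(drug)
    else:
        drugs = sorted(e.drug for e in kb.dose_entries)
    out = []
    for drug in drugs:
        result = resolve_ckd_dose(drug, profile, kb)
        if result is not None:
            out.append(result)
    return out


def recommend_t2dm_doses(profile: PatientProfile,
                         kb: KnowledgeBase) -> list[DoseRecommendation]:
    """Percent-reduction recommendations for diabetes drugs.

    Fires only for explicit ``has_t2dm == "Yes"``; the shipped rules reduce
    by 25% in the mid band and 50% in the low band.
    """
    if profile.has_t2dm != "Yes" or profile.gfr is None:
        return []
    band = band_for_gfr(profile.gfr)
    out = []
    for rule in kb.t2dm_dose_rules:
        if rule.band == band:
            adj = DoseAdjustment(kind="fraction",
                                 fraction_low=100 - rule.reduce_pct,
                                 fraction_high=100 - rule.reduce_pct)
            out.append(DoseRecommendation(
                drug=rule.drug, band=band, resolved=adj,
                rule_id=rule.rule_id, reduce_pct=rule.reduce_pct))
    out.sort(key=lambda r: (r.drug, r.rule_id))
    return out


def ddi_warnings(prescription, kb: KnowledgeBase) -> list[Warning]:
    """One warning per unordered interacting pair present in the
    prescription; symmetric and order-independent. Unknown drugs are
    skipped with a log line."""
    known = kb.all_drugs()
    drugs = sorted(d for d in prescription if d in known)
    for d in sorted(set(prescription) - set(drugs)):
        logger.warning("ddi check: skipping unknown drug %r", d)
    pairs = kb.interaction_pairs()
    rule_for = {}
    for rule in kb.interaction_rules:
        for other in rule.interacts_with:
            rule_for.setdefault(frozenset((rule.subject_drug, other)),
                                rule.rule_id)
    out = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            pair = frozenset((a, b))
            if pair in pairs:
                out.append(Warning(
                    kind="ddi", drugs=(a, b), rule_id=rule_for[pair],
                    message=f"{a} and {b} must not be used together"))
    return out


def k_raising_warnings(prescription, kb: KnowledgeBase) -> list[Warning]:
    """One warning per prescribed drug whose class (or the drug itself) is
    flagged as potassium-raising."""
    known = kb.all_drugs()
    class_members = {c.name: c.members for c in kb.drug_classes}
    out = []
    for drug in sorted(prescription):
        if drug not in known:
            logger.warning("k-raising check: skipping unknown drug %r", drug)
            continue
        for rule in kb.k_raising_rules:
            in_scope = (drug in class_members.get(rule.scope, ())
                        if rule.scope_is_class else drug == rule.scope)
            if in_scope:
                out.append(Warning(
                    kind="k_raising", drugs=(drug,), rule_id=rule.rule_id,
                    message=f"{drug} may raise serum potassium"))
                break
    return out


def generate_report(profile: PatientProfile, kb: KnowledgeBase,
                    restrict_to_prescription: bool = True) -> PatientReport:
    """Assemble the full per-patient report: stage, diabetes status, dose
    recommendations and warnings, deterministically ordered."""
    stage = (classify_ckd_stage(profile.gfr, kb.staging_rules)
             if profile.gfr is not None and profile.gfr > 0 else None)
    status = classify_t2dm_status(profile.hba1c, dict(kb.hba1c_thresholds))
    warnings = ddi_warnings(profile.prescription, kb)
    warnings += k_raising_warnings(profile.prescription, kb)
    ckd_recs = recommend_ckd_doses(profile, kb, restrict_to_prescription)
    dose_recs = [r for r in ckd_recs if isinstance(r, DoseRecommendation)]
    warnings += [r for r in ckd_recs if isinstance(r, Warning)]
    warnings.sort(key=lambda w: (w.kind, w.drugs, w.rule_id))
    dose_recs.sort(key=lambda r: (r.drug, r.rule_id))
    return PatientReport(
        patient_id=profile.patient_id, stage=stage, t2dm_status=status,
        ckd_dose_recs=dose_recs,
        t2dm_dose_recs=recommend_t2dm_doses(profile, kb),
        warnings=warnings)
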
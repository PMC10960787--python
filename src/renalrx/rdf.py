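"""RDF export of cohorts, knowledge and inference results.

Mirrors the spreadsheet-row-to-axioms pattern (one type assertion plus one
property assertion per non-missing column) and uses the rule-head predicate
vocabulary of the engine (recommendedKidneyDrugDosage,
recommendedDiabetesDrugDosage, hasDrugDrugInteractionWarning,
hasPotassiumLevelIncreaseWarning). Dose individuals are named in the
conventional style, e.g. ``AcarboseDose_50mg_tid``.

Namespace IRIs are configurable; the defaults are project-local.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .engine import DoseRecommendation, PatientReport, Warning
from .patients import Cohort, CORE_COLUMNS, PatientProfile

FORMATS = {"Turtle": "turtle", "RDF/XML": "xml", "N-Triples": "nt"}

_FREQ_TOKENS = {"t.i.d": "tid", "b.i.d": "bid", "q24h": "q24hr",
                "per-day": "day", "/day": "day", "variable": "variable"}


class ExportError(ValueError):
    """Unknown serialization format or unmapped column in strict mode."""


@dataclass(frozen=True)
class NamespaceConfig:
    """Prefix/IRI configuration for the export vocabulary."""

    core: str = "https://example.org/renalrx/core#"
    drug: str = "https://example.org/renalrx/drug#"
    patient: str = "https://example.org/renalrx/patient#"

    def bind(self, graph: Graph) -> tuple[Namespace, Namespace, Namespace]:
        core, drug, pat = (Namespace(self.core), Namespace(self.drug),
                           Namespace(self.patient))
        graph.bind("rx", core)
        graph.bind("drug", drug)
        graph.bind("pat", pat)
        return core, drug, pat


def _safe(name: str) -> str:
    return re.sub(r"[^0-9A-Za-z_.-]", "_", str(name))


def _literal(value) -> Literal:
    if isinstance(value, bool):
        return Literal(value)
    if isinstance(value, (int, float)):
        return Literal(float(value), datatype=XSD.double)
    return Literal(str(value))


def dose_individual_name(rec: DoseRecommendation) -> str:
    """Deterministic dose-individual local name for a recommendation."""
    if rec.reduce_pct is not None:
        return f"{_safe(rec.drug)}-Reduce_Dose_by_{rec.reduce_pct:g}_percent"
    if rec.resolved.kind == "absolute":
        amounts = (rec.resolved.amount_low, rec.resolved.amount_high)
        freq = rec.resolved.frequency or "variable"
    elif rec.adjusted_maximum_dose is not None:
        amounts = rec.adjusted_maximum_dose
        freq = rec.resolved.frequency or "variable"
    else:  # fraction of a non-numeric base dose
        lo = rec.resolved.fraction_low
        hi = rec.resolved.fraction_high
        pct = f"{lo:g}pct" if lo == hi else f"{lo:g}pct_{hi:g}pct"
        return f"{_safe(rec.drug)}Dose_{pct}"
    lo, hi = amounts
    amount = f"{lo:g}mg" if lo == hi else f"{lo:g}mg_{hi:g}mg"
    freq_token = "_".join(_FREQ_TOKENS.get(tok, _safe(tok))
                          for tok in freq.split())
    return f"{_safe(rec.drug)}Dose_{amount}_{freq_token}"


def default_column_mapping(profile: PatientProfile) -> dict[str, str]:
    """Column-to-predicate mapping covering every cohort column."""
    mapping = {col: col for col in CORE_COLUMNS}
    mapping.update({col: col for col in profile.extras})
    return mapping


def cohort_to_axioms(cohort: Cohort,
                     mapping: Optional[Mapping[str, str]] = None,
                     ns: Optional[NamespaceConfig] = None,
                     strict: bool = False) -> Graph:
    """Transform cohort rows to RDF axioms.

    Per patient: one ``rdf:type Patient`` assertion plus one property
    assertion per non-missing mapped column (missing values emit nothing).
    In strict mode a column absent from *mapping* raises.
    """
    graph = Graph()
    core, _drug, pat = (ns or NamespaceConfig()).bind(graph)
    for profile in cohort:
        colmap = dict(mapping) if mapping is not None else \
            default_column_mapping(profile)
        subject = pat[_safe(profile.patient_id)]
        graph.add((subject, RDF.type, core.Patient))
        values: dict[str, object] = {
            "patient_id": profile.patient_id, "age": profile.age,
            "gender": profile.gender, "bmi": profile.bmi,
            "hba1c": profile.hba1c, "gfr": profile.gfr, "scr": profile.scr,
            "has_ckd": profile.has_ckd, "has_t2dm": profile.has_t2dm,
            "has_dialysis": profile.has_dialysis,
            "prescription": (";".join(sorted(profile.prescription))
                             if profile.prescription else None),
        }
        values.update(profile.extras)
        for column, value in values.items():
            if value is None:
                continue
            if column not in colmap:
                if strict:
                    raise ExportError(f"unmapped column {column!r}")
                continue
            graph.add((subject, pat[_safe(colmap[column])], _literal(value)))
    return graph


def report_to_triples(report: PatientReport,
                      ns: Optional[NamespaceConfig] = None) -> Graph:
    """Serialize one patient report as RDF.

    One triple per recommendation/warning: dose recommendations point the
    patient at a named dose individual; interaction warnings emit the
    symmetric drug-level pair; potassium warnings assert the drug-level
    boolean, as in the rule heads.
    """
    graph = Graph()
    core, drug_ns, pat = (ns or NamespaceConfig()).bind(graph)
    subject = pat[_safe(report.patient_id)]
    graph.add((subject, RDF.type, core.Patient))
    if report.stage:
        graph.add((subject, RDF.type, core[report.stage]))
    if report.t2dm_status and report.t2dm_status != "unknown":
        graph.add((subject, core.hasT2dmStatus, Literal(report.t2dm_status)))
    for rec in report.ckd_dose_recs:
        graph.add((subject, core.recommendedKidneyDrugDosage,
                   drug_ns[dose_individual_name(rec)]))
    for rec in report.t2dm_dose_recs:
        graph.add((subject, core.recommendedDiabetesDrugDosage,
                   drug_ns[dose_individual_name(rec)]))
    for w in report.warnings:
        if w.kind == "ddi":
            a, b = (drug_ns[_safe(d)] for d in w.drugs)
            graph.add((a, core.hasDrugDrugInteractionWarning, b))
            graph.add((b, core.hasDrugDrugInteractionWarning, a))
        elif w.kind == "k_raising":
            graph.add((drug_ns[_safe(w.drugs[0])],
                       core.hasPotassiumLevelIncreaseWarning, Literal(True)))
        elif w.kind == "contraindicated":
            graph.add((subject, core.hasContraindicationWarning,
                       drug_ns[_safe(w.drugs[0])]))
        elif w.kind == "no_data":
            graph.add((subject, core.hasNoDosingDataWarning,
                       drug_ns[_safe(w.drugs[0])]))
        elif w.kind == "dialysis_referral":
            graph.add((subject, core.hasDialysisReferralWarning,
                       drug_ns[_safe(w.drugs[0])]))
    return graph


def expected_report_triple_count(report: PatientReport) -> int:
    """Triple count as a deterministic function of report contents."""
    n = 1  # patient type assertion
    n += 1 if report.stage else 0
    n += 1 if report.t2dm_status and report.t2dm_status != "unknown" else 0
    n += len(report.ckd_dose_recs) + len(report.t2dm_dose_recs)
    for w in report.warnings:
        n += 2 if w.kind == "ddi" else 1
    return n


def serialize_graph(graph: Graph, fmt: str, path: str | Path) -> Path:
    """Serialize to Turtle, RDF/XML or N-Triples; output re-parses to an
    isomorphic graph."""
    key = FORMATS.get(fmt, fmt if fmt in FORMATS.values() else None)
    if key is None:
        raise ExportError(
            f"unknown format {fmt!r}: expected one of {sorted(FORMATS)}")
    path = Path(path)
    graph.serialize(destination=str(path), format=key, encoding="utf-8")
    return path


def parse_graph(path: str | Path, fmt: str) -> Graph:
    key = FORMATS.get(fmt, fmt if fmt in FORMATS.values() else None)
    if key is None:
        raise ExportError(f"unknown format {fmt!r}")
    graph = Graph()
    graph.parse(str(path), format=key)
    return graph
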
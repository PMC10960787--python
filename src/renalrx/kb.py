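"""Declarative clinical knowledge base: drug classes, GFR-banded dose tables,
interaction sets, potassium-raising rules and CKD staging thresholds.

The knowledge base is shipped as a versioned YAML data file (diffable and
testable) rather than an OWL ontology; RDF is an export format, not the
storage format. Loading validates referential integrity; violations found
by :func:`validate_knowledge_base` are data, not exceptions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

BAND_LABELS = ("high", "mid", "low")
STAGE_LABELS = ("G1", "G2", "G3a", "G3b", "G4", "G5")
FREQUENCY_CODES = ("q24h", "b.i.d", "t.i.d", "per-day", "variable")

_DOSE_RE = re.compile(
    r"^\s*(?P<low>\d+(?:\.\d+)?)\s*(?:[-–]\s*(?P<high>\d+(?:\.\d+)?))?"
    r"\s*(?:mg)?\s*(?P<freq>.*)$"
)

_FREQ_MAP = {
    "t.i.d": "t.i.d", "tid": "t.i.d",
    "b.i.d": "b.i.d", "bid": "b.i.d",
    "q24h": "q24h", "q.24h": "q24h", "q. 24 h": "q24h", "q24hr": "q24h",
    "/day": "per-day", "day": "per-day", "per-day": "per-day",
}


class KBSchemaError(ValueError):
    """A knowledge-base file that does not parse as the documented schema."""


class KBIntegrityError(ValueError):
    """A structurally valid file whose cross references do not resolve."""


@dataclass(frozen=True)
class DoseText:
    """A dose cell as printed, plus the parsed amount range when numeric."""

    text: str
    amount_low: Optional[float] = None
    amount_high: Optional[float] = None
    frequency: Optional[str] = None

    @property
    def numeric(self) -> bool:
        return self.amount_low is not None


def parse_dose_text(text: str) -> DoseText:
    """Parse dose strings like ``"6.25-25 mg t.i.d"`` or ``"Variable"``.

    Non-numeric cells (``Variable``, ``No data``, percentage artifacts) keep
    only the printed text.
    """
    raw = text.strip()
    if raw.endswith("%"):
        return DoseText(text=raw)
    m = _DOSE_RE.match(raw)
    if not m or m.group("low") is None:
        freq = "variable" if raw.lower() == "variable" else None
        return DoseText(text=raw, frequency=freq)
    low = float(m.group("low"))
    high = float(m.group("high")) if m.group("high") else low
    freq_raw = m.group("freq").strip().lower()
    freq = _FREQ_MAP.get(freq_raw)
    if freq is None:
        for key, code in _FREQ_MAP.items():
            if key in freq_raw:
                freq = code
                break
    return DoseText(text=raw, amount_low=low, amount_high=high,
                    frequency=freq or "variable")


@dataclass(frozen=True)
class DoseAdjustment:
    """One GFR-band cell of the dose table.

    kind ``fraction`` carries a percent-of-normal-dose range (scalar cells
    have ``fraction_low == fraction_high``); ``absolute`` carries an explicit
    replacement dose; ``avoid`` and ``no_data`` carry no numeric payload.
    """

    kind: str
    fraction_low: Optional[float] = None
    fraction_high: Optional[float] = None
    dose_text: Optional[str] = None
    amount_low: Optional[float] = None
    amount_high: Optional[float] = None
    frequency: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("fraction", "absolute", "avoid", "no_data"):
            raise KBSchemaError(f"unknown adjustment kind {self.kind!r}")
        if self.kind == "fraction":
            if self.fraction_low is None or self.fraction_high is None:
                raise KBSchemaError("fraction adjustment requires a percent")
            if not (0 < self.fraction_low <= self.fraction_high <= 100):
                raise KBSchemaError(
                    f"fraction percent out of (0, 100]: "
                    f"{self.fraction_low}-{self.fraction_high}")
        if self.kind in ("avoid", "no_data") and (
                self.fraction_low is not None or self.amount_low is not None):
            raise KBSchemaError(f"{self.kind} cell carries numeric payload")


@dataclass(frozen=True)
class DrugClass:
    name: str
    members: frozenset[str]
    k_raising: bool = False


@dataclass(frozen=True)
class GfrBand:
    """Dose band over real-valued eGFR: high (50, inf), mid [10, 50], low [0, 10)."""

    label: str
    lower: float
    upper: Optional[float]


@dataclass(frozen=True)
class DrugDoseEntry:
    drug: str
    drug_class: str
    starting_dose: DoseText
    maximum_dose: DoseText
    band_adjustments: Mapping[str, DoseAdjustment]
    rule_id: str


@dataclass(frozen=True)
class InteractionRule:
    rule_id: str
    subject_drug: str
    interacts_with: frozenset[str]


@dataclass(frozen=True)
class KRaisingRule:
    rule_id: str
    scope: str           # class name or single drug name
    scope_is_class: bool


@dataclass(frozen=True)
class StagingRule:
    """Half-open eGFR interval [lower, upper) mapped to a CKD stage."""

    stage: str
    lower: float
    upper: Optional[float]

    def contains(self, gfr: float) -> bool:
        return gfr >= self.lower and (self.upper is None or gfr < self.upper)


@dataclass(frozen=True)
class T2dmDoseRule:
    rule_id: str
    drug: str
    band: str
    reduce_pct: float


@dataclass(frozen=True)
class KnowledgeBase:
    version: str
    drug_classes: tuple[DrugClass, ...]
    dose_entries: tuple[DrugDoseEntry, ...]
    interaction_rules: tuple[InteractionRule, ...]
    k_raising_rules: tuple[KRaisingRule, ...]
    staging_rules: tuple[StagingRule, ...]
    t2dm_dose_rules: tuple[T2dmDoseRule, ...]
    gfr_bands: tuple[GfrBand, ...]
    hba1c_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"normal_upper": 5.7, "diabetes_lower": 6.4})

    def all_drugs(self) -> frozenset[str]:
        """Every drug known to the KB (union of class memberships)."""
        out: set[str] = set()
        for cls in self.drug_classes:
            out.update(cls.members)
        return frozenset(out)

    def class_of(self, drug: str) -> Optional[str]:
        for cls in self.drug_classes:
            if drug in cls.members:
                return cls.name
        return None

    def dose_entry(self, drug: str) -> Optional[DrugDoseEntry]:
        for entry in self.dose_entries:
            if entry.drug == drug:
                return entry
        return None

    def interaction_pairs(self) -> frozenset[frozenset[str]]:
        """The closed (symmetric) interaction relation as unordered pairs."""
        pairs: set[frozenset[str]] = set()
        for rule in self.interaction_rules:
            for other in rule.interacts_with:
                pairs.add(frozenset((rule.subject_drug, other)))
        return frozenset(pairs)

    def k_raising_drugs(self) -> frozenset[str]:
        drugs: set[str] = set()
        class_members = {c.name: c.members for c in self.drug_classes}
        for rule in self.k_raising_rules:
            if rule.scope_is_class:
                drugs.update(class_members.get(rule.scope, ()))
            else:
                drugs.add(rule.scope)
        return frozenset(drugs)


def _parse_adjustment(cell: Mapping, where: str) -> DoseAdjustment:
    if not isinstance(cell, Mapping) or "kind" not in cell:
        raise KBSchemaError(f"{where}: band cell must be a mapping with 'kind'")
    kind = cell["kind"]
    if kind == "fraction":
        if "pct" in cell:
            low = high = float(cell["pct"])
        else:
            try:
                low, high = float(cell["pct_low"]), float(cell["pct_high"])
            except KeyError as exc:
                raise KBSchemaError(f"{where}: fraction cell missing {exc}")
        return DoseAdjustment(kind="fraction", fraction_low=low,
                              fraction_high=high)
    if kind == "absolute":
        try:
            return DoseAdjustment(
                kind="absolute", dose_text=str(cell["text"]),
                amount_low=float(cell["amount_low"]),
                amount_high=float(cell["amount_high"]),
                frequency=str(cell.get("frequency", "variable")))
        except KeyError as exc:
            raise KBSchemaError(f"{where}: absolute cell missing {exc}")
    return DoseAdjustment(kind=kind)


def _default_kb_text() -> str:
    return (resources.files("renalrx.data") / "knowledge_base.yaml").read_text(
        encoding="utf-8")


def load_knowledge_base(source: Optional[str | Path] = None) -> KnowledgeBase:
    """Load and integrity-check a knowledge base.

    Parameters
    ----------
    source
        Path to a KB YAML file; ``None`` loads the bundled default.

    Raises
    ------
    KBSchemaError
        Malformed file, naming the offending record.
    KBIntegrityError
        A rule references a drug that belongs to no drug class.
    """
    text = _default_kb_text() if source is None else Path(source).read_text(
        encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise KBSchemaError(f"KB file is not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise KBSchemaError("KB file must be a mapping at top level")

    classes = []
    for rec in raw.get("drug_classes", []):
        try:
            members = rec["members"]
            if not members:
                raise KBSchemaError(
                    f"drug class {rec.get('name')!r}: members must be non-empty")
            classes.append(DrugClass(
                name=str(rec["name"]), members=frozenset(map(str, members)),
                k_raising=bool(rec.get("k_raising", False))))
        except KeyError as exc:
            raise KBSchemaError(f"drug class record missing field {exc}")

    class_of: dict[str, str] = {}
    for cls in classes:
        for drug in cls.members:
            class_of.setdefault(drug, cls.name)

    entries = []
    for rec in raw.get("dose_entries", []):
        try:
            drug = str(rec["drug"])
            bands = rec["bands"]
            adjustments = {
                label: _parse_adjustment(bands[label], f"dose entry {drug}")
                for label in BAND_LABELS}
        except KeyError as exc:
            raise KBSchemaError(
                f"dose entry {rec.get('drug', '?')!r} missing field {exc}")
        entries.append(DrugDoseEntry(
            drug=drug, drug_class=class_of.get(drug, ""),
            starting_dose=parse_dose_text(str(rec["starting_dose"])),
            maximum_dose=parse_dose_text(str(rec["maximum_dose"])),
            band_adjustments=adjustments,
            rule_id=f"dose-{drug.lower().replace(' ', '-')}"))

    interactions = []
    for rec in raw.get("interaction_rules", []):
        try:
            interactions.append(InteractionRule(
                rule_id=str(rec["rule_id"]), subject_drug=str(rec["subject"]),
                interacts_with=frozenset(map(str, rec["interacts_with"]))))
        except KeyError as exc:
            raise KBSchemaError(
                f"interaction rule {rec.get('rule_id', '?')!r} missing {exc}")

    k_rules = []
    for rec in raw.get("k_raising_rules", []):
        rid = str(rec.get("rule_id", "?"))
        if "scope_class" in rec:
            k_rules.append(KRaisingRule(rid, str(rec["scope_class"]), True))
        elif "scope_drug" in rec:
            k_rules.append(KRaisingRule(rid, str(rec["scope_drug"]), False))
        else:
            raise KBSchemaError(
                f"k-raising rule {rid!r} needs scope_class or scope_drug")

    staging = []
    for rec in raw.get("staging_rules", []):
        try:
            staging.append(StagingRule(
                stage=str(rec["stage"]), lower=float(rec["lower"]),
                upper=None if rec.get("upper") is None else float(rec["upper"])))
        except KeyError as exc:
            raise KBSchemaError(f"staging rule missing field {exc}")

    t2dm_rules = []
    for rec in raw.get("t2dm_dose_rules", []):
        try:
            t2dm_rules.append(T2dmDoseRule(
                rule_id=str(rec["rule_id"]), drug=str(rec["drug"]),
                band=str(rec["band"]), reduce_pct=float(rec["reduce_pct"])))
        except KeyError as exc:
            raise KBSchemaError(f"t2dm dose rule missing field {exc}")

    bands = []
    for rec in raw.get("gfr_bands", []):
        bands.append(GfrBand(
            label=str(rec["label"]), lower=float(rec["lower"]),
            upper=None if rec.get("upper") is None else float(rec["upper"])))

    kb = KnowledgeBase(
        version=str(raw.get("version", "0")),
        drug_classes=tuple(classes), dose_entries=tuple(entries),
        interaction_rules=tuple(interactions), k_raising_rules=tuple(k_rules),
        staging_rules=tuple(staging), t2dm_dose_rules=tuple(t2dm_rules),
        gfr_bands=tuple(bands),
        hba1c_thresholds=dict(raw.get(
            "hba1c_thresholds",
            {"normal_upper": 5.7, "diabetes_lower": 6.4})))

    known = kb.all_drugs()
    for rule in kb.interaction_rules:
        for drug in {rule.subject_drug, *rule.interacts_with}:
            if drug not in known:
                raise KBIntegrityError(
                    f"interaction rule {rule.rule_id!r} references unknown "
                    f"drug {drug!r}")
    for entry in kb.dose_entries:
        if entry.drug not in known:
            raise KBIntegrityError(
                f"dose entry references unknown drug {entry.drug!r}")
    for rule in kb.t2dm_dose_rules:
        if rule.drug not in known:
            raise KBIntegrityError(
                f"t2dm rule {rule.rule_id!r} references unknown drug "
                f"{rule.drug!r}")
    return kb


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_knowledge_base(kb: KnowledgeBase) -> ValidationReport:
    """Report every integrity violation in *kb* (empty report = valid).

    Checks: unique class names, single class membership per drug, the three
    dose bands present per entry, interaction symmetry after closure,
    interaction subjects not self-interacting, staging intervals partitioning
    [0, inf), and K-raising scopes resolving.
    """
    report = ValidationReport()
    seen_names: set[str] = set()
    membership: dict[str, str] = {}
    for cls in kb.drug_classes:
        if cls.name in seen_names:
            report.violations.append(f"duplicate drug class name {cls.name!r}")
        seen_names.add(cls.name)
        for drug in cls.members:
            if drug in membership:
                report.violations.append(
                    f"duplicate class membership: {drug!r} in "
                    f"{membership[drug]!r} and {cls.name!r}")
            else:
                membership[drug] = cls.name

    for entry in kb.dose_entries:
        missing = [b for b in BAND_LABELS if b not in entry.band_adjustments]
        if missing:
            report.violations.append(
                f"dose entry {entry.drug!r} missing bands {missing}")

    # symmetric-closure check: a drug listed as an interaction target whose
    # own rule (if any) omits the subject is asymmetric curation
    by_subject = {r.subject_drug: r for r in kb.interaction_rules}
    for rule in kb.interaction_rules:
        if rule.subject_drug in rule.interacts_with:
            report.violations.append(
                f"interaction rule {rule.rule_id!r}: subject interacts "
                f"with itself")
        for other in rule.interacts_with:
            back = by_subject.get(other)
            if back is not None and rule.subject_drug not in back.interacts_with:
                report.violations.append(
                    f"interaction asymmetry: {rule.subject_drug!r} lists "
                    f"{other!r} but not vice versa")

    stages = sorted(kb.staging_rules, key=lambda r: r.lower)
    if stages:
        if stages[0].lower != 0:
            report.violations.append("staging intervals do not start at 0")
        for lo, hi in zip(stages, stages[1:]):
            if lo.upper != hi.lower:
                report.violations.append(
                    f"staging gap/overlap between {lo.stage} and {hi.stage}")
        if stages[-1].upper is not None:
            report.violations.append("staging intervals do not cover high eGFR")

    class_names = {c.name for c in kb.drug_classes}
    known = kb.all_drugs()
    for rule in kb.k_raising_rules:
        target_ok = (rule.scope in class_names if rule.scope_is_class
                     else rule.scope in known)
        if not target_ok:
            report.violations.append(
                f"k-raising rule {rule.rule_id!r}: unresolvable scope "
                f"{rule.scope!r}")
    return report


def rule_counts(kb: KnowledgeBase) -> dict[str, int]:
    """Counts of shipped rules per category."""
    return {
        "staging": len(kb.staging_rules),
        "ddi": len(kb.interaction_rules),
        "dose": len(kb.dose_entries),
        "k_raising": len(kb.k_raising_rules),
        "t2dm_dose": len(kb.t2dm_dose_rules),
    }
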
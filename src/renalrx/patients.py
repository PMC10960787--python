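"""Patient cohort I/O: the 41-feature profile shape, CSV reading/writing
and per-profile validation.

Missing clinical flags are kept missing, never coerced to "No": the dose
rules are closed predicates that fire only on explicit values, so absence of
evidence must not trigger a recommendation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .kb import KnowledgeBase

logger = logging.getLogger(__name__)

#: columns with first-class fields on PatientProfile
CORE_COLUMNS = ("patient_id", "age", "gender", "bmi", "hba1c", "gfr", "scr",
                "has_ckd", "has_t2dm", "has_dialysis", "prescription")

FLAG_VALUES = ("Yes", "No")


class CohortConfigError(ValueError):
    """A cohort file that cannot be mapped onto the expected columns."""


class CohortDataError(ValueError):
    """Row-level defects that invalidate the cohort (e.g. duplicate ids)."""


@dataclass
class PatientProfile:
    """One row of the cohort.

    ``extras`` holds the remaining (untyped) cohort columns so the full
    41-column shape round-trips through the engine.
    """

    patient_id: str
    age: Optional[float] = None
    gender: Optional[str] = None
    bmi: Optional[float] = None
    hba1c: Optional[float] = None
    gfr: Optional[float] = None
    scr: Optional[float] = None
    has_ckd: Optional[str] = None
    has_t2dm: Optional[str] = None
    has_dialysis: Optional[str] = None
    prescription: frozenset[str] = frozenset()
    extras: dict[str, object] = field(default_factory=dict)


@dataclass
class Cohort:
    patients: list[PatientProfile]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def _clean(value) -> Optional[object]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def _as_float(value, column: str, patient: str) -> Optional[float]:
    value = _clean(value)
    if value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        logger.warning("patient %s: unparseable %s=%r treated as missing",
                       patient, column, value)
        return None


def _as_flag(value, column: str, patient: str) -> Optional[str]:
    value = _clean(value)
    if value is None:
        return None
    text = str(value).strip().capitalize()
    if text in FLAG_VALUES:
        return text
    logger.warning("patient %s: %s=%r is not Yes/No, treated as missing",
                   patient, column, value)
    return None


def parse_prescription(value) -> frozenset[str]:
    """Parse a semicolon-delimited drug-name list cell."""
    value = _clean(value)
    if value is None:
        return frozenset()
    return frozenset(
        part.strip() for part in str(value).split(";") if part.strip())


def read_cohort(path: str | Path,
                column_map: Optional[Mapping[str, str]] = None) -> Cohort:
    """Read a UTF-8, header-row CSV cohort into :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file with one patient per row.
    column_map
        Optional mapping from profile field name to the file's column name,
        for cohorts with non-default headers.

    Raises
    ------
    CohortConfigError
        Mandatory column (patient_id or gfr) not resolvable.
    CohortDataError
        Duplicate patient ids.
    """
    frame = pd.read_csv(path, dtype=str)
    colmap = dict(column_map or {})

    def col(name: str) -> Optional[str]:
        target = colmap.get(name, name)
        return target if target in frame.columns else None

    for mandatory in ("patient_id", "gfr"):
        if col(mandatory) is None:
            raise CohortConfigError(
                f"mandatory column {mandatory!r} not found in {path}")

    patients: list[PatientProfile] = []
    seen: set[str] = set()
    core_cols = {name: col(name) for name in CORE_COLUMNS}
    extra_cols = [c for c in frame.columns
                  if c not in {v for v in core_cols.values() if v}]
    for _, row in frame.iterrows():
        pid = str(row[core_cols["patient_id"]]).strip()
        if pid in seen:
            raise CohortDataError(f"duplicate patient id {pid!r}")
        seen.add(pid)
        get = lambda name: row[core_cols[name]] if core_cols[name] else None
        profile = PatientProfile(
            patient_id=pid,
            age=_as_float(get("age"), "age", pid),
            gender=_clean(get("gender")),
            bmi=_as_float(get("bmi"), "bmi", pid),
            hba1c=_as_float(get("hba1c"), "hba1c", pid),
            gfr=_as_float(get("gfr"), "gfr", pid),
            scr=_as_float(get("scr"), "scr", pid),
            has_ckd=_as_flag(get("has_ckd"), "has_ckd", pid),
            has_t2dm=_as_flag(get("has_t2dm"), "has_t2dm", pid),
            has_dialysis=_as_flag(get("has_dialysis"), "has_dialysis", pid),
            prescription=parse_prescription(get("prescription")),
            extras={c: _clean(row[c]) for c in extra_cols},
        )
        patients.append(profile)
    return Cohort(patients=patients, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the CSV dialect :func:`read_cohort` accepts."""
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "patient_id": p.patient_id, "age": p.age, "gender": p.gender,
            "bmi": p.bmi, "hba1c": p.hba1c, "gfr": p.gfr, "scr": p.scr,
            "has_ckd": p.has_ckd, "has_t2dm": p.has_t2dm,
            "has_dialysis": p.has_dialysis,
            "prescription": ";".join(sorted(p.prescription)),
        }
        row.update(p.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_profile(profile: PatientProfile,
                     kb: Optional[KnowledgeBase] = None) -> list[str]:
    """Return a list of issues (out-of-range vitals, unknown drugs,
    contradictory flags). Suspicious combinations are flagged, not fatal."""
    issues: list[str] = []
    if profile.gfr is not None and profile.gfr <= 0:
        issues.append("gfr out of range (must be > 0)")
    if profile.hba1c is not None and not (3 < profile.hba1c < 20):
        issues.append("hba1c out of range (expected in (3, 20))")
    if profile.bmi is not None and not (8 < profile.bmi < 80):
        issues.append("bmi out of range")
    if profile.age is not None and not (0 <= profile.age <= 120):
        issues.append("age out of range")
    if kb is not None:
        known = kb.all_drugs()
        for drug in sorted(profile.prescription):
            if drug not in known:
                issues.append(f"unknown drug {drug!r} in prescription")
    if (profile.has_ckd == "No" and profile.gfr is not None
            and profile.gfr < 15):
        issues.append(
            "suspicious: has_ckd=No but gfr < 15 (kidney-failure range)")
    return issues
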
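"""Synthetic cohort and rater-panel generation.

The generator emulates the *shape* of the study cohort - 249 patients with
both diabetes and CKD at any stage (end-stage renal disease excluded, so
no dialysis by default), 41 columns per patient - not its joint
distribution: features are drawn uniformly within clinically plausible
ranges because no distributions are published. Coverage, not realism, is
the goal; every stage and every dose band occurs at the default size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .engine import PatientReport
from .kb import KnowledgeBase, load_knowledge_base
from .metrics import PanelConfigError, PanelItem, RatingPanel
from .patients import Cohort, PatientProfile

#: default stage proportions: CKD "at any stage", skewed to moderate disease
DEFAULT_STAGE_MIX = {"G1": 0.15, "G2": 0.25, "G3a": 0.20, "G3b": 0.15,
                     "G4": 0.15, "G5": 0.10}

#: sampling interval per stage (G1 capped at a plausible ceiling)
STAGE_INTERVALS = {"G1": (90.0, 130.0), "G2": (60.0, 90.0),
                   "G3a": (45.0, 60.0), "G3b": (30.0, 45.0),
                   "G4": (15.0, 30.0), "G5": (2.0, 15.0)}

#: numeric extra columns (uniform within range); with the 11 core columns
#: and the categorical extras below this makes the 41-column cohort shape
DEFAULT_FEATURE_RANGES = {
    "sbp_mmHg": (100, 180), "dbp_mmHg": (60, 110),
    "heart_rate_bpm": (55, 110), "potassium_mmol_l": (3.2, 6.0),
    "sodium_mmol_l": (130, 148), "calcium_mg_dl": (7.8, 10.6),
    "phosphorus_mg_dl": (2.4, 6.5), "hemoglobin_g_dl": (8.5, 16.5),
    "hematocrit_pct": (26, 50), "albumin_g_dl": (2.8, 5.0),
    "total_cholesterol_mg_dl": (120, 300), "hdl_mg_dl": (25, 80),
    "ldl_mg_dl": (50, 200), "triglycerides_mg_dl": (60, 400),
    "uric_acid_mg_dl": (3.0, 10.0), "bun_mg_dl": (8, 90),
    "uacr_mg_g": (5, 2000), "crp_mg_l": (0.2, 30.0),
    "fasting_glucose_mg_dl": (80, 280),
    "diabetes_duration_years": (0.5, 30.0),
    "ckd_duration_years": (0.2, 20.0), "follow_up_years": (0.5, 8.0),
    "weight_kg": (45, 130), "height_cm": (145, 195),
}

CATEGORICAL_EXTRAS = {
    "smoking_status": ("never", "former", "current"),
    "alcohol_use": ("none", "occasional", "regular"),
    "family_history_dm": ("Yes", "No"),
    "family_history_ckd": ("Yes", "No"),
    "retinopathy": ("Yes", "No"),
    "hypertension": ("Yes", "No"),
}


class ConfigError(ValueError):
    """Invalid cohort configuration, raised before any generation."""


@dataclass
class CohortConfig:
    """Knobs for synthetic cohort generation; defaults mirror the study
    conditions (249 diabetic CKD patients, ESRD/dialysis excluded)."""

    n: int = 249
    seed: int = 0
    stage_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MIX))
    t2dm_rate: float = 1.0
    ckd_rate: float = 1.0
    dialysis_rate: float = 0.0
    prescription_size: tuple[int, int] = (1, 5)
    feature_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_RANGES))

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        for name in ("t2dm_rate", "ckd_rate", "dialysis_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if abs(sum(self.stage_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("stage_mix proportions must sum to 1")
        unknown = set(self.stage_mix) - set(STAGE_INTERVALS)
        if unknown:
            raise ConfigError(f"unknown stages in stage_mix: {sorted(unknown)}")
        lo, hi = self.prescription_size
        if not (0 <= lo <= hi):
            raise ConfigError(
                f"prescription_size must be a 0 <= lo <= hi range, got "
                f"{self.prescription_size}")


def generate_cohort(config: Optional[CohortConfig] = None,
                    kb: Optional[KnowledgeBase] = None) -> Cohort:
    """Generate a reproducible synthetic cohort.

    eGFR is drawn uniformly inside the configured stage's interval, so every
    generated value satisfies its stage by construction; prescriptions are
    sampled from the KB drug list. The same seed yields identical cohorts.
    """
    config = config or CohortConfig()
    config.validate()
    kb = kb or load_knowledge_base()
    rng = np.random.default_rng(config.seed)
    stages = sorted(config.stage_mix)
    probs = np.array([config.stage_mix[s] for s in stages])
    drug_pool = sorted(kb.all_drugs())

    patients = []
    for i in range(config.n):
        stage = rng.choice(stages, p=probs)
        lo, hi = STAGE_INTERVALS[stage]
        gfr = round(float(rng.uniform(lo, hi)), 1)
        has_t2dm = "Yes" if rng.random() < config.t2dm_rate else "No"
        has_ckd = "Yes" if rng.random() < config.ckd_rate else "No"
        has_dialysis = "Yes" if rng.random() < config.dialysis_rate else "No"
        hba1c = round(float(rng.uniform(6.5, 11.0) if has_t2dm == "Yes"
                            else rng.uniform(4.5, 6.3)), 1)
        n_rx = int(rng.integers(config.prescription_size[0],
                                config.prescription_size[1] + 1))
        prescription = frozenset(
            rng.choice(drug_pool, size=min(n_rx, len(drug_pool)),
                       replace=False).tolist())
        extras: dict[str, object] = {
            name: round(float(rng.uniform(lo_, hi_)), 1)
            for name, (lo_, hi_) in config.feature_ranges.items()}
        for name, choices in CATEGORICAL_EXTRAS.items():
            extras[name] = str(rng.choice(choices))
        patients.append(PatientProfile(
            patient_id=f"S{i + 1:04d}",
            age=round(float(rng.uniform(30, 85)), 1),
            gender=str(rng.choice(("F", "M"))),
            bmi=round(float(rng.uniform(18, 42)), 1),
            hba1c=hba1c, gfr=gfr,
            scr=round(0.7 + 65.0 / gfr * float(rng.uniform(0.8, 1.2)), 2),
            has_ckd=has_ckd, has_t2dm=has_t2dm, has_dialysis=has_dialysis,
            prescription=prescription, extras=extras))
    return Cohort(patients=patients,
                  provenance=f"synthetic(seed={config.seed}, n={config.n})")


def panel_items_for_report(report: PatientReport,
                           kb: Optional[KnowledgeBase] = None
                           ) -> list[tuple[str, str, str, bool]]:
    """Enumerate the rateable items of one report.

    Returns (item_id, category, subcategory, system_flag) tuples: one
    positive item per dose recommendation and warning, and - when *kb* is
    given - one negative item per KB dose-entry drug the system did not
    mention for this patient, so true negatives are representable.
    """
    pid = report.patient_id
    items: list[tuple[str, str, str, bool]] = []
    mentioned: set[str] = set()
    for rec in report.ckd_dose_recs:
        items.append((f"{pid}|drug_dose|ckd|{rec.drug}", "drug_dose", "ckd",
                      True))
        mentioned.add(rec.drug)
    for rec in report.t2dm_dose_recs:
        items.append((f"{pid}|drug_dose|t2dm|{rec.drug}", "drug_dose", "t2dm",
                      True))
        mentioned.add(rec.drug)
    for w in report.warnings:
        if w.kind == "ddi":
            items.append((f"{pid}|ddi|{'+'.join(w.drugs)}", "ddi", "", True))
        elif w.kind == "k_raising":
            items.append((f"{pid}|k_raising|{w.drugs[0]}", "k_raising", "",
                          True))
        else:  # contraindicated / no_data / dialysis_referral are dose calls
            items.append((f"{pid}|drug_dose|ckd|{w.kind}:{w.drugs[0]}",
                          "drug_dose", "ckd", True))
            mentioned.add(w.drugs[0])
    if kb is not None:
        for entry in sorted(kb.dose_entries, key=lambda e: e.drug):
            if entry.drug not in mentioned:
                items.append((f"{pid}|drug_dose|ckd|absent:{entry.drug}",
                              "drug_dose", "ckd", False))
    return items


def simulate_rater_panel(reports: Iterable[PatientReport],
                         raters: int = 3,
                         flip_rate: float = 0.0,
                         seed: Optional[int] = None,
                         kb: Optional[KnowledgeBase] = None) -> RatingPanel:
    """Simulate the independent-specialist rating protocol.

    Each rater independently reports the correct judgment for each item,
    flipped with probability *flip_rate*. ``kb`` adds the negative
    (not-recommended) items so specificity is measurable.
    """
    if raters < 1 or raters % 2 == 0:
        raise PanelConfigError(
            f"rater count must be odd and >= 1, got {raters}")
    if not 0 <= flip_rate <= 1:
        raise ValueError(f"flip_rate must be in [0, 1], got {flip_rate}")
    rng = np.random.default_rng(seed)
    items = []
    for report in reports:
        for item_id, cat, sub, flag in panel_items_for_report(report, kb):
            # ground truth: the system call is the right call; raters err
            # independently at flip_rate
            ratings = tuple(
                bool(flag) ^ (rng.random() < flip_rate)
                for _ in range(raters))
            items.append(PanelItem(
                item_id=item_id, patient_id=report.patient_id, category=cat,
                subcategory=sub, system_flag=flag, ratings=ratings))
    return RatingPanel(items)
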
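"""Evaluation of system outputs against physician rater panels.

Ground truth per item is either one rater's judgment or the 3-rater
majority vote; system flags are compared against that truth to form a
confusion matrix, from which accuracy, specificity, sensitivity and
precision are computed, plus a mean-squared-error over binary correctness
indicators (which makes MSE = 1 - accuracy by construction; see
docs/methods.md).

Undefined metrics (zero denominators) raise rather than silently
returning 0, so degenerate per-patient curves cannot masquerade as real
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

CATEGORIES = ("drug_dose", "ddi", "k_raising")


class PanelConfigError(ValueError):
    """Structurally invalid rating panel (even rater count, bad labels)."""


class ReconciliationError(ValueError):
    """Panel items that cannot be matched to system report items."""


class UndefinedMetricError(ZeroDivisionError):
    """A ratio metric whose denominator is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class PanelItem:
    """One rated item: a system assertion (or deliberate non-assertion) with
    per-rater True/False judgments of what the right call was."""

    item_id: str
    patient_id: str
    category: str
    system_flag: bool
    ratings: tuple[bool, ...]
    subcategory: str = ""  # e.g. "ckd" / "t2dm" split within drug_dose


@dataclass
class RatingPanel:
    items: list[PanelItem]

    def __post_init__(self) -> None:
        counts = {len(i.ratings) for i in self.items}
        if len(counts) > 1:
            raise PanelConfigError(
                f"unequal rater counts across items: {sorted(counts)}")


def majority_vote(ratings: Sequence[bool]) -> bool:
    """Majority label of an odd-length rating sequence."""
    n = len(ratings)
    if n < 1 or n % 2 == 0:
        raise PanelConfigError(
            f"majority vote needs an odd number of ratings >= 1, got {n}")
    return sum(bool(r) for r in ratings) * 2 > n


def _truth(item: PanelItem, truth_rule: Union[int, str]) -> bool:
    if truth_rule == "majority":
        return majority_vote(item.ratings)
    if isinstance(truth_rule, int):
        try:
            return item.ratings[truth_rule]
        except IndexError:
            raise PanelConfigError(
                f"rater index {truth_rule} out of range for "
                f"{len(item.ratings)} raters")
    raise PanelConfigError(f"unknown truth rule {truth_rule!r}")


def confusion_from_panel(panel: RatingPanel,
                         truth_rule: Union[int, str] = "majority"
                         ) -> ConfusionCounts:
    """Tally each item into exactly one of TP/TN/FP/FN by comparing the
    system flag to the derived ground truth."""
    tp = tn = fp = fn = 0
    for item in panel.items:
        truth = _truth(item, truth_rule)
        if item.system_flag and truth:
            tp += 1
        elif item.system_flag and not truth:
            fp += 1
        elif not item.system_flag and not truth:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TN + TP) / (TN + TP + FN + FP)."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on empty counts")
    return (c.tn + c.tp) / c.total


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP) - the true-negative ratio."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives")
    return c.tn / (c.tn + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN) - the true-positive ratio."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    return c.tp / (c.tp + c.fp)


def mse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error (1/n) * sum (A_i - P_i)^2 over equal-length
    sequences."""
    if len(actual) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(actual)} actual vs {len(predicted)} "
            f"predicted")
    if not actual:
        raise UndefinedMetricError("mse undefined on empty sequences")
    return sum((float(a) - float(p)) ** 2
               for a, p in zip(actual, predicted)) / len(actual)


def _metric_block(c: ConfusionCounts) -> dict:
    def safe(fn):
        try:
            return fn(c)
        except UndefinedMetricError:
            return None

    return {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "accuracy": safe(accuracy), "specificity": safe(specificity),
            "sensitivity": safe(sensitivity), "precision": safe(precision)}


@dataclass
class MetricReport:
    overall: dict
    mse: float
    per_category: dict[str, dict]
    per_patient: dict[str, dict]
    mse_curve: list[float]

    def to_dict(self) -> dict:
        return {"overall": self.overall, "mse": self.mse,
                "per_category": self.per_category,
                "per_patient": self.per_patient,
                "mse_curve": self.mse_curve}


def evaluate_panel(panel: RatingPanel,
                   truth_rule: Union[int, str] = "majority") -> MetricReport:
    """Overall, per-category and per-patient metrics plus the running MSE
    curve over patients in panel order."""
    overall = confusion_from_panel(panel, truth_rule)
    by_cat: dict[str, list[PanelItem]] = {}
    by_patient: dict[str, list[PanelItem]] = {}
    for item in panel.items:
        by_cat.setdefault(item.category, []).append(item)
        by_patient.setdefault(item.patient_id, []).append(item)

    per_category = {
        cat: _metric_block(confusion_from_panel(RatingPanel(items), truth_rule))
        for cat, items in sorted(by_cat.items())}
    per_patient = {
        pid: _metric_block(confusion_from_panel(RatingPanel(items), truth_rule))
        for pid, items in sorted(by_patient.items())}

    # running MSE over binary correctness indicators, patient by patient
    actual: list[int] = []
    predicted: list[int] = []
    curve: list[float] = []
    for pid in sorted(by_patient):
        for item in by_patient[pid]:
            actual.append(int(_truth(item, truth_rule)))
            predicted.append(int(item.system_flag))
        curve.append(mse(actual, predicted))

    return MetricReport(
        overall=_metric_block(overall),
        mse=mse(actual, predicted) if actual else 0.0,
        per_category=per_category, per_patient=per_patient, mse_curve=curve)


def evaluate_cohort(reports, panel: RatingPanel,
                    truth_rule: Union[int, str] = "majority",
                    kb=None) -> MetricReport:
    """Evaluate a panel against the reports it was rated from.

    Every panel item id must be reconcilable with an item derivable from the
    reports (see :func:`renalrx.simulate.panel_items_for_report` for the id
    scheme); only items present in the panel are scored. Pass the knowledge
    base used to build the panel when it contains negative (not-recommended)
    items.
    """
    from .simulate import panel_items_for_report  # local import, no cycle at module load

    known_ids: dict[str, bool] = {}
    for report in reports:
        for item_id, _cat, _sub, flag in panel_items_for_report(report, kb):
            known_ids[item_id] = flag
    unmatched = [i.item_id for i in panel.items if i.item_id not in known_ids]
    if unmatched:
        raise ReconciliationError(
            f"{len(unmatched)} panel items not derivable from reports, "
            f"e.g. {unmatched[:3]}")
    return evaluate_panel(panel, truth_rule)


def write_panel_csv(panel: RatingPanel, path: str | Path) -> None:
    """Rater file: item_id, patient_id, category, system, rater1..raterN."""
    rows = []
    for item in panel.items:
        row = {"item_id": item.item_id, "patient_id": item.patient_id,
               "category": item.category, "subcategory": item.subcategory,
               "system": "T" if item.system_flag else "F"}
        for j, r in enumerate(item.ratings, start=1):
            row[f"rater{j}"] = "T" if r else "F"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> RatingPanel:
    """Read a rater file written by :func:`write_panel_csv`."""
    frame = pd.read_csv(path, dtype=str)
    rater_cols = sorted((c for c in frame.columns if c.startswith("rater")),
                        key=lambda c: int(c[5:]))
    if not rater_cols:
        raise PanelConfigError(f"no rater columns found in {path}")
    required = {"item_id", "patient_id", "category", "system"}
    missing = required - set(frame.columns)
    if missing:
        raise PanelConfigError(f"rater file missing columns {sorted(missing)}")

    def as_bool(v, col):
        v = str(v).strip().upper()
        if v in ("T", "TRUE", "1"):
            return True
        if v in ("F", "FALSE", "0"):
            return False
        raise PanelConfigError(f"bad {col} value {v!r}: expected T/F")

    items = []
    for _, row in frame.iterrows():
        sub = row.get("subcategory", "")
        if pd.isna(sub):
            sub = ""
        items.append(PanelItem(
            item_id=str(row["item_id"]), patient_id=str(row["patient_id"]),
            category=str(row["category"]),
            subcategory=str(sub),
            system_flag=as_bool(row["system"], "system"),
            ratings=tuple(as_bool(row[c], c) for c in rater_cols)))
    return RatingPanel(items)
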
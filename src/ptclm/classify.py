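"""Mutation class taxonomy for paired PT/CLM cohorts.

A mutation detected in both the primary tumor and the liver metastasis of a
patient is class1 (shared); detected only in the primary, class2; only in the
metastasis, class3. Class 1-H is the subset of class1 whose metastasis VAF
exceeds the primary VAF by at least 15 (or 30) percentage points — the
signature of clonal enrichment or allelic loss during metastasis.

"Detected" is an explicit policy (minimum depth, alt reads and VAF), and a
mutation whose absent sample is too shallow to distinguish absence from
dropout is labelled unassessable rather than forced into a class.

Class assignment uses exome observations only: absence from RNA can reflect
low expression rather than clonal absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    ClinicalRecord,
    ContractError,
    MutationObservation,
    PairedMutationRecord,
    ValidationError,
)
from .stats import StatResult, chi_square_2x2, pearson_regression


@dataclass
class DetectionPolicy:
    """Operational definition of a detected mutation in one observation."""

    min_depth: int = 10
    min_alt_reads: int = 3
    min_vaf: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_alt_reads < 0 or self.min_vaf < 0:
            raise ValidationError("detection policy thresholds must be >= 0")

    def detected(self, obs: Optional[MutationObservation]) -> bool:
        if obs is None or obs.depth == 0:
            return False
        return (
            obs.depth >= self.min_depth
            and obs.alt_reads >= self.min_alt_reads
            and obs.vaf >= self.min_vaf
        )


def assign_class(record: PairedMutationRecord,
                 policy: DetectionPolicy = DetectionPolicy()) -> str:
    """Assign class1/class2/class3/unassessable from the two exome observations.

    When a mutation is detected in only one tumor, the other tumor must be
    covered at >= policy.min_depth for the absence to count as real; otherwise
    the record is unassessable.
    """
    pt = record.obs("PT", "exome")
    clm = record.obs("CLM", "exome")
    if pt is None and clm is None:
        raise ValidationError(
            f"record {record.key} has neither PT-exome nor CLM-exome observation")
    det_pt = policy.detected(pt)
    det_clm = policy.detected(clm)
    if det_pt and det_clm:
        return "class1"
    if det_pt:
        if clm is not None and clm.depth >= policy.min_depth:
            return "class2"
        return "unassessable"
    if det_clm:
        if pt is not None and pt.depth >= policy.min_depth:
            return "class3"
        return "unassessable"
    return "unassessable"


def flag_class1h(record: PairedMutationRecord, delta: float) -> bool:
    """True iff the CLM exome VAF exceeds the PT exome VAF by >= delta.

    delta is in absolute VAF units (0.15 for the 15-percentage-point tier).
    Only meaningful for class1 records.
    """
    if record.class_label != "class1":
        raise ContractError("flag_class1h requires a class1 record")
    vaf_pt = record.vaf("PT", "exome")
    vaf_clm = record.vaf("CLM", "exome")
    if vaf_pt is None or vaf_clm is None:
        return False
    return (vaf_clm - vaf_pt) >= delta


def assign_classes(records: Iterable[PairedMutationRecord],
                   policy: DetectionPolicy = DetectionPolicy()) -> List[PairedMutationRecord]:
    """Assign class_label and both class1h tiers in place; returns the list."""
    out = list(records)
    for rec in out:
        rec.class_label = assign_class(rec, policy)
        if rec.class_label == "class1":
            rec.class1h_15 = flag_class1h(rec, 0.15)
            rec.class1h_30 = flag_class1h(rec, 0.30)
        else:
            rec.class1h_15 = False
            rec.class1h_30 = False
    return out


@dataclass
class ClassSummary:
    """Per-patient and cohort class composition over assessable mutations."""

    per_patient: pd.DataFrame
    totals: dict = field(default_factory=dict)


def class_fractions(records: Iterable[PairedMutationRecord]) -> ClassSummary:
    """Count classes per patient; proportions are over assessable records only."""
    rows = {}
    for rec in records:
        if rec.class_label is None:
            raise ContractError("class_fractions requires classified records")
        row = rows.setdefault(rec.patient_id, {
            "patient": rec.patient_id, "n_class1": 0, "n_class2": 0,
            "n_class3": 0, "n_unassessable": 0, "n_class1h_15": 0,
            "n_class1h_30": 0})
        if rec.class_label == "unassessable":
            row["n_unassessable"] += 1
        else:
            row[f"n_{rec.class_label}"] += 1
            if rec.class1h_15:
                row["n_class1h_15"] += 1
            if rec.class1h_30:
                row["n_class1h_30"] += 1
    per_patient = pd.DataFrame(sorted(rows.values(), key=lambda r: r["patient"]))
    totals: dict = {"n_class1": 0, "n_class2": 0, "n_class3": 0,
                    "n_unassessable": 0, "n_class1h_15": 0, "n_class1h_30": 0}
    if not per_patient.empty:
        n_assess = per_patient[["n_class1", "n_class2", "n_class3"]].sum(axis=1)
        for cls in ("class1", "class2", "class3"):
            per_patient[f"frac_{cls}"] = per_patient[f"n_{cls}"] / n_assess.where(n_assess > 0)
        for key in totals:
            totals[key] = int(per_patient[key].sum())
    total_assess = totals["n_class1"] + totals["n_class2"] + totals["n_class3"]
    totals["n_assessable"] = total_assess
    for cls in ("class1", "class2", "class3"):
        totals[f"frac_{cls}"] = (
            totals[f"n_{cls}"] / total_assess if total_assess > 0 else None)
    return ClassSummary(per_patient=per_patient, totals=totals)


def _attribute_positive(clin: ClinicalRecord, attribute: str) -> bool:
    if attribute == "lvi":
        return clin.lvi
    if attribute == "advanced_t":
        return clin.t_stage in ("T3", "T4")
    raise ContractError(f"unknown clinical attribute {attribute!r}")


def _in_class(rec: PairedMutationRecord, label: str) -> bool:
    if label in ("class1", "class2", "class3"):
        return rec.class_label == label
    if label == "class1h_15":
        return bool(rec.class1h_15)
    if label == "class1h_30":
        return bool(rec.class1h_30)
    raise ContractError(f"unknown class selector {label!r}")


def clinical_association(records: Iterable[PairedMutationRecord],
                         clinical: Sequence[ClinicalRecord],
                         attribute: str = "lvi",
                         classes: Tuple[str, str] = ("class1", "class2"),
                         correction: bool = False):
    """2x2 association between class membership and a clinical attribute.

    Rows are the two class selectors, columns attribute-positive/-negative
    patient groups; cells count mutations. Returns (counts table, StatResult).
    """
    clin_by_patient = {c.patient_id: c for c in clinical}
    counts = [[0, 0], [0, 0]]
    for rec in records:
        clin = clin_by_patient.get(rec.patient_id)
        if clin is None:
            raise ValidationError(f"no clinical record for patient {rec.patient_id}")
        pos = _attribute_positive(clin, attribute)
        for i, label in enumerate(classes):
            if _in_class(rec, label):
                counts[i][0 if pos else 1] += 1
    for i, label in enumerate(classes):
        if counts[i][0] + counts[i][1] == 0:
            raise ContractError(f"class {label} has zero mutations; association undefined")
    result = chi_square_2x2(counts, correction=correction)
    return counts, result


def concordance_vs_clonality(summary: ClassSummary,
                             clinical: Sequence[ClinicalRecord],
                             which: str = "class1") -> StatResult:
    """Regress per-patient class fraction on clonality change (CLM - PT clusters)."""
    clin_by_patient = {c.patient_id: c for c in clinical}
    xs, ys = [], []
    for row in summary.per_patient.itertuples(index=False):
        clin = clin_by_patient.get(row.patient)
        if clin is None or clin.clonality_change is None:
            continue
        frac = getattr(row, f"frac_{which}")
        if pd.isna(frac):
            continue
        xs.append(clin.clonality_change)
        ys.append(frac)
    if len(xs) < 3:
        raise ContractError("concordance_vs_clonality needs >= 3 patients with both "
                            "class fractions and clonality counts")
    result = pearson_regression(xs, ys)
    if result.extra and result.extra.get("degenerate"):
        raise ContractError("correlation undefined: zero variance in class fraction "
                            "or clonality change")
    return result
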
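"""Exome-transcriptome integration.

Four analyses share this module: (1) rescue of exome-rejected variants that
the RNA caller confidently supports, (2) the exome/RNA detection overlap with
an expression explanation for exome-only calls, (3) VAF-delta selections —
mutations preferentially represented in the transcriptome, and the
high-CLM-VAF candidate filter — and (4) coupling of a driver gene's mutant
VAF to the mean expression of its downstream targets (p53 represses its
transcriptional program when mutant, so mutant-TP53 VAF should correlate
negatively with p53-target expression; mutant APC activates WNT signalling,
so APC VAF should correlate positively with WNT-target expression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import DetectionPolicy
from .model import (
    ContractError,
    ExpressionMatrix,
    PairedMutationRecord,
    ValidationError,
)
from .stats import StatResult, pearson_regression

TUMOR_ROLES = ("PT", "CLM")

# canonical downstream programs used for driver-VAF/target-expression coupling
P53_TARGETS = ["BBC3", "BAX", "FAS", "APAF1", "CCNG1", "CDKN1A", "GADD45A",
               "PTEN", "SFN", "TSC2", "TP53I3"]
WNT_TARGETS = ["MYC", "CCND1", "HNF1A", "LEF1", "PPARD", "JUN", "FOSL1",
               "MMP7", "AXIN2", "NRCAM", "TCF4", "CLDN1", "VEGFA", "FGF18",
               "MYCBP", "ID2", "TERT", "LGR5", "FZD7"]


@dataclass
class RescuePolicy:
    """An exome-rejected call is revived when RNA independently keeps it
    at more than 10x coverage (strictly greater, i.e. depth >= 11)."""

    min_rna_depth: int = 11

    def __post_init__(self) -> None:
        if self.min_rna_depth < 1:
            raise ValidationError("min_rna_depth must be >= 1")


@dataclass
class RescueResult:
    rescued: List[PairedMutationRecord]
    n_missing_rna: int = 0


def rescue_rejected(records: Iterable[PairedMutationRecord],
                    policy: RescuePolicy = RescuePolicy(),
                    roles: Sequence[str] = TUMOR_ROLES) -> RescueResult:
    """Return the records revived by RNA support.

    A record is rescued when, in at least one tumor role, its exome verdict
    is reject while its RNA verdict is keep with depth >= policy.min_rna_depth.
    Records whose rejected role lacks an RNA observation are skipped and
    counted, not errors.
    """
    rescued, n_missing = [], 0
    for rec in records:
        hit = False
        missing = False
        for role in roles:
            ex = rec.obs(role, "exome")
            if ex is None or ex.caller_verdict != "reject":
                continue
            rna = rec.obs(role, "rna")
            if rna is None:
                missing = True
                continue
            if rna.caller_verdict == "keep" and rna.depth >= policy.min_rna_depth:
                hit = True
        if hit:
            rescued.append(rec)
        elif missing:
            n_missing += 1
    return RescueResult(rescued=rescued, n_missing_rna=n_missing)


@dataclass
class IntersectionResult:
    sample_role: str
    n_common: int
    n_exome_only: int
    n_rna_only: int
    frac_common_of_exome: float
    frac_common_of_rna: float
    exome_only_records: List[PairedMutationRecord] = field(default_factory=list)
    frac_exome_only_low_expression: Optional[float] = None


def intersect_exome_rna(records: Iterable[PairedMutationRecord],
                        policy: DetectionPolicy = DetectionPolicy(),
                        sample_role: str = "PT",
                        expression: Optional[ExpressionMatrix] = None,
                        low_expression_log2_rpkm: float = 1.0) -> IntersectionResult:
    """Partition one tumor's mutations by the assay(s) that detect them.

    When an expression matrix is supplied, exome-only records are annotated
    with whether their gene stays below ``low_expression_log2_rpkm`` (in
    log2(RPKM+1)) across all samples — the expression explanation for
    exome-specific calls.
    """
    n_common = n_exome_only = n_rna_only = 0
    exome_only: List[PairedMutationRecord] = []
    for rec in records:
        de = policy.detected(rec.obs(sample_role, "exome"))
        dr = policy.detected(rec.obs(sample_role, "rna"))
        if de and dr:
            n_common += 1
        elif de:
            n_exome_only += 1
            exome_only.append(rec)
        elif dr:
            n_rna_only += 1
    n_exome = n_common + n_exome_only
    n_rna = n_common + n_rna_only
    frac_low = None
    if expression is not None and exome_only:
        log2 = np.log2(expression.values + 1.0)
        n_low = 0
        n_known = 0
        for rec in exome_only:
            if rec.gene and rec.gene in log2.index:
                n_known += 1
                if (log2.loc[rec.gene] < low_expression_log2_rpkm).all():
                    n_low += 1
        frac_low = n_low / n_known if n_known else float("nan")
    return IntersectionResult(
        sample_role=sample_role,
        n_common=n_common, n_exome_only=n_exome_only, n_rna_only=n_rna_only,
        frac_common_of_exome=n_common / n_exome if n_exome else float("nan"),
        frac_common_of_rna=n_common / n_rna if n_rna else float("nan"),
        exome_only_records=exome_only,
        frac_exome_only_low_expression=frac_low)


def _vaf_delta(rec: PairedMutationRecord, role: str) -> Optional[float]:
    v_rna = rec.vaf(role, "rna")
    v_ex = rec.vaf(role, "exome")
    if v_rna is None or v_ex is None:
        return None
    return v_rna - v_ex


def select_rna_enriched(records: Iterable[PairedMutationRecord],
                        delta: float = 0.15):
    """Mutations with RNA VAF >= exome VAF + delta in BOTH PT and CLM.

    Records with any of the four VAFs undefined are excluded and counted.
    Returns (selected records, n_excluded).
    """
    selected, n_excluded = [], 0
    for rec in records:
        d_pt = _vaf_delta(rec, "PT")
        d_clm = _vaf_delta(rec, "CLM")
        if d_pt is None or d_clm is None:
            n_excluded += 1
            continue
        if d_pt >= delta and d_clm >= delta:
            selected.append(rec)
    return selected, n_excluded


def select_candidate_clm(records: Iterable[PairedMutationRecord],
                         vaf_min: float = 0.60, delta: float = 0.15):
    """High-CLM-VAF candidates: CLM RNA VAF >= vaf_min and transcriptome
    enrichment (RNA - exome VAF >= delta) in PT OR in CLM.

    Records without a defined CLM RNA VAF are excluded and counted.
    """
    selected, n_excluded = [], 0
    for rec in records:
        v_clm_rna = rec.vaf("CLM", "rna")
        if v_clm_rna is None:
            n_excluded += 1
            continue
        if v_clm_rna < vaf_min:
            continue
        d_pt = _vaf_delta(rec, "PT")
        d_clm = _vaf_delta(rec, "CLM")
        if (d_pt is not None and d_pt >= delta) or (d_clm is not None and d_clm >= delta):
            selected.append(rec)
    return selected, n_excluded


def bin_ma_scores_by_vaf(records: Iterable[PairedMutationRecord],
                         assay: str = "rna", sample_role: str = "CLM",
                         bin_width: float = 0.10, min_depth: int = 10):
    """Mean functional-impact (MA) score per VAF bin, with a monotone-trend test.

    Bins are [0, 0.1), ..., [0.9, 1.0]; the last bin is closed so VAF = 1
    lands in it. Observations shallower than ``min_depth`` are skipped — a
    VAF from a handful of reads would land in an arbitrary bin. Returns
    (table, trend) where trend holds the Spearman correlation of bin midpoint
    vs bin mean over populated bins, or flags the trend undefined when fewer
    than 3 bins are populated.
    """
    n_bins = int(round(1.0 / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for rec in records:
        if rec.ma_score is None:
            continue
        o = rec.obs(sample_role, assay)
        if o is None or o.depth < min_depth:
            continue
        v = o.vaf
        b = min(int(v / bin_width), n_bins - 1)
        sums[b] += rec.ma_score
        counts[b] += 1
    table = pd.DataFrame({
        "bin_left": np.arange(n_bins) * bin_width,
        "bin_right": (np.arange(n_bins) + 1) * bin_width,
        "n": counts,
        "mean_ma_score": np.where(counts > 0, sums / np.maximum(counts, 1), np.nan),
    })
    populated = table[table["n"] > 0]
    if len(populated) < 3:
        trend = {"defined": False, "rho": float("nan"), "p": float("nan")}
    else:
        mid = (populated["bin_left"] + populated["bin_right"]) / 2
        rho, p = sps.spearmanr(mid, populated["mean_ma_score"])
        trend = {"defined": True, "rho": float(rho), "p": float(p)}
    return table, trend


@dataclass
class TargetGeneSet:
    """A driver gene's downstream transcriptional program."""

    driver: str
    direction: str  # "negative" (repressed targets) or "positive"
    members: List[str]

    def __post_init__(self) -> None:
        if self.direction not in ("negative", "positive"):
            raise ValidationError("direction must be 'negative' or 'positive'")
        if not self.members:
            raise ValidationError("TargetGeneSet needs a non-empty member list")


P53_PROGRAM = TargetGeneSet("TP53", "negative", P53_TARGETS)
WNT_PROGRAM = TargetGeneSet("APC", "positive", WNT_TARGETS)


def vaf_expression_correlation(records: Iterable[PairedMutationRecord],
                               expression: ExpressionMatrix,
                               targets: TargetGeneSet,
                               assay: str = "rna", sample_role: str = "CLM",
                               reducer: Callable = max):
    """Correlate per-patient driver VAF with mean target-program expression.

    The per-patient driver VAF is ``reducer`` (default max) over the driver's
    mutations with a defined VAF in the chosen (role, assay); the response is
    the mean over target genes of log2(RPKM+1) in that patient's sample.
    Returns (per-patient table, StatResult with r/slope/p, sign_consistent).
    """
    present = [g for g in targets.members if g in expression.values.index]
    if not present:
        raise ValidationError(
            f"no target genes of {targets.driver} present in expression matrix; "
            f"missing: {', '.join(targets.members)}")
    log2 = np.log2(expression.values.loc[present] + 1.0)

    per_patient_vafs: dict = {}
    for rec in records:
        if rec.gene != targets.driver:
            continue
        v = rec.vaf(sample_role, assay)
        if v is None:
            continue
        per_patient_vafs.setdefault(rec.patient_id, []).append(v)

    rows = []
    for patient, vafs in sorted(per_patient_vafs.items()):
        col = f"{patient}:{sample_role}"
        if col not in log2.columns:
            continue
        rows.append({"patient": patient,
                     "driver_vaf": float(reducer(vafs)),
                     "mean_target_expression": float(log2[col].mean())})
    table = pd.DataFrame(rows, columns=["patient", "driver_vaf",
                                        "mean_target_expression"])
    if len(table) < 3:
        raise ContractError(
            "vaf_expression_correlation needs >= 3 patients with both a driver "
            f"VAF and expression (got {len(table)})")
    result = pearson_regression(table["driver_vaf"], table["mean_target_expression"])
    sign_consistent = None
    if result.p_value is not None:
        expected = -1.0 if targets.direction == "negative" else 1.0
        sign_consistent = bool(np.sign(result.value) == expected)
    return table, result, sign_consistent
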
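"""Shared data model for paired primary-tumor (PT) / liver-metastasis (CLM) cohorts.

All genomic coordinates are 1-based and intervals are closed on both ends,
following VCF and segment-table conventions. Any half-open arithmetic is an
implementation detail and never crosses a public interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SAMPLE_ROLES = ("normal", "PT", "CLM")
ASSAYS = ("exome", "rna")
VERDICTS = ("keep", "reject", "absent")
CLASS_LABELS = ("class1", "class2", "class3", "unassessable")


class PtclmError(Exception):
    """Base class for all package errors."""


class FormatError(PtclmError):
    """A file does not conform to its documented layout."""


class ValidationError(PtclmError):
    """A value violates a documented invariant."""


class ContractError(PtclmError):
    """An operation was called outside its stated precondition."""


class ConfigurationError(PtclmError):
    """A pipeline configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class GenomicPosition:
    """A single 1-based genomic coordinate."""

    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError("chromosome must be non-empty")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")


@dataclass
class MutationObservation:
    """Read support for one variant in one (sample role, assay) slot."""

    sample_role: str
    assay: str
    ref_reads: int
    alt_reads: int
    caller_verdict: str = "absent"

    def __post_init__(self) -> None:
        if self.sample_role not in SAMPLE_ROLES:
            raise ValidationError(f"unknown sample role {self.sample_role!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValidationError(
                f"read counts must be non-negative, got ref={self.ref_reads} alt={self.alt_reads}"
            )
        if self.caller_verdict not in VERDICTS:
            raise ValidationError(f"unknown caller verdict {self.caller_verdict!r}")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele frequency alt/(ref+alt); None when depth is zero."""
        d = self.depth
        if d == 0:
            return None
        return self.alt_reads / d


@dataclass
class PairedMutationRecord:
    """One somatic variant observed across PT/CLM x exome/RNA for one patient.

    ``observations`` maps (sample_role, assay) to a MutationObservation.
    ``flank5``/``flank3`` carry the reference bases immediately 5' and 3' of
    the variant when known (needed only for trinucleotide spectra).
    Classification fields stay None until class assignment runs.
    """

    patient_id: str
    position: GenomicPosition
    ref_allele: str
    alt_allele: str
    gene: str = ""
    consequence: str = ""
    observations: dict = field(default_factory=dict)
    ma_score: Optional[float] = None
    flank5: Optional[str] = None
    flank3: Optional[str] = None
    class_label: Optional[str] = None
    class1h_15: Optional[bool] = None
    class1h_30: Optional[bool] = None

    def obs(self, sample_role: str, assay: str) -> Optional[MutationObservation]:
        return self.observations.get((sample_role, assay))

    def vaf(self, sample_role: str, assay: str) -> Optional[float]:
        o = self.obs(sample_role, assay)
        return None if o is None else o.vaf

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
        )

    @property
    def key(self):
        """Identity of the variant: (patient, chrom, pos, ref, alt)."""
        return (
            self.patient_id,
            self.position.chromosome,
            self.position.position,
            self.ref_allele,
            self.alt_allele,
        )


@dataclass
class CNASegment:
    """A copy-number segment with log2 tumor/normal ratio.

    ``sample`` identifies the tumor the segment belongs to as "patient:role".
    ``state`` is None until CNA calling, then one of deletion/neutral/amplification.
    """

    chromosome: str
    start: int
    end: int
    log2_ratio: float
    sample: str = ""
    state: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} on {self.chromosome}"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end


@dataclass
class SNPSite:
    """A SNP heterozygous in the matched normal, with tumor B-allele frequency.

    ``sample`` is "patient:role" naming the tumor whose BAF is recorded.
    ``loh`` stays None until LOH calling; it can also be None afterwards when
    the site is unevaluable (zero depth).
    """

    sample: str
    position: GenomicPosition
    normal_baf: float
    tumor_baf: float
    normal_depth: int
    tumor_depth: int
    loh: Optional[bool] = None

    def __post_init__(self) -> None:
        for name, v in (("normal_baf", self.normal_baf), ("tumor_baf", self.tumor_baf)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclass
class JunctionCount:
    """Read support for one exon-exon junction in one RNA sample.

    donor_end is the last base of the upstream exon, acceptor_start the first
    base of the downstream exon (both 1-based).
    """

    sample: str
    chromosome: str
    donor_end: int
    acceptor_start: int
    read_count: int

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValidationError(
                f"junction donor_end {self.donor_end} must precede acceptor_start "
                f"{self.acceptor_start}"
            )
        if self.read_count < 0:
            raise ValidationError("junction read_count must be >= 0")


@dataclass
class GeneModel:
    """Transcript anatomy: ordered exons plus the CDS span.

    Exons are 1-based closed intervals sorted in genomic order and
    non-overlapping. ``cds_start``/``cds_end`` bound the coding sequence in
    genomic coordinates; both None for a non-coding transcript.
    """

    gene: str
    transcript: str
    chromosome: str
    strand: str
    exons: list
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"exon start {s} > end {e} in {self.transcript}")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"exons must be sorted and non-overlapping in {self.transcript}"
                )
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError("cds_start and cds_end must both be set or both None")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_coding_length(self, index: int) -> int:
        """Number of coding bases in exon ``index`` (genomic order, 0-based)."""
        if self.cds_start is None:
            return 0
        s, e = self.exons[index]
        lo = max(s, self.cds_start)
        hi = min(e, self.cds_end)
        return max(0, hi - lo + 1)


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotation and externally inferred clonality."""

    patient_id: str
    lvi: bool
    t_stage: str
    msi_status: str
    clonality_pt: Optional[int] = None
    clonality_clm: Optional[int] = None

    def __post_init__(self) -> None:
        if self.t_stage not in ("T1", "T2", "T3", "T4"):
            raise ValidationError(f"t_stage must be T1..T4, got {self.t_stage!r}")
        if self.msi_status not in ("MSS", "MSI-high"):
            raise ValidationError(f"msi_status must be MSS or MSI-high, got {self.msi_status!r}")
        for name, v in (("clonality_pt", self.clonality_pt), ("clonality_clm", self.clonality_clm)):
            if v is not None and v < 1:
                raise ValidationError(f"{name} must be >= 1 when present, got {v}")

    @property
    def clonality_change(self) -> Optional[int]:
        if self.clonality_pt is None or self.clonality_clm is None:
            return None
        return self.clonality_clm - self.clonality_pt


class ExpressionMatrix:
    """Genes x samples table of RPKM values.

    Sample columns are named "patient:role" with role in normal/PT/CLM; the
    metadata accessors parse that convention. Values must be non-negative.
    """

    def __init__(self, values) -> None:
        import pandas as pd

        if not isinstance(values, pd.DataFrame):
            raise ValidationError("ExpressionMatrix requires a pandas DataFrame")
        arr = values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("RPKM values must be non-negative")
        self.values = values

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)

    def sample_meta(self):
        """DataFrame with columns sample, patient, role parsed from headers."""
        import pandas as pd

        rows = []
        for s in self.samples:
            patient, _, role = s.rpartition(":")
            rows.append({"sample": s, "patient": patient, "role": role})
        return pd.DataFrame(rows)

    def columns_for_role(self, role: str):
        return [s for s in self.samples if s.endswith(":" + role)]

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)
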
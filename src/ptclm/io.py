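"""Readers and writers for the cohort's tabular formats.

The primary interchange format for mutation calls is an 11-column TSV dialect
(patient, role, assay, chrom, pos, ref, alt, ref_reads, alt_reads, verdict,
gene) with optional extra columns (consequence, ma_score, flank5, flank3).
VCF 4.x is also accepted, with per-sample allele depths in AD and caller
verdict taken from FILTER (PASS -> keep, REJECT -> reject) or a per-sample
FORMAT field ``VD`` when present; VCF sample names encode role and assay as
``<role>_<assay>`` (e.g. ``PT_exome``) and the patient comes from a
``##patient=`` header line.

Segment, SNP, junction, gene-model, expression and clinical tables are plain
TSVs in the layouts documented on each reader.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Optional

import pandas as pd

from .model import (
    CNASegment,
    ClinicalRecord,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    GenomicPosition,
    JunctionCount,
    MutationObservation,
    PairedMutationRecord,
    SNPSite,
    ValidationError,
)

MUTATION_COLUMNS = [
    "patient", "role", "assay", "chrom", "pos", "ref", "alt",
    "ref_reads", "alt_reads", "verdict", "gene",
]
OPTIONAL_MUTATION_COLUMNS = ["consequence", "ma_score", "flank5", "flank3"]


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: chr2 before chr10, X/Y/M after numerics."""
    m = re.match(r"(?:chr)?(\d+)$", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_mutation_table(path, dialect: str = "tsv") -> List[PairedMutationRecord]:
    """Read somatic mutation calls into PairedMutationRecords.

    One record per unique (patient, chrom, pos, ref, alt); rows contribute
    per-(role, assay) observations. A duplicate (patient, site, role, assay)
    row is an error, not a silent overwrite.
    """
    if dialect == "vcf":
        return _read_mutation_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient": str})
    _require_columns(df, MUTATION_COLUMNS, path)
    records: dict = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.ref_reads < 0 or row.alt_reads < 0:
            raise ValidationError(f"{path}: negative read count at row {i}")
        key = (str(row.patient), str(row.chrom), int(row.pos), row.ref, row.alt)
        rec = records.get(key)
        if rec is None:
            rec = PairedMutationRecord(
                patient_id=str(row.patient),
                position=GenomicPosition(str(row.chrom), int(row.pos)),
                ref_allele=row.ref,
                alt_allele=row.alt,
                gene="" if pd.isna(row.gene) else str(row.gene),
            )
            for col in OPTIONAL_MUTATION_COLUMNS:
                if hasattr(row, col):
                    v = getattr(row, col)
                    if not pd.isna(v):
                        if col == "ma_score":
                            rec.ma_score = float(v)
                        else:
                            setattr(rec, col, str(v))
            records[key] = rec
        slot = (row.role, row.assay)
        if slot in rec.observations:
            raise ValidationError(
                f"{path}: duplicate observation for {key} slot {slot} at row {i}"
            )
        rec.observations[slot] = MutationObservation(
            sample_role=row.role,
            assay=row.assay,
            ref_reads=int(row.ref_reads),
            alt_reads=int(row.alt_reads),
            caller_verdict=row.verdict,
        )
    out = list(records.values())
    out.sort(key=lambda r: (chrom_sort_key(r.position.chromosome), r.position.position,
                            r.patient_id, r.ref_allele, r.alt_allele))
    return out


def write_mutation_table(records: Iterable[PairedMutationRecord], path) -> None:
    rows = []
    for rec in records:
        for (role, assay), o in sorted(rec.observations.items()):
            rows.append({
                "patient": rec.patient_id,
                "role": role,
                "assay": assay,
                "chrom": rec.position.chromosome,
                "pos": rec.position.position,
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "ref_reads": o.ref_reads,
                "alt_reads": o.alt_reads,
                "verdict": o.caller_verdict,
                "gene": rec.gene,
                "consequence": rec.consequence,
                "ma_score": "" if rec.ma_score is None else rec.ma_score,
                "flank5": "" if rec.flank5 is None else rec.flank5,
                "flank3": "" if rec.flank3 is None else rec.flank3,
            })
    pd.DataFrame(rows, columns=MUTATION_COLUMNS + OPTIONAL_MUTATION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def _read_mutation_vcf(path) -> List[PairedMutationRecord]:
    import pysam

    vf = pysam.VariantFile(str(path))
    patient = "unknown"
    for hrec in vf.header.records:
        line = str(hrec)
        if line.startswith("##patient="):
            patient = line.split("=", 1)[1].strip()
    records: dict = {}
    for var in vf:
        filt = list(var.filter.keys())
        verdict = "keep" if (not filt or filt == ["PASS"]) else "reject"
        for sname in var.samples:
            m = re.match(r"(normal|PT|CLM)_(exome|rna)$", sname)
            if not m:
                raise FormatError(
                    f"{path}: VCF sample {sname!r} must be named <role>_<assay>")
            sample = var.samples[sname]
            ad = sample.get("AD")
            if ad is None or ad[0] is None:
                continue
            sv = sample.get("VD")
            key = (patient, var.chrom, var.pos, var.ref, var.alts[0])
            rec = records.get(key)
            if rec is None:
                rec = PairedMutationRecord(
                    patient_id=patient,
                    position=GenomicPosition(var.chrom, var.pos),
                    ref_allele=var.ref,
                    alt_allele=var.alts[0],
                    gene=str(var.info.get("GENE", "")),
                )
                records[key] = rec
            rec.observations[(m.group(1), m.group(2))] = MutationObservation(
                sample_role=m.group(1),
                assay=m.group(2),
                ref_reads=int(ad[0]),
                alt_reads=int(ad[1]),
                caller_verdict=sv if sv is not None else verdict,
            )
    out = list(records.values())
    out.sort(key=lambda r: (chrom_sort_key(r.position.chromosome), r.position.position))
    return out


def read_segments(path) -> List[CNASegment]:
    """5-column TSV: chrom, start, end, log2_ratio, sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "start", "end", "log2_ratio", "sample"], path)
    segs = [
        CNASegment(str(r.chrom), int(r.start), int(r.end), float(r.log2_ratio),
                   str(r.sample))
        for r in df.itertuples(index=False)
    ]
    segs.sort(key=lambda s: (s.sample, chrom_sort_key(s.chromosome), s.start))
    return segs


def write_segments(segments: Iterable[CNASegment], path) -> None:
    pd.DataFrame([
        {"chrom": s.chromosome, "start": s.start, "end": s.end,
         "log2_ratio": s.log2_ratio, "sample": s.sample}
        for s in segments
    ], columns=["chrom", "start", "end", "log2_ratio", "sample"]).to_csv(
        path, sep="\t", index=False)


def read_snp_sites(path) -> List[SNPSite]:
    """7-column TSV: sample, chrom, pos, normal_baf, tumor_baf, normal_depth, tumor_depth."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(
        df, ["sample", "chrom", "pos", "normal_baf", "tumor_baf",
             "normal_depth", "tumor_depth"], path)
    snps = [
        SNPSite(str(r.sample), GenomicPosition(str(r.chrom), int(r.pos)),
                float(r.normal_baf), float(r.tumor_baf),
                int(r.normal_depth), int(r.tumor_depth))
        for r in df.itertuples(index=False)
    ]
    snps.sort(key=lambda s: (s.sample, chrom_sort_key(s.position.chromosome),
                             s.position.position))
    return snps


def write_snp_sites(snps: Iterable[SNPSite], path) -> None:
    pd.DataFrame([
        {"sample": s.sample, "chrom": s.position.chromosome, "pos": s.position.position,
         "normal_baf": s.normal_baf, "tumor_baf": s.tumor_baf,
         "normal_depth": s.normal_depth, "tumor_depth": s.tumor_depth}
        for s in snps
    ], columns=["sample", "chrom", "pos", "normal_baf", "tumor_baf",
                "normal_depth", "tumor_depth"]).to_csv(path, sep="\t", index=False)


def read_junctions(path) -> List[JunctionCount]:
    """BED-like 5-column TSV: sample, chrom, donor_end, acceptor_start, read_count."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["sample", "chrom", "donor_end", "acceptor_start",
                          "read_count"], path)
    juncs = [
        JunctionCount(str(r.sample), str(r.chrom), int(r.donor_end),
                      int(r.acceptor_start), int(r.read_count))
        for r in df.itertuples(index=False)
    ]
    juncs.sort(key=lambda j: (j.sample, chrom_sort_key(j.chromosome), j.donor_end))
    return juncs


def write_junctions(junctions: Iterable[JunctionCount], path) -> None:
    pd.DataFrame([
        {"sample": j.sample, "chrom": j.chromosome, "donor_end": j.donor_end,
         "acceptor_start": j.acceptor_start, "read_count": j.read_count}
        for j in junctions
    ], columns=["sample", "chrom", "donor_end", "acceptor_start",
                "read_count"]).to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> List[GeneModel]:
    """Gene models as BED12 (.bed/.bed12) or an exon TSV.

    The TSV layout is gene, transcript, chrom, strand, exon_starts,
    exon_ends (comma-separated 1-based closed), cds_start, cds_end (empty for
    non-coding). BED12 follows the UCSC convention (0-based half-open,
    thickStart/thickEnd bounding the CDS).
    """
    spath = str(path)
    if spath.endswith(".bed") or spath.endswith(".bed12"):
        models = _read_bed12(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        _require_columns(df, ["gene", "transcript", "chrom", "strand",
                              "exon_starts", "exon_ends"], path)
        models = []
        for r in df.itertuples(index=False):
            starts = [int(x) for x in str(r.exon_starts).split(",") if x]
            ends = [int(x) for x in str(r.exon_ends).split(",") if x]
            if len(starts) != len(ends):
                raise FormatError(f"{path}: exon_starts/exon_ends length mismatch "
                                  f"for {r.transcript}")
            cds_start = None if pd.isna(getattr(r, "cds_start", float("nan"))) else int(r.cds_start)
            cds_end = None if pd.isna(getattr(r, "cds_end", float("nan"))) else int(r.cds_end)
            models.append(GeneModel(
                gene=str(r.gene), transcript=str(r.transcript), chromosome=str(r.chrom),
                strand=str(r.strand), exons=list(zip(starts, ends)),
                cds_start=cds_start, cds_end=cds_end))
    models.sort(key=lambda m: (chrom_sort_key(m.chromosome),
                               m.exons[0][0] if m.exons else 0, m.transcript))
    return models


def _read_bed12(path) -> List[GeneModel]:
    models = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {line_no}: BED12 needs 12 fields")
            chrom, chrom_start, name = f[0], int(f[1]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(chrom_start + o + 1, chrom_start + o + sz)
                     for o, sz in zip(offsets, sizes)]
            gene, _, transcript = name.partition("|")
            if thick_start == thick_end:
                cds_start = cds_end = None
            else:
                cds_start, cds_end = thick_start + 1, thick_end
            models.append(GeneModel(
                gene=gene, transcript=transcript or name, chromosome=chrom,
                strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end))
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    """Write the exon TSV layout (lossless for GeneModel)."""
    pd.DataFrame([
        {"gene": m.gene, "transcript": m.transcript, "chrom": m.chromosome,
         "strand": m.strand,
         "exon_starts": ",".join(str(s) for s, _ in m.exons),
         "exon_ends": ",".join(str(e) for _, e in m.exons),
         "cds_start": "" if m.cds_start is None else m.cds_start,
         "cds_end": "" if m.cds_end is None else m.cds_end}
        for m in models
    ], columns=["gene", "transcript", "chrom", "strand", "exon_starts",
                "exon_ends", "cds_start", "cds_end"]).to_csv(
        path, sep="\t", index=False)


def read_expression(path) -> ExpressionMatrix:
    """Genes x samples TSV with a ``gene`` index column and sample headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> List[ClinicalRecord]:
    """TSV: patient, lvi (0/1), t_stage, msi_status, clonality_pt, clonality_clm."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    _require_columns(df, ["patient", "lvi", "t_stage", "msi_status"], path)
    out = []
    for r in df.itertuples(index=False):
        cpt = getattr(r, "clonality_pt", None)
        cclm = getattr(r, "clonality_clm", None)
        out.append(ClinicalRecord(
            patient_id=str(r.patient), lvi=bool(int(r.lvi)),
            t_stage=str(r.t_stage), msi_status=str(r.msi_status),
            clonality_pt=None if cpt is None or pd.isna(cpt) else int(cpt),
            clonality_clm=None if cclm is None or pd.isna(cclm) else int(cclm)))
    return out


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    pd.DataFrame([
        {"patient": c.patient_id, "lvi": int(c.lvi), "t_stage": c.t_stage,
         "msi_status": c.msi_status,
         "clonality_pt": "" if c.clonality_pt is None else c.clonality_pt,
         "clonality_clm": "" if c.clonality_clm is None else c.clonality_clm}
        for c in records
    ], columns=["patient", "lvi", "t_stage", "msi_status", "clonality_pt",
                "clonality_clm"]).to_csv(path, sep="\t", index=False)
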
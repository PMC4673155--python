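"""Synthetic paired-cohort generator with ground truth.

Emulates the inputs of a paired normal / primary-tumor (PT) / liver-metastasis
(CLM) study profiled by exome and RNA sequencing: somatic mutation tables with
read counts and caller verdicts for both assays, copy-number segments,
heterozygous-SNP B-allele frequencies, an RPKM expression matrix, exon-exon
junction counts, gene models, and clinical annotation. Every emitted
observation is covered by a ground-truth table so downstream stages can be
scored exactly.

The generative model, per mutation:

    expected VAF = purity * CCF * mutant_copies
                   / (purity * tumor_CN + (1 - purity) * 2)

with read depth ~ Poisson(mean depth, floor 1) and alt reads ~
Binomial(depth, expected VAF). Shared mutations carry the same cancer-cell
fraction (CCF) in both tumors; PT-specific mutations have CLM CCF 0 and vice
versa. Class 1-H mutations (VAF rises >= 15 points during metastasis) are
planted as a PT subclone (CCF 0.5) that becomes clonal in the CLM and either
loses the wild-type allele outright (a deletion segment is superimposed) or
undergoes copy-neutral LOH (two mutant copies of two) — the two mechanisms the
class is designed to capture. Deletions induce LOH at the heterozygous SNPs
they cover; allele-specific expression (ASE) multiplies the mutant-allele
sampling probability in RNA only; target-gene expression couples linearly to
the driver's true RNA VAF; junction reads are drawn multinomially around the
configured percent-spliced-in (PSI).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import (
    CNASegment,
    ClinicalRecord,
    ContractError,
    ExpressionMatrix,
    GeneModel,
    GenomicPosition,
    JunctionCount,
    MutationObservation,
    PairedMutationRecord,
    SNPSite,
    ValidationError,
)

CHROMS = tuple(f"chr{i}" for i in range(1, 23))
CHROM_LEN = 100_000_000
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def expected_vaf(purity: float, ccf: float, mutant_copies: int,
                 total_tumor_cn: int) -> float:
    """Expected variant allele frequency of a somatic mutation.

    A fraction ``purity`` of cells are tumor cells; of those, ``ccf`` carry
    the mutation on ``mutant_copies`` of ``total_tumor_cn`` local copies;
    admixed normal cells contribute two reference copies.
    """
    if not (0.0 <= purity <= 1.0):
        raise ValidationError(f"purity must be in [0,1], got {purity}")
    if not (0.0 <= ccf <= 1.0):
        raise ValidationError(f"ccf must be in [0,1], got {ccf}")
    if mutant_copies < 0 or total_tumor_cn < mutant_copies:
        raise ValidationError(
            f"need 0 <= mutant_copies <= total_tumor_cn, got "
            f"{mutant_copies}/{total_tumor_cn}")
    denom = purity * total_tumor_cn + (1.0 - purity) * 2.0
    if denom == 0.0:
        raise ContractError(
            "degenerate input: purity 1 with zero tumor copy number")
    return purity * ccf * mutant_copies / denom


def _default_deletion_rates() -> Dict[str, float]:
    return {"class1": 0.058, "class2": 0.0413, "class3": 0.0423,
            "class1h": 0.20}


def _default_ase_drivers() -> Dict[str, Tuple[float, float]]:
    # driver -> (min, max) of the per-patient mutant-allele skew factor
    return {"TP53": (1.0, 2.0), "APC": (1.0, 3.0)}


def _default_target_coupling() -> Dict[str, float]:
    # driver -> slope of mean target-gene log2 expression per unit RNA VAF
    return {"TP53": -2.0, "APC": 2.0}


def _default_expression_sd() -> Dict[str, float]:
    # transcriptome variability widens from normal tissue to metastasis
    return {"normal": 0.30, "PT": 0.45, "CLM": 0.60}


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the paired-cohort design the analysis targets: 19
    patients, mean mathematically estimated purities 0.466 (PT) and 0.476
    (CLM), shared/PT-only/CLM-only mutation mix 0.576/0.209/0.215, and
    deletion-superposition rates per class taken from the co-occurrence
    frequencies the analysis is meant to recover.
    """

    n_patients: int = 19
    mutations_per_patient: int = 105
    purity_pt: float = 0.466
    purity_clm: float = 0.476
    mean_depth_exome: float = 100.0
    mean_depth_rna: float = 80.0
    class_mix: Tuple[float, float, float] = (0.576, 0.209, 0.215)
    class1h_fraction: float = 0.10
    class1h_pt_ccf: float = 0.5
    subclonal_fraction: float = 0.15
    subclonal_ccf_range: Tuple[float, float] = (0.5, 1.0)
    deletion_rates: Dict[str, float] = field(default_factory=_default_deletion_rates)
    amplification_rate: float = 0.03
    deletion_halfwidth: int = 200_000
    rescue_fraction: float = 0.05
    decoy_reject_fraction: float = 0.05
    rna_only_fraction: float = 0.03
    low_expression_fraction: float = 0.10
    low_expression_rna_depth: float = 2.0
    snps_per_mutation: int = 10
    snp_window: int = 1_000_000
    snp_mean_depth: float = 60.0
    background_loh_rate: float = 0.02
    loh_baf: float = 0.9
    ase_drivers: Dict[str, Tuple[float, float]] = field(default_factory=_default_ase_drivers)
    target_coupling: Dict[str, float] = field(default_factory=_default_target_coupling)
    target_noise_sd: float = 0.3
    ma_noise_sd: float = 0.5
    n_background_genes: int = 200
    n_low_genes: int = 40
    expression_sd_by_group: Dict[str, float] = field(default_factory=_default_expression_sd)
    skipping_events: Tuple[Tuple[str, int, float], ...] = (
        ("SKPA", 2, 0.5), ("SKPB", 3, 0.5))
    null_splice_genes: Tuple[str, ...] = ("SKPC", "SKPD")
    junction_mean_reads: float = 2000.0
    noncarrier_psi: float = 0.01
    spectrum_weights_pt: Tuple[float, ...] = (0.10, 0.07, 0.574, 0.06, 0.146, 0.05)
    spectrum_weights_clm: Tuple[float, ...] = (0.14, 0.09, 0.463, 0.08, 0.161, 0.066)
    lvi_class1_multiplier: float = 1.0
    clonality_coupling: Optional[Tuple[float, float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValidationError(
                f"class_mix must sum to 1, got {sum(self.class_mix)}")
        for name in ("purity_pt", "purity_clm", "class1h_fraction",
                     "subclonal_fraction", "rescue_fraction",
                     "decoy_reject_fraction", "rna_only_fraction",
                     "low_expression_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")


@dataclass
class SyntheticCohortTruth:
    """Ground truth covering every emitted observation."""

    mutations: pd.DataFrame  # one row per mutation with true class/CCF/CN/ASE
    snps: pd.DataFrame       # one row per SNP site with true LOH status
    skipping: pd.DataFrame   # one row per splice-site mutation with true PSI
    params: SimulationParams


@dataclass
class SyntheticCohort:
    """All inputs for the downstream stages, plus the truth."""

    records: List[PairedMutationRecord]
    segments: List[CNASegment]
    snp_sites: List[SNPSite]
    junctions: List[JunctionCount]
    gene_models: List[GeneModel]
    expression: ExpressionMatrix
    clinical: List[ClinicalRecord]
    truth: SyntheticCohortTruth


def _patient_mix(params: SimulationParams, rng, lvi: bool):
    """Per-patient class mix with optional clinical/clonality couplings.

    Returns (mix, clonality_change or None)."""
    w1, w2, w3 = params.class_mix
    dc = None
    if params.clonality_coupling is not None:
        intercept, slope, sigma = params.clonality_coupling
        dc = int(rng.integers(-2, 3))
        f1 = float(np.clip(intercept + slope * dc + rng.normal(0, sigma),
                           0.05, 0.95))
        rest = w2 + w3
        w1, w2, w3 = f1, (1 - f1) * w2 / rest, (1 - f1) * w3 / rest
    if lvi and params.lvi_class1_multiplier != 1.0:
        w1 *= params.lvi_class1_multiplier
    total = w1 + w2 + w3
    return (w1 / total, w2 / total, w3 / total), dc


def _make_gene_models(params: SimulationParams) -> List[GeneModel]:
    """Six-exon plus-strand transcripts on chr20, spaced well apart."""
    exon_lengths = [300, 120, 100, 99, 87, 210]
    intron = 500
    models = []
    genes = [g for g, _, _ in params.skipping_events] + list(params.null_splice_genes)
    for i, gene in enumerate(genes):
        start = 1_000_000 + i * 100_000
        exons = []
        pos = start
        for L in exon_lengths:
            exons.append((pos, pos + L - 1))
            pos += L + intron
        cds_start = exons[0][0] + 60
        cds_end = exons[-1][0] + 29
        models.append(GeneModel(gene=gene, transcript=f"{gene}-T1",
                                chromosome="chr20", strand="+", exons=exons,
                                cds_start=cds_start, cds_end=cds_end))
    return models


def _draw_substitution(rng, weights):
    """(ref, alt, flank5, flank3) with random strand representation."""
    cls = SUB_CLASSES[rng.choice(6, p=np.asarray(weights) / np.sum(weights))]
    ref, alt = cls[0], cls[2]
    if rng.random() < 0.5:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    f5, f3 = rng.choice(list("ACGT"), size=2)
    return ref, alt, str(f5), str(f3)


def simulate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Generate one cohort and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(params.seed)
    patients = [f"P{i + 1:02d}" for i in range(params.n_patients)]

    clinical: List[ClinicalRecord] = []
    mixes = {}
    for pid in patients:
        lvi = bool(rng.random() < 0.5)
        mix, dc = _patient_mix(params, rng, lvi)
        mixes[pid] = mix
        clon_pt = int(rng.integers(2, 6))
        if dc is None:
            dc = int(rng.integers(-2, 3))
        clinical.append(ClinicalRecord(
            patient_id=pid, lvi=lvi,
            t_stage=str(rng.choice(["T2", "T3", "T4"], p=[0.3, 0.4, 0.3])),
            msi_status=str(rng.choice(["MSS", "MSI-high"], p=[0.85, 0.15])),
            clonality_pt=clon_pt,
            clonality_clm=int(np.clip(clon_pt + dc, 1, 8))))

    gene_models = _make_gene_models(params)
    models_by_gene = {m.gene: m for m in gene_models}

    avg_weights = (np.asarray(params.spectrum_weights_pt)
                   + np.asarray(params.spectrum_weights_clm)) / 2.0

    # ------------------------------------------------------------------ #
    # mutation truth assembly                                            #
    # ------------------------------------------------------------------ #
    truth_rows: List[dict] = []
    segments: List[CNASegment] = []
    seg_spans: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    del_spans: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    half = params.deletion_halfwidth

    def _plant_segment(pid, role, chrom, pos, log2):
        key = (f"{pid}:{role}", chrom)
        spans = seg_spans.setdefault(key, [])
        lo, hi = max(1, pos - half), pos + half
        if any(hi >= s and lo <= e for s, e in spans):
            return False
        spans.append((lo, hi))
        if log2 < 0:
            del_spans.setdefault(key, []).append((lo, hi))
        segments.append(CNASegment(chromosome=chrom, start=lo, end=hi,
                                   log2_ratio=log2, sample=f"{pid}:{role}"))
        return True

    low_gene_cursor = 0
    bg_gene_cursor = 0
    for pid in patients:
        mix = mixes[pid]
        for _ in range(params.mutations_per_patient):
            u = rng.random()
            if u < mix[0]:
                cls = "class1"
            elif u < mix[0] + mix[1]:
                cls = "class2"
            else:
                cls = "class3"
            group = cls
            if cls == "class1" and rng.random() < params.class1h_fraction:
                group = "class1h"

            # clone structure
            if group == "class1h":
                ccf_pt, ccf_clm = params.class1h_pt_ccf, 1.0
            else:
                if rng.random() < params.subclonal_fraction:
                    ccf = float(rng.uniform(*params.subclonal_ccf_range))
                else:
                    ccf = 1.0
                ccf_pt = ccf if cls != "class3" else 0.0
                ccf_clm = ccf if cls != "class2" else 0.0

            # copy number / deletion superposition
            cn_pt = cn_clm = 2
            mult_pt = 1 if ccf_pt > 0 else 0
            mult_clm = 1 if ccf_clm > 0 else 0
            del_role = ""
            target_role = "PT" if cls == "class2" else "CLM"
            deleted = rng.random() < params.deletion_rates.get(group, 0.0)
            # class1h VAF gains come from allelic loss, never amplification
            amplified = (group != "class1h" and not deleted
                         and rng.random() < params.amplification_rate)

            chrom = CHROMS[int(rng.integers(0, len(CHROMS)))]
            pos = int(rng.integers(half + 1, CHROM_LEN - half))
            if deleted or amplified:
                log2 = (float(rng.uniform(-1.2, -0.7)) if deleted
                        else float(rng.uniform(0.7, 1.2)))
                planted = False
                for _attempt in range(50):
                    if _plant_segment(pid, target_role, chrom, pos, log2):
                        planted = True
                        break
                    pos = int(rng.integers(half + 1, CHROM_LEN - half))
                if not planted:
                    deleted = amplified = False
            if deleted:
                del_role = target_role
                if target_role == "PT":
                    cn_pt, mult_pt = 1, min(1, mult_pt)
                else:
                    cn_clm, mult_clm = 1, min(1, mult_clm)
            elif amplified:
                if target_role == "PT":
                    cn_pt = 4
                else:
                    cn_clm = 4
            elif group == "class1h":
                cn_clm, mult_clm = 2, 2  # copy-neutral LOH in the metastasis

            low_expr = rng.random() < params.low_expression_fraction
            if low_expr and params.n_low_genes > 0:
                gene = f"LOW{low_gene_cursor % params.n_low_genes + 1:03d}"
                low_gene_cursor += 1
            elif params.n_background_genes > 0:
                gene = f"BG{bg_gene_cursor % params.n_background_genes + 1:03d}"
                bg_gene_cursor += 1
            else:
                gene = ""

            weights = {"class2": params.spectrum_weights_pt,
                       "class3": params.spectrum_weights_clm}.get(group, avg_weights)
            ref, alt, f5, f3 = _draw_substitution(rng, weights)

            truth_rows.append(dict(
                patient=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                flank5=f5, flank3=f3, gene=gene, group=group,
                true_class=cls, true_class1h=(group == "class1h"),
                ccf_pt=ccf_pt, ccf_clm=ccf_clm, cn_pt=cn_pt, cn_clm=cn_clm,
                mult_pt=mult_pt, mult_clm=mult_clm, deletion_role=del_role,
                ase_skew=1.0, low_expression=low_expr, rna_only=False,
                rescued=False, decoy_reject=False, consequence="nonsynonymous"))

        # one mutation per ASE driver per patient (shared, clonal)
        for driver, (lo_skew, hi_skew) in params.ase_drivers.items():
            skew = float(rng.uniform(lo_skew, hi_skew))
            cn_clm, mult_clm = (2, 2) if driver == "TP53" else (2, 1)
            chrom = "chr17" if driver == "TP53" else "chr5"
            pos = 7_578_000 if driver == "TP53" else 112_170_000
            ref, alt, f5, f3 = _draw_substitution(rng, avg_weights)
            truth_rows.append(dict(
                patient=pid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                flank5=f5, flank3=f3, gene=driver, group="driver",
                true_class="class1", true_class1h=False,
                ccf_pt=1.0, ccf_clm=1.0, cn_pt=2, cn_clm=cn_clm,
                mult_pt=1, mult_clm=mult_clm, deletion_role="",
                ase_skew=skew, low_expression=False, rna_only=False,
                rescued=False, decoy_reject=False, consequence="nonsynonymous"))

    # splice-site mutations (planted skipping + null controls)
    skipping_rows = []
    splice_specs = [(g, k, psi, True) for g, k, psi in params.skipping_events]
    splice_specs += [(g, 2, params.noncarrier_psi, False)
                     for g in params.null_splice_genes]
    for i, (gene, exon_index, psi, planted) in enumerate(splice_specs):
        if params.n_patients == 0:
            break
        carrier = patients[i % params.n_patients]
        model = models_by_gene[gene]
        pos = model.exons[exon_index][1] + 1  # first intronic base (donor +1)
        truth_rows.append(dict(
            patient=carrier, chrom=model.chromosome, pos=pos, ref="G", alt="A",
            flank5="A", flank3="T", gene=gene, group="splice",
            true_class="class1", true_class1h=False,
            ccf_pt=1.0, ccf_clm=1.0, cn_pt=2, cn_clm=2, mult_pt=1, mult_clm=1,
            deletion_role="", ase_skew=1.0, low_expression=False,
            rna_only=False, rescued=False, decoy_reject=False,
            consequence="splice-site"))
        skipping_rows.append(dict(gene=gene, exon_index=exon_index,
                                  carrier_patient=carrier, carrier_psi=psi,
                                  planted=planted))
    truth = pd.DataFrame(truth_rows)
    skipping = pd.DataFrame(skipping_rows, columns=[
        "gene", "exon_index", "carrier_patient", "carrier_psi", "planted"])

    # rna-only / rescue / decoy planting over the non-driver bulk
    if len(truth) > 0:
        plain = truth.index[(truth["group"].isin(["class1", "class1h", "class2",
                                                  "class3"]))
                            & ~truth["low_expression"]].to_numpy()
        rng.shuffle(plain)
        n_rna_only = int(round(params.rna_only_fraction * len(truth)))
        n_rescue = int(round(params.rescue_fraction * len(truth)))
        n_decoy = int(round(params.decoy_reject_fraction * len(truth)))
        take = plain[: n_rna_only + n_rescue + n_decoy]
        truth.loc[take[:n_rna_only], "rna_only"] = True
        truth.loc[take[n_rna_only:n_rna_only + n_rescue], "rescued"] = True
        truth.loc[take[n_rna_only + n_rescue:], "decoy_reject"] = True

    # ------------------------------------------------------------------ #
    # read counts (vectorized)                                           #
    # ------------------------------------------------------------------ #
    n = len(truth)
    records: List[PairedMutationRecord] = []
    if n > 0:
        p_ex = {}
        p_rna = {}
        for role, purity in (("PT", params.purity_pt), ("CLM", params.purity_clm)):
            ccf = truth["ccf_pt"].to_numpy() if role == "PT" else truth["ccf_clm"].to_numpy()
            cn = truth["cn_pt"].to_numpy() if role == "PT" else truth["cn_clm"].to_numpy()
            mult = truth["mult_pt"].to_numpy() if role == "PT" else truth["mult_clm"].to_numpy()
            denom = purity * cn + (1 - purity) * 2.0
            p = purity * ccf * mult / denom
            p_ex[role] = p
            p_rna[role] = np.minimum(0.98, p * truth["ase_skew"].to_numpy())
        truth["expected_vaf_pt_exome"] = p_ex["PT"]
        truth["expected_vaf_clm_exome"] = p_ex["CLM"]
        truth["expected_vaf_pt_rna"] = p_rna["PT"]
        truth["expected_vaf_clm_rna"] = p_rna["CLM"]

        rna_only = truth["rna_only"].to_numpy()
        low_expr = truth["low_expression"].to_numpy()
        depth_ex = {r: np.maximum(1, rng.poisson(params.mean_depth_exome, n))
                    for r in ("PT", "CLM")}
        for r in ("PT", "CLM"):
            # rna-only sites sit in poorly captured exome regions
            depth_ex[r] = np.where(rna_only, np.maximum(1, rng.poisson(5.0, n)),
                                   depth_ex[r])
        depth_n = np.maximum(1, rng.poisson(params.mean_depth_exome, n))
        rna_mean = np.where(low_expr, params.low_expression_rna_depth,
                            params.mean_depth_rna)
        depth_rna = {r: rng.poisson(rna_mean) for r in ("PT", "CLM")}
        alt_ex = {r: rng.binomial(depth_ex[r], p_ex[r]) for r in ("PT", "CLM")}
        alt_rna = {r: rng.binomial(depth_rna[r], p_rna[r]) for r in ("PT", "CLM")}

        # MA score couples to the true CLM RNA VAF
        ma = np.maximum(0.0, 1.0 + 2.0 * truth["expected_vaf_clm_rna"].to_numpy()
                        + rng.normal(0.0, params.ma_noise_sd, n))
        truth["ma_score"] = ma

        rescued = truth["rescued"].to_numpy()
        decoy = truth["decoy_reject"].to_numpy()
        # role whose exome verdict is rejected for rescue/decoy planting
        rej_role = np.where(truth["true_class"].to_numpy() == "class3", "CLM",
                            np.where(truth["true_class"].to_numpy() == "class2",
                                     "PT",
                                     np.where(rng.random(n) < 0.5, "PT", "CLM")))
        decoy_kind = rng.random(n) < 0.5  # True: RNA reject; False: shallow RNA

        col = {name: truth[name].to_numpy() for name in
               ("patient", "chrom", "pos", "ref", "alt", "gene", "consequence",
                "flank5", "flank3")}
        for i in range(n):
            obs = {}
            obs[("normal", "exome")] = MutationObservation(
                "normal", "exome", int(depth_n[i]), 0, "absent")
            for r in ("PT", "CLM"):
                a_e, d_e = int(alt_ex[r][i]), int(depth_ex[r][i])
                verdict_e = "keep" if a_e >= 1 else "absent"
                a_r, d_r = int(alt_rna[r][i]), int(depth_rna[r][i])
                verdict_r = "keep" if a_r >= 1 else "absent"
                if (rescued[i] or decoy[i]) and rej_role[i] == r:
                    verdict_e = "reject"
                    if rescued[i]:
                        d_r = max(d_r, 11)
                        a_r = max(a_r, 1)
                        verdict_r = "keep"
                    elif decoy_kind[i]:
                        verdict_r = "reject" if d_r > 0 else "absent"
                    else:
                        d_r = int(rng.integers(1, 11))
                        a_r = min(a_r, d_r)
                        a_r = max(a_r, 1)
                        verdict_r = "keep"
                obs[(r, "exome")] = MutationObservation(r, "exome",
                                                        d_e - a_e, a_e, verdict_e)
                obs[(r, "rna")] = MutationObservation(r, "rna",
                                                      d_r - a_r, a_r, verdict_r)
            records.append(PairedMutationRecord(
                patient_id=col["patient"][i],
                position=GenomicPosition(col["chrom"][i], int(col["pos"][i])),
                ref_allele=col["ref"][i], alt_allele=col["alt"][i],
                gene=col["gene"][i], consequence=col["consequence"][i],
                observations=obs, ma_score=float(ma[i]),
                flank5=col["flank5"][i], flank3=col["flank3"][i]))

    # ------------------------------------------------------------------ #
    # heterozygous SNP sites around mutations                            #
    # ------------------------------------------------------------------ #
    snp_sites: List[SNPSite] = []
    snp_truth_rows = []
    if n > 0 and params.snps_per_mutation > 0:
        reps = params.snps_per_mutation
        mut_chrom = np.repeat(truth["chrom"].to_numpy(), reps)
        mut_pos = np.repeat(truth["pos"].to_numpy(), reps)
        mut_patient = np.repeat(truth["patient"].to_numpy(), reps)
        offsets = rng.integers(-params.snp_window, params.snp_window,
                               size=n * reps)
        spos = np.maximum(1, mut_pos + offsets)
        for role in ("PT", "CLM"):
            m = n * reps
            nd = np.maximum(1, rng.poisson(params.snp_mean_depth, m))
            td = np.maximum(1, rng.poisson(params.snp_mean_depth, m))
            # inside a deletion of this sample?
            in_del = np.zeros(m, dtype=bool)
            for j in range(m):
                spans = del_spans.get((f"{mut_patient[j]}:{role}", mut_chrom[j]))
                if spans:
                    p = spos[j]
                    in_del[j] = any(lo <= p <= hi for lo, hi in spans)
            true_loh = in_del | (rng.random(m) < params.background_loh_rate)
            shifted = np.where(rng.random(m) < 0.5, params.loh_baf,
                               1.0 - params.loh_baf)
            p_baf = np.where(true_loh, shifted, 0.5)
            nb = rng.binomial(nd, 0.5) / nd
            tb = rng.binomial(td, p_baf) / td
            for j in range(m):
                snp_sites.append(SNPSite(
                    sample=f"{mut_patient[j]}:{role}",
                    position=GenomicPosition(mut_chrom[j], int(spos[j])),
                    normal_baf=float(nb[j]), tumor_baf=float(tb[j]),
                    normal_depth=int(nd[j]), tumor_depth=int(td[j])))
                snp_truth_rows.append(dict(
                    sample=f"{mut_patient[j]}:{role}", chrom=mut_chrom[j],
                    pos=int(spos[j]), in_deletion=bool(in_del[j]),
                    true_loh=bool(true_loh[j])))
    snp_truth = pd.DataFrame(snp_truth_rows, columns=[
        "sample", "chrom", "pos", "in_deletion", "true_loh"])

    # ------------------------------------------------------------------ #
    # junction reads                                                     #
    # ------------------------------------------------------------------ #
    junctions: List[JunctionCount] = []
    skip_by_gene = {r["gene"]: r for r in skipping_rows}
    for pid in patients:
        for role in ("PT", "CLM"):
            sample = f"{pid}:{role}"
            for model in gene_models:
                ev = skip_by_gene.get(model.gene)
                k = ev["exon_index"] if ev else None
                psi = (ev["carrier_psi"]
                       if ev and ev["carrier_patient"] == pid
                       else params.noncarrier_psi)
                counts: Dict[Tuple[int, int], int] = {}
                for j in range(model.n_exons - 1):
                    counts[(model.exons[j][1], model.exons[j + 1][0])] = int(
                        rng.poisson(params.junction_mean_reads))
                if k is not None and 0 < k < model.n_exons - 1:
                    total = int(rng.poisson(2 * params.junction_mean_reads))
                    skip_c, inc_l, inc_r = rng.multinomial(
                        total, [psi, (1 - psi) / 2, (1 - psi) / 2])
                    counts[(model.exons[k - 1][1], model.exons[k][0])] = int(inc_l)
                    counts[(model.exons[k][1], model.exons[k + 1][0])] = int(inc_r)
                    if skip_c > 0:
                        counts[(model.exons[k - 1][1],
                                model.exons[k + 1][0])] = int(skip_c)
                for (d, a), c in sorted(counts.items()):
                    junctions.append(JunctionCount(
                        sample=sample, chromosome=model.chromosome,
                        donor_end=d, acceptor_start=a, read_count=c))

    # ------------------------------------------------------------------ #
    # expression matrix                                                  #
    # ------------------------------------------------------------------ #
    from .rna import P53_TARGETS, WNT_TARGETS

    genes = ([f"BG{i + 1:03d}" for i in range(params.n_background_genes)]
             + [f"LOW{i + 1:03d}" for i in range(params.n_low_genes)]
             + P53_TARGETS + WNT_TARGETS)
    samples = [f"{pid}:{role}" for pid in patients
               for role in ("normal", "PT", "CLM")]
    baselines = np.concatenate([
        rng.normal(3.0, 1.5, params.n_background_genes),
        rng.normal(-3.0, 0.5, params.n_low_genes),
        rng.normal(4.0, 0.5, len(P53_TARGETS) + len(WNT_TARGETS)),
    ])
    driver_rna_vaf = {}
    if n > 0:
        for driver in params.ase_drivers:
            sub = truth[truth["gene"] == driver]
            for _, row in sub.iterrows():
                driver_rna_vaf[(row["patient"], "PT", driver)] = row["expected_vaf_pt_rna"]
                driver_rna_vaf[(row["patient"], "CLM", driver)] = row["expected_vaf_clm_rna"]
    target_driver = {g: "TP53" for g in P53_TARGETS}
    target_driver.update({g: "APC" for g in WNT_TARGETS})
    data = np.empty((len(genes), len(samples)))
    for sj, sample in enumerate(samples):
        pid, _, role = sample.rpartition(":")
        sd = params.expression_sd_by_group[role]
        col = baselines + rng.normal(0.0, sd, len(genes))
        if role in ("PT", "CLM"):
            for gi, g in enumerate(genes):
                drv = target_driver.get(g)
                if drv is None:
                    continue
                v = driver_rna_vaf.get((pid, role, drv))
                if v is None:
                    continue
                slope = params.target_coupling.get(drv, 0.0)
                col[gi] = (baselines[gi] + slope * v
                           + rng.normal(0.0, params.target_noise_sd))
        data[:, sj] = col
    expression = ExpressionMatrix(
        pd.DataFrame(np.power(2.0, data), index=genes, columns=samples))

    segments.sort(key=lambda s: (s.sample, s.chromosome, s.start))
    return SyntheticCohort(
        records=records, segments=segments, snp_sites=snp_sites,
        junctions=junctions, gene_models=gene_models, expression=expression,
        clinical=clinical,
        truth=SyntheticCohortTruth(mutations=truth, snps=snp_truth,
                                   skipping=skipping, params=params))


def write_cohort(cohort: SyntheticCohort, out_dir) -> Dict[str, str]:
    """Write all input tables (and the truth) under out_dir; returns the paths."""
    import os

    from . import io as pio

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "segments": os.path.join(out_dir, "segments.tsv"),
        "snp_sites": os.path.join(out_dir, "snp_sites.tsv"),
        "junctions": os.path.join(out_dir, "junctions.tsv"),
        "gene_models": os.path.join(out_dir, "gene_models.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "clinical": os.path.join(out_dir, "clinical.tsv"),
    }
    pio.write_mutation_table(cohort.records, paths["mutations"])
    pio.write_segments(cohort.segments, paths["segments"])
    pio.write_snp_sites(cohort.snp_sites, paths["snp_sites"])
    pio.write_junctions(cohort.junctions, paths["junctions"])
    pio.write_gene_models(cohort.gene_models, paths["gene_models"])
    pio.write_expression(cohort.expression, paths["expression"])
    pio.write_clinical(cohort.clinical, paths["clinical"])
    cohort.truth.mutations.to_csv(os.path.join(out_dir, "truth_mutations.tsv"),
                                  sep="\t", index=False)
    cohort.truth.snps.to_csv(os.path.join(out_dir, "truth_snps.tsv"),
                             sep="\t", index=False)
    cohort.truth.skipping.to_csv(os.path.join(out_dir, "truth_skipping.tsv"),
                                 sep="\t", index=False)
    return paths
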
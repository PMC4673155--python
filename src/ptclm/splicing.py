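"""Expression summaries and mutation-dependent splicing detection.

RPKM normalizes raw gene counts by transcript length and library size.
Per-gene expression variability (SD of log2(RPKM+1) within a tissue group)
summarizes transcriptome destabilization along the normal -> primary ->
metastasis axis.

Splice-site mutations are variants landing in the two canonical intronic
bases (the GT/AG dinucleotides) adjacent to an exon boundary. For each such
mutation we test whether the adjacent exon is skipped specifically in the
mutation carrier: the skip ratio contrasts reads on the exon-skipping
junction (exon k-1 -> k+1) against the mean of the two inclusion junctions,
and a call is flagged only when the carrier's ratio is high, every
non-carrier's is low, and the carrier junction depth is adequate. Skipping a
coding exon whose length is not a multiple of 3 shifts the reading frame and
predicts a premature stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    ContractError,
    ExpressionMatrix,
    GeneModel,
    JunctionCount,
    PairedMutationRecord,
)


def compute_rpkm(read_count: float, gene_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length <= 0:
        raise ContractError(f"gene_length must be > 0, got {gene_length}")
    if total_mapped <= 0:
        raise ContractError(f"total_mapped must be > 0, got {total_mapped}")
    return read_count / (gene_length / 1_000) / (total_mapped / 1_000_000)


def expression_sd_distribution(matrix: ExpressionMatrix,
                               groups: Sequence[str] = ("normal", "PT", "CLM")):
    """Per-gene SD of log2(RPKM+1) within each tissue group, plus pairwise
    Mann-Whitney location tests between the group SD distributions.

    Returns (sds DataFrame genes x groups, dict of {(g1, g2): {u, p, median_g1,
    median_g2}}).
    """
    log2 = np.log2(matrix.values + 1.0)
    sds = {}
    for group in groups:
        cols = matrix.columns_for_role(group) if hasattr(matrix, "columns_for_role") else []
        if len(cols) < 2:
            raise ContractError(
                f"group {group!r} has {len(cols)} sample(s); need >= 2 for SDs")
        sds[group] = log2[cols].std(axis=1, ddof=1)
    sds_df = pd.DataFrame(sds)
    tests = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            u, p = sps.mannwhitneyu(sds_df[g1], sds_df[g2], alternative="two-sided")
            tests[(g1, g2)] = {"u": float(u), "p": float(p),
                               f"median_{g1}": float(sds_df[g1].median()),
                               f"median_{g2}": float(sds_df[g2].median())}
    return sds_df, tests


@dataclass
class SpliceSiteAnnotation:
    """A mutation in the 2 canonical intronic bases flanking an exon."""

    mutation_key: tuple
    gene: str
    transcript: str
    side: str  # donor_5prime | acceptor_3prime (in transcription direction)
    exon_index: int  # genomic-order 0-based index of the adjacent exon
    offset: int  # 1 or 2 bases into the intron


def annotate_splice_site(mutation: PairedMutationRecord,
                         models: Sequence[GeneModel]) -> Optional[SpliceSiteAnnotation]:
    """Return the splice-site annotation for a mutation, or None.

    The position must fall within the 2 intronic bases adjacent to any exon
    boundary of a supplied transcript on the same chromosome. Side follows the
    transcription direction: on the plus strand the intron bases after an exon
    end form the donor (5') site; on the minus strand the same genomic
    geometry is the acceptor (3') site.
    """
    chrom = mutation.position.chromosome
    pos = mutation.position.position
    for model in models:
        if model.chromosome != chrom:
            continue
        n = model.n_exons
        for i, (s, e) in enumerate(model.exons):
            if i < n - 1 and e + 1 <= pos <= e + 2:  # intron right of exon i
                side = "donor_5prime" if model.strand == "+" else "acceptor_3prime"
                return SpliceSiteAnnotation(
                    mutation_key=mutation.key, gene=model.gene,
                    transcript=model.transcript, side=side, exon_index=i,
                    offset=pos - e)
            if i > 0 and s - 2 <= pos <= s - 1:  # intron left of exon i
                side = "acceptor_3prime" if model.strand == "+" else "donor_5prime"
                return SpliceSiteAnnotation(
                    mutation_key=mutation.key, gene=model.gene,
                    transcript=model.transcript, side=side, exon_index=i,
                    offset=s - pos)
    return None


@dataclass
class SkippingPolicy:
    min_carrier_ratio: float = 0.2
    max_noncarrier_ratio: float = 0.05
    min_carrier_depth: float = 10.0  # skip + mean(inclusion) in the carrier


@dataclass
class SkippingCall:
    exon_index: int
    carrier_samples: List[str]
    skip_ratios: Dict[str, float] = field(default_factory=dict)
    evaluable: bool = True
    flagged: bool = False
    reason: str = ""
    consequence: Optional[str] = None


def _junction_reads(junctions_by_sample: Dict[str, Dict[Tuple[int, int], int]],
                    sample: str, donor_end: int, acceptor_start: int) -> int:
    return junctions_by_sample.get(sample, {}).get((donor_end, acceptor_start), 0)


def index_junctions(junctions: Iterable[JunctionCount]):
    """Group junction counts as {sample: {(donor_end, acceptor_start): reads}}."""
    idx: Dict[str, Dict[Tuple[int, int], int]] = {}
    for j in junctions:
        idx.setdefault(j.sample, {})[(j.donor_end, j.acceptor_start)] = j.read_count
    return idx


def skip_ratio(skip_reads: int, inclusion_left: int, inclusion_right: int) -> Optional[float]:
    """skip / (skip + mean of the two inclusion junctions); None if depth 0."""
    denom = skip_reads + (inclusion_left + inclusion_right) / 2.0
    if denom == 0:
        return None
    return skip_reads / denom


def detect_exon_skipping(annotation: SpliceSiteAnnotation,
                         model: GeneModel,
                         junctions: Iterable[JunctionCount],
                         carrier_samples: Sequence[str],
                         policy: SkippingPolicy = SkippingPolicy()) -> SkippingCall:
    """Test whether the exon adjacent to a splice-site mutation is skipped
    specifically in the carrier sample(s).

    Flagged iff at least one carrier reaches skip_ratio >=
    policy.min_carrier_ratio at junction depth >= policy.min_carrier_depth,
    and the maximum non-carrier skip_ratio stays below
    policy.max_noncarrier_ratio (the most conservative baseline). The first
    and last exon have no skipping junction and are unevaluable.
    """
    k = annotation.exon_index
    call = SkippingCall(exon_index=k, carrier_samples=list(carrier_samples))
    if k == 0 or k == model.n_exons - 1:
        call.evaluable = False
        call.reason = "terminal exon: no skipping junction definable"
        return call
    left_end = model.exons[k - 1][1]
    own_start, own_end = model.exons[k]
    right_start = model.exons[k + 1][0]

    idx = index_junctions(junctions)
    carrier_ok = False
    carrier_depth_ok = False
    for sample, jmap in idx.items():
        skip = jmap.get((left_end, right_start), 0)
        inc_l = jmap.get((left_end, own_start), 0)
        inc_r = jmap.get((own_end, right_start), 0)
        ratio = skip_ratio(skip, inc_l, inc_r)
        if ratio is None:
            continue
        call.skip_ratios[sample] = ratio
        denom = skip + (inc_l + inc_r) / 2.0
        if sample in carrier_samples and denom >= policy.min_carrier_depth:
            carrier_depth_ok = True
            if ratio >= policy.min_carrier_ratio:
                carrier_ok = True
    noncarrier_ratios = [r for s, r in call.skip_ratios.items()
                         if s not in carrier_samples]
    if not carrier_depth_ok:
        call.evaluable = False
        call.reason = "insufficient junction depth in carrier"
        return call
    if not noncarrier_ratios:
        call.evaluable = False
        call.reason = "no non-carrier junction coverage"
        return call
    call.flagged = carrier_ok and max(noncarrier_ratios) < policy.max_noncarrier_ratio
    call.consequence = predict_truncation(model, k)
    return call


def predict_truncation(model: GeneModel, exon_index: int) -> str:
    """Consequence of skipping one exon: frame-preserving or truncating.

    A coding exon whose coding length is not a multiple of 3 shifts the
    downstream frame (frameshift/premature-stop); a multiple of 3 gives an
    in-frame deletion; an exon with no coding bases is non-coding.
    """
    coding = model.exon_coding_length(exon_index)
    if coding == 0:
        return "non-coding"
    if coding % 3 != 0:
        return "frameshift/premature-stop"
    return "in-frame-deletion"
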
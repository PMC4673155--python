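"""Copy-number states, LOH calls, and their co-occurrence with mutation classes.

A segment is a deletion (amplification) when its log2 tumor/normal ratio is
strictly below -0.5 (above +0.5); the boundary is neutral. LOH is called at a
SNP that is heterozygous in the matched normal (BAF in [0.3, 0.7]) whose
tumor BAF has moved at least 0.3 away from 0.5, with both samples covered at
>= 20x.

Co-occurrence asks, per mutation class, what fraction of mutations fall
inside deletion (resp. amplification) segments of the relevant tumor:
shared and metastasis-specific classes are scored against metastasis
segments, primary-specific mutations against primary segments. The LOH
density profile pools heterozygous SNPs within +-1 Mb of each mutation into
signed-distance bins and reports the per-bin LOH rate.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    CNASegment,
    ConfigurationError,
    PairedMutationRecord,
    SNPSite,
    ValidationError,
)

CLASS_SELECTORS = ("class1", "class2", "class3", "class1h_15", "class1h_30")

# tumor sample whose segments/SNPs a class is scored against
ROLE_FOR_CLASS = {"class1": "CLM", "class1h_15": "CLM", "class1h_30": "CLM",
                  "class2": "PT", "class3": "CLM"}


@dataclass
class CNAPolicy:
    log2_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.log2_threshold > 0:
            raise ValidationError("log2_threshold must be > 0")


@dataclass
class LOHPolicy:
    normal_het_low: float = 0.3
    normal_het_high: float = 0.7
    tumor_loh_distance: float = 0.3
    min_depth: int = 20


def call_cna(segment: CNASegment, policy: CNAPolicy = CNAPolicy()) -> str:
    """deletion / neutral / amplification; |log2| == threshold stays neutral."""
    r = segment.log2_ratio
    if math.isnan(r):
        raise ValidationError(
            f"NaN log2 ratio in segment {segment.chromosome}:{segment.start}-{segment.end}")
    if r < -policy.log2_threshold:
        return "deletion"
    if r > policy.log2_threshold:
        return "amplification"
    return "neutral"


def call_cna_states(segments: Iterable[CNASegment],
                    policy: CNAPolicy = CNAPolicy()) -> List[CNASegment]:
    out = list(segments)
    for seg in out:
        seg.state = call_cna(seg, policy)
    return out


def call_loh(snp: SNPSite, policy: LOHPolicy = LOHPolicy()) -> Optional[bool]:
    """True/False LOH call; None when either sample has zero depth (unevaluable)."""
    if snp.normal_depth == 0 or snp.tumor_depth == 0:
        return None
    if not (policy.normal_het_low <= snp.normal_baf <= policy.normal_het_high):
        return False
    if snp.normal_depth < policy.min_depth or snp.tumor_depth < policy.min_depth:
        return False
    return abs(snp.tumor_baf - 0.5) >= policy.tumor_loh_distance


def call_loh_states(snps: Iterable[SNPSite],
                    policy: LOHPolicy = LOHPolicy()) -> List[SNPSite]:
    out = list(snps)
    for snp in out:
        snp.loh = call_loh(snp, policy)
    return out


class _SegmentIndex:
    """Point lookup into non-overlapping segments keyed by (sample, chrom)."""

    def __init__(self, segments: Sequence[CNASegment]):
        self._by_key: Dict[Tuple[str, str], Tuple[list, list]] = {}
        grouped: Dict[Tuple[str, str], List[CNASegment]] = {}
        for seg in segments:
            grouped.setdefault((seg.sample, seg.chromosome), []).append(seg)
        for key, segs in grouped.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValidationError(
                        f"overlapping segments in {key[0]} {key[1]}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}")
            self._by_key[key] = ([s.start for s in segs], segs)

    def lookup(self, sample: str, chrom: str, pos: int) -> Optional[CNASegment]:
        entry = self._by_key.get((sample, chrom))
        if entry is None:
            return None
        starts, segs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and segs[i].end >= pos:
            return segs[i]
        return None


def _selector_members(records, selector):
    for rec in records:
        if selector in ("class1", "class2", "class3"):
            if rec.class_label == selector:
                yield rec
        elif selector == "class1h_15" and rec.class1h_15:
            yield rec
        elif selector == "class1h_30" and rec.class1h_30:
            yield rec


def cooccurrence_frequency(records: Iterable[PairedMutationRecord],
                           segments: Sequence[CNASegment],
                           selectors: Sequence[str] = CLASS_SELECTORS) -> pd.DataFrame:
    """Fraction of each class's mutations lying inside deletions/amplifications.

    Segments must carry called states and be non-overlapping per sample.
    A mutation on a chromosome with no segment is counted as non-overlapping.
    """
    for seg in segments:
        if seg.state is None:
            raise ValidationError("segments must have called CNA states; "
                                  "run call_cna_states first")
    index = _SegmentIndex(segments)
    records = list(records)
    rows = []
    for selector in selectors:
        role = ROLE_FOR_CLASS[selector]
        n = n_del = n_amp = 0
        for rec in _selector_members(records, selector):
            n += 1
            seg = index.lookup(f"{rec.patient_id}:{role}",
                               rec.position.chromosome, rec.position.position)
            if seg is not None:
                if seg.state == "deletion":
                    n_del += 1
                elif seg.state == "amplification":
                    n_amp += 1
        rows.append({
            "class": selector, "n": n,
            "n_deletion": n_del, "n_amplification": n_amp,
            "frac_deletion": n_del / n if n else float("nan"),
            "frac_amplification": n_amp / n if n else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class LOHDensityProfile:
    """Pooled LOH rate per signed-distance bin around a mutation set.

    ``bins`` has columns bin_left, bin_right (signed distance, half-open
    [left, right)), n_loh, n_het, rate (NaN where no informative SNP fell in
    the bin).
    """

    bins: pd.DataFrame
    window: int
    bin_width: int
    n_mutations: int


def loh_density_profile(mutations: Iterable[PairedMutationRecord],
                        snps: Sequence[SNPSite],
                        role: str = "CLM",
                        window: int = 1_000_000,
                        bin_width: int = 100_000) -> LOHDensityProfile:
    """LOH rate at heterozygous SNPs per distance bin within +-window of mutations.

    Distances are signed (SNP position minus mutation position); bins are
    half-open [left, right), so the window covers [-window, +window) and a
    SNP at exactly +window is excluded. SNPs must have LOH calls; unevaluable
    SNPs (loh is None) are skipped.
    """
    if window % bin_width != 0:
        raise ConfigurationError(
            f"window {window} is not a multiple of bin_width {bin_width}")
    n_bins = 2 * (window // bin_width)
    edges = np.arange(-window, window + bin_width, bin_width)
    n_loh = np.zeros(n_bins, dtype=int)
    n_het = np.zeros(n_bins, dtype=int)

    snps_by_key: Dict[Tuple[str, str], Tuple[list, list]] = {}
    grouped: Dict[Tuple[str, str], List[SNPSite]] = {}
    for snp in snps:
        grouped.setdefault((snp.sample, snp.position.chromosome), []).append(snp)
    for key, group in grouped.items():
        group.sort(key=lambda s: s.position.position)
        snps_by_key[key] = ([s.position.position for s in group], group)

    n_mut = 0
    for rec in mutations:
        n_mut += 1
        key = (f"{rec.patient_id}:{role}", rec.position.chromosome)
        entry = snps_by_key.get(key)
        if entry is None:
            continue
        positions, group = entry
        mpos = rec.position.position
        lo = bisect_right(positions, mpos - window - 1)
        for snp in group[lo:]:
            d = snp.position.position - mpos
            if d >= window:
                break
            if d < -window or snp.loh is None:
                continue
            b = (d + window) // bin_width
            n_het[b] += 1
            if snp.loh:
                n_loh[b] += 1

    bins = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "n_loh": n_loh, "n_het": n_het,
        "rate": np.where(n_het > 0, n_loh / np.maximum(n_het, 1), np.nan),
    })
    return LOHDensityProfile(bins=bins, window=window, bin_width=bin_width,
                             n_mutations=n_mut)


def central_enrichment_test(profile: LOHDensityProfile,
                            n_central: int = 4) -> dict:
    """One-sided test that the central bins' LOH rate exceeds the outer bins'.

    Pools counts over the n_central bins straddling distance zero versus all
    remaining bins and applies a one-sided two-proportion z-test.
    """
    n_bins = len(profile.bins)
    mid = n_bins // 2
    half = n_central // 2
    central = profile.bins.iloc[mid - half: mid + (n_central - half)]
    outer = profile.bins.drop(central.index)
    k_c, n_c = int(central["n_loh"].sum()), int(central["n_het"].sum())
    k_o, n_o = int(outer["n_loh"].sum()), int(outer["n_het"].sum())
    if n_c == 0 or n_o == 0:
        return {"rate_central": float("nan"), "rate_outer": float("nan"),
                "z": float("nan"), "p": float("nan")}
    p_c, p_o = k_c / n_c, k_o / n_o
    pooled = (k_c + k_o) / (n_c + n_o)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n_c + 1 / n_o))
    z = (p_c - p_o) / se if se > 0 else 0.0
    p = float(sps.norm.sf(z)) if se > 0 else (0.5 if p_c == p_o else float(p_c < p_o))
    return {"rate_central": p_c, "rate_outer": p_o, "z": z, "p": p}
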
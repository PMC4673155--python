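"""Base-substitution classes, Ts/Tv balance, and 96-trinucleotide spectra.

Substitutions are collapsed to the pyrimidine reference strand (G>A is
counted as C>T), giving 6 substitution classes and, with the two flanking
bases, the standard 96 trinucleotide categories written ``X[C>A]Y``.
Spectra are compared between primary tumors and metastases with per-class
two-proportion z-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

import pandas as pd

from .classify import DetectionPolicy
from .model import ContractError, PairedMutationRecord, ValidationError
from .stats import benjamini_hochberg, two_proportion_z

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = frozenset({"C>T", "T>C"})
BASES = "ACGT"

CONTEXT_96 = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5, f3 in product(BASES, BASES)
)


def _check_base(b: str, what: str) -> None:
    if b not in COMPLEMENT:
        raise ValidationError(f"{what} must be one of A/C/G/T, got {b!r}")


def classify_substitution(ref: str, alt: str) -> tuple:
    """Return (substitution class, 'transition'|'transversion').

    Purine references are collapsed by complementing both alleles, so the
    class is always written with a pyrimidine reference.
    """
    _check_base(ref, "ref")
    _check_base(alt, "alt")
    if ref == alt:
        raise ValidationError("ref and alt must differ")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    sub = f"{ref}>{alt}"
    return sub, ("transition" if sub in TRANSITIONS else "transversion")


def trinucleotide_context(flank5: str, ref: str, alt: str, flank3: str) -> str:
    """One of the 96 pyrimidine-strand trinucleotide categories, e.g. G[C>A]C.

    When the reference base is a purine the whole triplet (and the alt) is
    reverse-complemented before the category is formed.
    """
    for b, what in ((flank5, "flank5"), (ref, "ref"), (alt, "alt"), (flank3, "flank3")):
        _check_base(b, what)
    if ref == alt:
        raise ValidationError("ref and alt must differ")
    if ref in "AG":
        flank5, ref, alt, flank3 = (
            COMPLEMENT[flank3], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[flank5])
    return f"{flank5}[{ref}>{alt}]{flank3}"


@dataclass
class Spectrum:
    """Counts over substitution categories for one tumor group."""

    group: str
    mode: str  # "6-class", "96-context" or "tstv"
    counts: pd.Series
    n_excluded: int = 0  # indels / MNVs dropped

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> pd.Series:
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total


def spectrum(records: Iterable[PairedMutationRecord], group: str,
             mode: str = "6-class",
             policy: Optional[DetectionPolicy] = None) -> Spectrum:
    """Substitution spectrum of the mutations detected in one tumor group.

    ``group`` selects records whose PT (or CLM) exome observation passes the
    detection policy. Indels and multi-nucleotide variants are excluded and
    counted in ``n_excluded``. 96-context mode requires flanking bases on
    every SNV and errors otherwise: contexts are meaningless without true
    flanks.
    """
    if group not in ("PT", "CLM"):
        raise ContractError(f"group must be PT or CLM, got {group!r}")
    if mode not in ("6-class", "96-context", "tstv"):
        raise ContractError(f"unknown spectrum mode {mode!r}")
    policy = policy or DetectionPolicy()
    if mode == "6-class":
        index = list(SUBSTITUTION_CLASSES)
    elif mode == "96-context":
        index = list(CONTEXT_96)
    else:
        index = ["transition", "transversion"]
    counts = pd.Series(0, index=index, dtype=int)
    n_excluded = 0
    for rec in records:
        if not policy.detected(rec.obs(group, "exome")):
            continue
        if not rec.is_snv:
            n_excluded += 1
            continue
        if mode == "96-context":
            if rec.flank5 is None or rec.flank3 is None:
                raise ValidationError(
                    f"record {rec.key} lacks flanking bases; 96-context mode "
                    "requires flanks (supply flank columns or a reference FASTA)")
            cat = trinucleotide_context(rec.flank5, rec.ref_allele,
                                        rec.alt_allele, rec.flank3)
        else:
            sub, tstv = classify_substitution(rec.ref_allele, rec.alt_allele)
            cat = sub if mode == "6-class" else tstv
        counts[cat] += 1
    return Spectrum(group=group, mode=mode, counts=counts, n_excluded=n_excluded)


def collapse_96_to_6(spec: Spectrum) -> Spectrum:
    """Marginalize a 96-context spectrum over flanks into the 6-class spectrum."""
    if spec.mode != "96-context":
        raise ContractError("collapse_96_to_6 requires a 96-context spectrum")
    counts = pd.Series(0, index=list(SUBSTITUTION_CLASSES), dtype=int)
    for cat, k in spec.counts.items():
        counts[cat[2:5]] += int(k)
    return Spectrum(group=spec.group, mode="6-class", counts=counts,
                    n_excluded=spec.n_excluded)


def compare_spectra(spectrum_pt: Spectrum, spectrum_clm: Spectrum,
                    adjust: bool = False) -> pd.DataFrame:
    """Per-category PT-vs-CLM proportion differences with z-tests.

    Returns a DataFrame with proportions, delta (CLM - PT), z, p (optionally
    Benjamini-Hochberg adjusted), and a higher_in_clm flag (delta > 0 and
    p < 0.05).
    """
    if spectrum_pt.mode != spectrum_clm.mode:
        raise ContractError(
            f"spectrum modes differ: {spectrum_pt.mode} vs {spectrum_clm.mode}")
    n_pt, n_clm = spectrum_pt.n, spectrum_clm.n
    rows = []
    for cat in spectrum_pt.counts.index:
        k_pt = int(spectrum_pt.counts[cat])
        k_clm = int(spectrum_clm.counts[cat])
        res = two_proportion_z(k_pt, n_pt, k_clm, n_clm)
        rows.append({
            "category": cat,
            "count_pt": k_pt, "count_clm": k_clm,
            "prop_pt": k_pt / n_pt if n_pt else float("nan"),
            "prop_clm": k_clm / n_clm if n_clm else float("nan"),
            "delta": (k_clm / n_clm - k_pt / n_pt) if n_pt and n_clm else float("nan"),
            "z": res.value,
            "p": res.p_value if res.p_value is not None else float("nan"),
        })
    df = pd.DataFrame(rows)
    if adjust:
        df["p"] = benjamini_hochberg(df["p"].to_numpy())
    df["higher_in_clm"] = (df["delta"] > 0) & (df["p"] < 0.05)
    return df
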
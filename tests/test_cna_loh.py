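"""CNA state calls, LOH calls, co-occurrence, and LOH density profiles."""

import math

import numpy as np
import pytest

from ptclm.cna_loh import (
    CNAPolicy,
    LOHPolicy,
    call_cna,
    call_cna_states,
    call_loh,
    call_loh_states,
    central_enrichment_test,
    cooccurrence_frequency,
    loh_density_profile,
)
from ptclm.classify import assign_classes
from ptclm.model import (
    CNASegment,
    ConfigurationError,
    GenomicPosition,
    SNPSite,
    ValidationError,
)

from conftest import build_record


class TestCallCNA:
    @pytest.mark.parametrize("log2, state", [
        (-0.8, "deletion"),
        (-0.5, "neutral"),    # "more than +-0.5" is strict
        (0.5, "neutral"),
        (0.6, "amplification"),
        (0.0, "neutral"),
    ])
    def test_threshold_rule(self, log2, state):
        seg = CNASegment("chr1", 1, 100, log2)
        assert call_cna(seg) == state

    def test_nan_ratio_rejected(self):
        with pytest.raises(ValidationError):
            call_cna(CNASegment("chr1", 1, 100, float("nan")))

    def test_states_partition_the_line(self):
        for log2 in np.linspace(-2, 2, 41):
            assert call_cna(CNASegment("chr1", 1, 2, float(log2))) in (
                "deletion", "neutral", "amplification")


class TestCallLOH:
    def _snp(self, normal_baf, tumor_baf, nd=50, td=60):
        return SNPSite("P1:CLM", GenomicPosition("chr1", 100), normal_baf,
                       tumor_baf, nd, td)

    def test_clear_loh(self):
        assert call_loh(self._snp(0.50, 0.92)) is True

    def test_balanced_tumor_not_loh(self):
        assert call_loh(self._snp(0.50, 0.55)) is False

    def test_non_het_normal_uninformative(self):
        assert call_loh(self._snp(0.10, 0.95)) is False

    def test_depth_floor(self):
        assert call_loh(self._snp(0.50, 0.92, nd=10)) is False

    def test_zero_depth_unevaluable(self):
        assert call_loh(self._snp(0.0, 0.92, nd=0)) is None

    def test_boundary_distance_inclusive(self):
        assert call_loh(self._snp(0.50, 0.80)) is True


def _classed(patient, pos, label, chrom="chr1", h15=False):
    rec = build_record(patient=patient, chrom=chrom, pos=pos,
                       pt_exome=(70, 30), clm_exome=(65, 35))
    rec.class_label = label
    rec.class1h_15 = h15
    rec.class1h_30 = False
    return rec


class TestCooccurrence:
    def test_half_inside_deletion(self):
        recs = [_classed("P1", 500, "class1"), _classed("P1", 5000, "class1")]
        segs = call_cna_states([CNASegment("chr1", 100, 1000, -0.9, "P1:CLM")])
        table = cooccurrence_frequency(recs, segs).set_index("class")
        assert table.loc["class1", "frac_deletion"] == pytest.approx(0.5)
        assert table.loc["class1", "n"] == 2

    def test_no_segments_all_zero(self):
        recs = [_classed("P1", 500, "class1"), _classed("P1", 600, "class2")]
        table = cooccurrence_frequency(recs, [])
        assert (table["frac_deletion"].dropna() == 0).all()

    def test_class2_scored_against_pt_segments(self):
        recs = [_classed("P1", 500, "class2")]
        clm_only = call_cna_states([CNASegment("chr1", 100, 1000, -0.9, "P1:CLM")])
        table = cooccurrence_frequency(recs, clm_only).set_index("class")
        assert table.loc["class2", "frac_deletion"] == 0.0
        pt_seg = call_cna_states([CNASegment("chr1", 100, 1000, -0.9, "P1:PT")])
        table = cooccurrence_frequency(recs, pt_seg).set_index("class")
        assert table.loc["class2", "frac_deletion"] == 1.0

    def test_overlapping_segments_rejected(self):
        recs = [_classed("P1", 500, "class1")]
        segs = call_cna_states([
            CNASegment("chr1", 100, 1000, -0.9, "P1:CLM"),
            CNASegment("chr1", 900, 2000, 0.9, "P1:CLM")])
        with pytest.raises(ValidationError, match="overlap"):
            cooccurrence_frequency(recs, segs)

    def test_uncalled_segments_rejected(self):
        recs = [_classed("P1", 500, "class1")]
        with pytest.raises(ValidationError, match="state"):
            cooccurrence_frequency(recs, [CNASegment("chr1", 1, 10, -0.9,
                                                     "P1:CLM")])

    def test_planted_rates_recovered(self, default_cohort):
        """Deletion-superposition rates recovered per planting group."""
        truth = default_cohort.truth.mutations
        records = list(default_cohort.records)
        for rec, group in zip(records, truth["group"]):
            rec.class_label = {"class1h": "class1"}.get(group, group) \
                if group in ("class1", "class1h", "class2", "class3") else None
            rec.class1h_15 = group == "class1h"
            rec.class1h_30 = False
        segs = call_cna_states(default_cohort.segments)
        usable = [r for r in records if r.class_label is not None]
        table = cooccurrence_frequency(usable, segs).set_index("class")
        rates = default_cohort.truth.params.deletion_rates
        for selector, key in (("class1h_15", "class1h"), ("class2", "class2"),
                              ("class3", "class3")):
            n = table.loc[selector, "n"]
            planted = rates[key]
            se = math.sqrt(planted * (1 - planted) / n)
            assert abs(table.loc[selector, "frac_deletion"] - planted) < 3 * se
        # paper-style ordering: class1h > class1 (pooled) > class2
        assert (table.loc["class1h_15", "frac_deletion"]
                > table.loc["class1", "frac_deletion"]
                > table.loc["class2", "frac_deletion"])


class TestLOHDensity:
    def _snp_at(self, pos, loh, sample="P1:CLM", chrom="chr1"):
        snp = SNPSite(sample, GenomicPosition(chrom, pos), 0.5,
                      0.95 if loh else 0.5, 50, 50)
        snp.loh = loh
        return snp

    def test_bin_assignment(self):
        mut = _classed("P1", 10_000_000, "class1")
        profile = loh_density_profile([mut],
                                      [self._snp_at(10_050_000, True)])
        bins = profile.bins.set_index("bin_left")
        assert bins.loc[0, "n_loh"] == 1
        assert bins.loc[0, "rate"] == pytest.approx(1.0)

    def test_outer_edge_half_open(self):
        mut = _classed("P1", 10_000_000, "class1")
        at_plus_1mb = self._snp_at(11_000_000, True)
        just_inside = self._snp_at(10_999_999, True)
        at_minus_1mb = self._snp_at(9_000_000, True)
        profile = loh_density_profile([mut], [at_plus_1mb, just_inside,
                                              at_minus_1mb])
        assert profile.bins["n_het"].sum() == 2  # +1 Mb excluded

    def test_window_must_tile(self):
        with pytest.raises(ConfigurationError):
            loh_density_profile([], [], window=1_000_000, bin_width=300_000)

    def test_unevaluable_snps_skipped(self):
        mut = _classed("P1", 10_000_000, "class1")
        snp = self._snp_at(10_050_000, True)
        snp.loh = None
        profile = loh_density_profile([mut], [snp])
        assert profile.bins["n_het"].sum() == 0

    def test_uniform_loh_profile_is_flat(self):
        """Under spatially uniform LOH no bin leaves 3 SE of the global rate."""
        from ptclm.simulate import SimulationParams, simulate_cohort

        cohort = simulate_cohort(SimulationParams(
            seed=12, background_loh_rate=0.1,
            deletion_rates={"class1": 0.0, "class2": 0.0, "class3": 0.0,
                            "class1h": 0.0}))
        snps = call_loh_states(cohort.snp_sites)
        records = assign_classes(cohort.records)
        profile = loh_density_profile(records, snps)
        bins = profile.bins.dropna(subset=["rate"])
        global_rate = bins["n_loh"].sum() / bins["n_het"].sum()
        se = np.sqrt(global_rate * (1 - global_rate) / bins["n_het"])
        assert (np.abs(bins["rate"] - global_rate) <= 3 * se).all()

    def test_planted_enrichment_detected(self, default_cohort):
        """Deletions around class1-H loci produce a central LOH peak."""
        truth = default_cohort.truth.mutations
        class1h = [r for r, g in zip(default_cohort.records, truth["group"])
                   if g == "class1h"]
        snps = call_loh_states(default_cohort.snp_sites)
        profile = loh_density_profile(class1h, snps)
        res = central_enrichment_test(profile)
        assert res["rate_central"] > res["rate_outer"]
        assert res["p"] < 0.05
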
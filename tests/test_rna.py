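"""Exome-RNA integration: rescue, intersection, selections, couplings."""

import numpy as np
import pandas as pd
import pytest

from ptclm.model import ContractError, ExpressionMatrix, ValidationError
from ptclm.rna import (
    P53_PROGRAM,
    RescuePolicy,
    TargetGeneSet,
    bin_ma_scores_by_vaf,
    intersect_exome_rna,
    rescue_rejected,
    select_candidate_clm,
    select_rna_enriched,
    vaf_expression_correlation,
)

from conftest import build_record


class TestRescue:
    def test_reject_with_rna_support_is_rescued(self):
        rec = build_record(pt_exome=(90, 10, "reject"), pt_rna=(6, 6, "keep"))
        assert rescue_rejected([rec]).rescued == [rec]

    def test_ten_x_coverage_is_not_enough(self):
        # "more than 10x" is strict: depth 10 fails, depth 11 passes
        at10 = build_record(pt_exome=(90, 10, "reject"), pt_rna=(5, 5, "keep"))
        at11 = build_record(pt_exome=(90, 10, "reject"), pt_rna=(6, 5, "keep"))
        res = rescue_rejected([at10, at11])
        assert res.rescued == [at11]

    def test_kept_exome_calls_not_rescued(self):
        rec = build_record(pt_exome=(70, 30, "keep"), pt_rna=(25, 25, "keep"))
        assert rescue_rejected([rec]).rescued == []

    def test_rna_reject_not_rescued(self):
        rec = build_record(pt_exome=(90, 10, "reject"), pt_rna=(20, 20, "reject"))
        assert rescue_rejected([rec]).rescued == []

    def test_missing_rna_skipped_and_counted(self):
        rec = build_record(pt_exome=(90, 10, "reject"))
        res = rescue_rejected([rec])
        assert res.rescued == [] and res.n_missing_rna == 1

    def test_subset_and_idempotent(self, default_cohort):
        records = default_cohort.records
        first = rescue_rejected(records)
        again = rescue_rejected(first.rescued)
        assert set(id(r) for r in again.rescued) == \
               set(id(r) for r in first.rescued)

    def test_policy_threshold_parameter(self):
        rec = build_record(pt_exome=(90, 10, "reject"), pt_rna=(3, 3, "keep"))
        assert rescue_rejected([rec], RescuePolicy(min_rna_depth=5)).rescued == [rec]

    def test_planted_rescues_recovered_exactly(self):
        """All planted reject-but-expressed records, and only those, revive."""
        from ptclm.simulate import SimulationParams, simulate_cohort

        cohort = simulate_cohort(SimulationParams(seed=6, snps_per_mutation=0))
        truth = cohort.truth.mutations
        planted = {(p, c, int(x)) for p, c, x in zip(
            truth.loc[truth["rescued"], "patient"],
            truth.loc[truth["rescued"], "chrom"],
            truth.loc[truth["rescued"], "pos"])}
        got = {(r.patient_id, r.position.chromosome, r.position.position)
               for r in rescue_rejected(cohort.records).rescued}
        assert got == planted


class TestIntersection:
    def test_three_way_enumeration(self):
        both = build_record(pos=1, pt_exome=(70, 30), pt_rna=(60, 40))
        exome_only = build_record(pos=2, pt_exome=(70, 30), pt_rna=(100, 0))
        rna_only = build_record(pos=3, pt_exome=(100, 0), pt_rna=(60, 40))
        res = intersect_exome_rna([both, exome_only, rna_only],
                                  sample_role="PT")
        assert (res.n_common, res.n_exome_only, res.n_rna_only) == (1, 1, 1)
        assert res.frac_common_of_exome == pytest.approx(0.5)
        assert res.frac_common_of_rna == pytest.approx(0.5)

    def test_counts_partition_detected_sets(self, default_cohort):
        res = intersect_exome_rna(default_cohort.records, sample_role="CLM")
        from ptclm.classify import DetectionPolicy

        policy = DetectionPolicy()
        n_exome = sum(policy.detected(r.obs("CLM", "exome"))
                      for r in default_cohort.records)
        n_rna = sum(policy.detected(r.obs("CLM", "rna"))
                    for r in default_cohort.records)
        assert res.n_common + res.n_exome_only == n_exome
        assert res.n_common + res.n_rna_only == n_rna

    def test_exome_only_low_expression_recovery(self):
        """Exome-only sites planted in sub-1-RPKM genes are annotated as such."""
        from ptclm.simulate import SimulationParams, simulate_cohort

        cohort = simulate_cohort(SimulationParams(
            seed=9, snps_per_mutation=0, rescue_fraction=0,
            decoy_reject_fraction=0, rna_only_fraction=0))
        res = intersect_exome_rna(cohort.records, sample_role="PT",
                                  expression=cohort.expression)
        assert res.frac_exome_only_low_expression >= 0.95


class TestSelections:
    def test_rna_enriched_requires_both_roles(self):
        both = build_record(pos=1, pt_exome=(70, 30), pt_rna=(50, 50),
                            clm_exome=(60, 40), clm_rna=(40, 60))
        pt_only = build_record(pos=2, pt_exome=(70, 30), pt_rna=(50, 50),
                               clm_exome=(60, 40), clm_rna=(50, 50))
        selected, _ = select_rna_enriched([both, pt_only])
        assert selected == [both]

    def test_rna_enriched_boundary_inclusive(self):
        # deltas exactly 0.15 in both roles (0.25 -> 0.40)
        rec = build_record(pt_exome=(75, 25), pt_rna=(60, 40),
                           clm_exome=(75, 25), clm_rna=(60, 40))
        selected, _ = select_rna_enriched([rec])
        assert selected == [rec]

    def test_rna_enriched_excludes_undefined_vaf(self):
        rec = build_record(pt_exome=(70, 30), pt_rna=(0, 0),
                           clm_exome=(60, 40), clm_rna=(40, 60))
        selected, n_excluded = select_rna_enriched([rec])
        assert selected == [] and n_excluded == 1

    def test_candidate_clm_rules(self):
        selected_one = build_record(
            pos=1, pt_exome=(70, 30), pt_rna=(70, 30),
            clm_exome=(55, 45), clm_rna=(35, 65))  # 0.65 rna, delta 0.20 CLM
        below_floor = build_record(
            pos=2, pt_exome=(80, 20), pt_rna=(50, 50),
            clm_exome=(75, 25), clm_rna=(45, 55))  # 0.55 rna despite deltas
        or_over_roles = build_record(
            pos=3, pt_exome=(80, 20), pt_rna=(62, 38),  # PT delta 0.18
            clm_exome=(43, 57), clm_rna=(38, 62))       # CLM 0.62, delta 0.05
        selected, _ = select_candidate_clm(
            [selected_one, below_floor, or_over_roles])
        assert selected == [selected_one, or_over_roles]

    def test_candidate_clm_respects_vaf_floor_exactly(self, default_cohort):
        selected, _ = select_candidate_clm(default_cohort.records)
        assert all(r.vaf("CLM", "rna") >= 0.60 for r in selected)


class TestMABinning:
    def test_two_records_two_bins(self):
        low = build_record(pos=1, ma_score=1.0, clm_rna=(95, 5))
        high = build_record(pos=2, ma_score=3.0, clm_rna=(5, 95))
        table, trend = bin_ma_scores_by_vaf([low, high])
        assert table.loc[0, "n"] == 1 and table.loc[0, "mean_ma_score"] == 1.0
        assert table.loc[9, "n"] == 1 and table.loc[9, "mean_ma_score"] == 3.0
        assert not trend["defined"]  # two populated bins only

    def test_single_bin_trend_undefined(self):
        recs = [build_record(pos=i, ma_score=2.0, clm_rna=(50, 50))
                for i in range(1, 4)]
        _, trend = bin_ma_scores_by_vaf(recs)
        assert not trend["defined"]

    def test_coupled_scores_give_positive_trend(self, default_cohort):
        """MA scores drawn as 1 + 2*(true CLM RNA VAF) yield a rising trend."""
        _, trend = bin_ma_scores_by_vaf(default_cohort.records)
        assert trend["defined"] and trend["rho"] > 0


class TestVafExpressionCoupling:
    def _matrix(self, per_patient):
        cols = {f"{p}:CLM": [v] * len(P53_PROGRAM.members)
                for p, v in per_patient.items()}
        rpkm = np.power(2.0, pd.DataFrame(cols, index=P53_PROGRAM.members)) - 1
        return ExpressionMatrix(rpkm.clip(lower=0))

    def _records(self, vafs):
        return [build_record(patient=p, gene="TP53",
                             clm_rna=(int(100 - 100 * v), int(100 * v)))
                for p, v in vafs.items()]

    def test_perfect_line(self):
        records = self._records({"P1": 0.2, "P2": 0.5, "P3": 0.8})
        matrix = self._matrix({"P1": 3.0, "P2": 2.0, "P3": 1.0})
        table, res, sign_ok = vaf_expression_correlation(records, matrix,
                                                         P53_PROGRAM)
        assert res.value == pytest.approx(-1.0)
        assert res.extra["slope"] == pytest.approx(-10 / 3, rel=1e-9)
        assert sign_ok

    def test_constant_expression_flagged(self):
        records = self._records({"P1": 0.2, "P2": 0.5, "P3": 0.8})
        matrix = self._matrix({"P1": 2.0, "P2": 2.0, "P3": 2.0})
        _, res, sign_ok = vaf_expression_correlation(records, matrix,
                                                     P53_PROGRAM)
        assert res.extra["degenerate"] and sign_ok is None

    def test_missing_target_genes_error(self):
        records = self._records({"P1": 0.2, "P2": 0.5, "P3": 0.8})
        matrix = ExpressionMatrix(pd.DataFrame(
            [[1.0, 1.0, 1.0]], index=["OTHER"],
            columns=["P1:CLM", "P2:CLM", "P3:CLM"]))
        with pytest.raises(ValidationError, match="BBC3"):
            vaf_expression_correlation(records, matrix, P53_PROGRAM)

    def test_too_few_patients_contract(self):
        records = self._records({"P1": 0.2, "P2": 0.5})
        matrix = self._matrix({"P1": 3.0, "P2": 2.0})
        with pytest.raises(ContractError):
            vaf_expression_correlation(records, matrix, P53_PROGRAM)

    def test_rna_coupling_stronger_than_exome(self, default_cohort):
        """ASE decouples exome VAF from expression: RNA |r| should dominate."""
        _, res_rna, sign_ok = vaf_expression_correlation(
            default_cohort.records, default_cohort.expression, P53_PROGRAM,
            assay="rna")
        _, res_ex, _ = vaf_expression_correlation(
            default_cohort.records, default_cohort.expression, P53_PROGRAM,
            assay="exome")
        assert sign_ok and res_rna.value < 0
        assert abs(res_rna.value) > abs(res_ex.value)

    def test_direction_validation(self):
        with pytest.raises(ValidationError):
            TargetGeneSet("X", "sideways", ["A"])
        with pytest.raises(ValidationError):
            TargetGeneSet("X", "negative", [])
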
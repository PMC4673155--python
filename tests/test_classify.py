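"""Class taxonomy: assignment rules, Class 1-H flags, fractions, associations."""

import numpy as np
import pytest

from ptclm.classify import (
    DetectionPolicy,
    assign_class,
    assign_classes,
    class_fractions,
    clinical_association,
    concordance_vs_clonality,
)
from ptclm.model import ClinicalRecord, ContractError, ValidationError
from ptclm.classify import flag_class1h

from conftest import build_record


class TestAssignClass:
    @pytest.mark.parametrize("pt, clm, expected", [
        ((70, 30), (65, 35), "class1"),     # detected in both
        ((70, 30), (100, 0), "class2"),     # PT only, CLM well covered
        ((100, 0), (80, 20), "class3"),     # CLM only, PT well covered
        ((70, 30), (5, 0), "unassessable"),  # absent sample too shallow
        ((0, 0), (0, 0), "unassessable"),
    ])
    def test_rules(self, pt, clm, expected):
        rec = build_record(pt_exome=pt, clm_exome=clm)
        assert assign_class(rec) == expected

    def test_detection_policy_boundaries(self):
        # 2 alt reads at depth 100 fails min_alt_reads=3
        rec = build_record(pt_exome=(98, 2), clm_exome=(70, 30))
        assert assign_class(rec) == "class3"
        # VAF floor: 4/100 = 0.04 < 0.05
        rec = build_record(pt_exome=(96, 4), clm_exome=(70, 30))
        assert assign_class(rec) == "class3"
        # depth floor: detected needs depth >= 10
        rec = build_record(pt_exome=(5, 4), clm_exome=(70, 30))
        assert assign_class(rec) == "unassessable"

    def test_missing_both_tumors_is_error(self):
        rec = build_record(normal_exome=(50, 0))
        with pytest.raises(ValidationError):
            assign_class(rec)

    def test_swapping_tumors_maps_class2_to_class3(self):
        rec = build_record(pt_exome=(70, 30), clm_exome=(100, 0))
        assert assign_class(rec) == "class2"
        swapped = build_record(pt_exome=(100, 0), clm_exome=(70, 30))
        assert assign_class(swapped) == "class3"


class TestClass1H:
    def _class1(self, pt, clm):
        rec = build_record(pt_exome=pt, clm_exome=clm)
        rec.class_label = "class1"
        return rec

    def test_fifteen_point_gain_true(self):
        assert flag_class1h(self._class1((80, 20), (60, 40)), 0.15)

    def test_below_threshold_false(self):
        # 0.34 - 0.20 = 13.99... points
        assert not flag_class1h(self._class1((80, 20), (66, 34)), 0.15)

    def test_boundary_inclusive(self):
        # 0.40 - 0.25 = exactly 15 points
        assert flag_class1h(self._class1((75, 25), (60, 40)), 0.15)

    def test_decreasing_vaf_false(self):
        assert not flag_class1h(self._class1((60, 40), (80, 20)), 0.15)

    def test_contract_on_non_class1(self):
        rec = build_record(pt_exome=(70, 30), clm_exome=(100, 0))
        rec.class_label = "class2"
        with pytest.raises(ContractError):
            flag_class1h(rec, 0.15)

    def test_class1h_implies_class1(self, default_cohort):
        records = assign_classes(default_cohort.records)
        for rec in records:
            if rec.class1h_15 or rec.class1h_30:
                assert rec.class_label == "class1"
            if rec.class1h_30:
                assert rec.class1h_15  # 30-point tier nests in the 15-point tier


class TestFractions:
    def test_per_patient_arithmetic(self):
        recs = ([build_record(pos=i, pt_exome=(70, 30), clm_exome=(65, 35))
                 for i in range(1, 5)]
                + [build_record(pos=5, pt_exome=(70, 30), clm_exome=(100, 0)),
                   build_record(pos=6, pt_exome=(100, 0), clm_exome=(70, 30))])
        summary = class_fractions(assign_classes(recs))
        row = summary.per_patient.iloc[0]
        assert row["frac_class1"] == pytest.approx(4 / 6)
        assert row["frac_class2"] == pytest.approx(1 / 6)
        assert row["frac_class3"] == pytest.approx(1 / 6)

    def test_empty_input_gives_empty_summary(self):
        summary = class_fractions([])
        assert summary.totals["frac_class1"] is None
        assert summary.per_patient.empty

    def test_all_unassessable_flagged(self):
        recs = assign_classes([build_record(pos=i, pt_exome=(3, 2),
                                            clm_exome=(3, 1))
                               for i in range(1, 4)])
        summary = class_fractions(recs)
        assert summary.totals["n_unassessable"] == 3
        assert summary.totals["frac_class1"] is None

    def test_cohort_mix_recovery(self, default_cohort):
        """Assigned cohort fractions recover the simulated class mix."""
        records = assign_classes(default_cohort.records)
        truth = default_cohort.truth.mutations
        bulk = truth["group"].isin(["class1", "class1h", "class2", "class3"])
        summary = class_fractions([r for r, b in zip(records, bulk) if b])
        n = summary.totals["n_assessable"]
        for frac, expected in zip(("class1", "class2", "class3"),
                                  default_cohort.truth.params.class_mix):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(summary.totals[f"frac_{frac}"] - expected) < 3 * se


class TestAssociations:
    def _clin(self, patients, lvi):
        return [ClinicalRecord(p, lvi=l, t_stage="T3", msi_status="MSS",
                               clonality_pt=3, clonality_clm=3)
                for p, l in zip(patients, lvi)]

    def test_counts_and_chi2(self):
        # 30/100 class1 and 10/100 class2 mutations in LVI-positive patients
        recs = []
        for i in range(100):
            recs.append(build_record(patient="Ppos" if i < 30 else "Pneg",
                                     pos=i + 1, pt_exome=(70, 30),
                                     clm_exome=(65, 35)))
        for i in range(100):
            recs.append(build_record(patient="Ppos" if i < 10 else "Pneg",
                                     pos=i + 1000, pt_exome=(70, 30),
                                     clm_exome=(100, 0)))
        recs = assign_classes(recs)
        clin = self._clin(["Ppos", "Pneg"], [True, False])
        counts, res = clinical_association(recs, clin, attribute="lvi")
        assert counts == [[30, 70], [10, 90]]
        assert res.value == pytest.approx(12.5, abs=1e-9)
        assert res.p_value < 0.001

    def test_empty_class_is_error(self):
        recs = assign_classes([build_record(pt_exome=(70, 30),
                                            clm_exome=(65, 35))])
        clin = self._clin(["P1"], [True])
        with pytest.raises(ContractError):
            clinical_association(recs, clin)

    def test_planted_lvi_enrichment_detected(self):
        """Class1 planted more often in LVI patients shows up as association."""
        from ptclm.simulate import SimulationParams, simulate_cohort

        cohort = simulate_cohort(SimulationParams(
            seed=5, lvi_class1_multiplier=2.0, snps_per_mutation=0))
        records = assign_classes(cohort.records)
        _, res = clinical_association(records, cohort.clinical, attribute="lvi")
        assert res.p_value < 0.05


class TestConcordanceVsClonality:
    def test_perfect_line_recovered(self):
        recs = []
        clin = []
        rng = np.random.default_rng(0)
        for i, dc in enumerate([-2, -1, 0, 1, 2]):
            pid = f"P{i}"
            frac1 = 0.6 - 0.1 * dc
            n1 = int(round(frac1 * 100))
            for j in range(100):
                if j < n1:
                    recs.append(build_record(patient=pid, pos=j + 1,
                                             pt_exome=(70, 30),
                                             clm_exome=(65, 35)))
                else:
                    recs.append(build_record(patient=pid, pos=j + 1,
                                             pt_exome=(70, 30),
                                             clm_exome=(100, 0)))
            clin.append(ClinicalRecord(pid, lvi=False, t_stage="T3",
                                       msi_status="MSS", clonality_pt=3,
                                       clonality_clm=3 + dc))
        summary = class_fractions(assign_classes(recs))
        res = concordance_vs_clonality(summary, clin, which="class1")
        assert res.value == pytest.approx(-1.0)
        assert res.extra["slope"] == pytest.approx(-0.1, abs=1e-9)

    def test_coupled_simulation_recovers_slope(self):
        from ptclm.simulate import SimulationParams, simulate_cohort

        cohort = simulate_cohort(SimulationParams(
            seed=3, clonality_coupling=(0.6, -0.1, 0.05), snps_per_mutation=0))
        summary = class_fractions(assign_classes(cohort.records))
        res = concordance_vs_clonality(summary, cohort.clinical, which="class1")
        # generating slope -0.1 recovered well within sampling noise
        assert res.extra["slope"] == pytest.approx(-0.1, abs=0.05)
        assert res.value < 0 and res.p_value < 0.05

    def test_zero_variance_error(self):
        recs = assign_classes([
            build_record(patient=f"P{i}", pos=i + 1, pt_exome=(70, 30),
                         clm_exome=(65, 35)) for i in range(3)])
        clin = self._flat_clin()
        with pytest.raises(ContractError):
            concordance_vs_clonality(class_fractions(recs), clin)

    @staticmethod
    def _flat_clin():
        return [ClinicalRecord(f"P{i}", lvi=False, t_stage="T3",
                               msi_status="MSS", clonality_pt=3,
                               clonality_clm=4) for i in range(3)]
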
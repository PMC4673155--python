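import pytest

from ptclm.model import GenomicPosition, MutationObservation, PairedMutationRecord


def build_record(patient="P1", chrom="chr1", pos=1000, ref="C", alt="T",
                 gene="", ma_score=None, flank5="A", flank3="G", **slots):
    """Assemble a PairedMutationRecord from keyword observation slots.

    Slots are named like pt_exome=(ref_reads, alt_reads[, verdict]); roles are
    pt/clm/normal, assays exome/rna.
    """
    role_map = {"pt": "PT", "clm": "CLM", "normal": "normal"}
    obs = {}
    for key, spec in slots.items():
        role_key, _, assay = key.partition("_")
        role = role_map[role_key]
        ref_reads, alt_reads = spec[0], spec[1]
        verdict = spec[2] if len(spec) > 2 else ("keep" if alt_reads else "absent")
        obs[(role, assay)] = MutationObservation(role, assay, ref_reads,
                                                 alt_reads, verdict)
    return PairedMutationRecord(
        patient_id=patient, position=GenomicPosition(chrom, pos),
        ref_allele=ref, alt_allele=alt, gene=gene, ma_score=ma_score,
        flank5=flank5, flank3=flank3, observations=obs)


@pytest.fixture
def record_builder():
    return build_record


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    from ptclm.simulate import SimulationParams, simulate_cohort

    return simulate_cohort(SimulationParams(seed=11))
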
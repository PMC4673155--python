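"""End-to-end pipeline: run every analysis stage on a cohort and assemble a report.

A configuration either names input files (see :mod:`ptclm.io` for layouts) or
carries a ``simulation`` block, in which case the synthetic cohort generator
supplies all inputs. The report is a pure function of (inputs, config, seed):
running the same configuration twice yields byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as pio
from .classify import (
    DetectionPolicy,
    assign_classes,
    class_fractions,
    clinical_association,
    concordance_vs_clonality,
)
from .cna_loh import (
    CNAPolicy,
    LOHPolicy,
    call_cna_states,
    call_loh_states,
    central_enrichment_test,
    cooccurrence_frequency,
    loh_density_profile,
)
from .model import ConfigurationError, ContractError, ValidationError
from .rna import (
    P53_PROGRAM,
    WNT_PROGRAM,
    RescuePolicy,
    bin_ma_scores_by_vaf,
    intersect_exome_rna,
    rescue_rejected,
    select_candidate_clm,
    select_rna_enriched,
    vaf_expression_correlation,
)
from .simulate import SimulationParams, simulate_cohort
from .spectra import compare_spectra, spectrum
from .splicing import (
    SkippingPolicy,
    annotate_splice_site,
    detect_exon_skipping,
    expression_sd_distribution,
)

ALL_STAGES = ("classes", "spectra", "cna_loh", "integration", "splicing",
              "expression")
SUMMARY_SCHEMA_VERSION = 1


@dataclass
class CohortInputs:
    records: list
    segments: list = field(default_factory=list)
    snp_sites: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    gene_models: list = field(default_factory=list)
    expression: object = None
    clinical: list = field(default_factory=list)


@dataclass
class CohortReport:
    summary: dict
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(_jsonable(self.summary), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _load_inputs(config: dict) -> CohortInputs:
    if "simulation" in config:
        sim_kwargs = dict(config["simulation"] or {})
        if "seed" in config:
            sim_kwargs["seed"] = config["seed"]
        known = {f.name for f in fields(SimulationParams)}
        unknown = set(sim_kwargs) - known
        if unknown:
            raise ConfigurationError(
                f"unknown simulation parameter(s): {', '.join(sorted(unknown))}")
        cohort = simulate_cohort(SimulationParams(**sim_kwargs))
        return CohortInputs(records=cohort.records, segments=cohort.segments,
                            snp_sites=cohort.snp_sites,
                            junctions=cohort.junctions,
                            gene_models=cohort.gene_models,
                            expression=cohort.expression,
                            clinical=cohort.clinical)
    paths = config.get("inputs")
    if not paths or "mutations" not in paths:
        raise ConfigurationError(
            "config needs either a 'simulation' block or an 'inputs' block "
            "with at least a 'mutations' path")
    dialect = "vcf" if str(paths["mutations"]).endswith(".vcf") else "tsv"
    inputs = CohortInputs(records=pio.read_mutation_table(paths["mutations"],
                                                          dialect=dialect))
    if "segments" in paths:
        inputs.segments = pio.read_segments(paths["segments"])
    if "snp_sites" in paths:
        inputs.snp_sites = pio.read_snp_sites(paths["snp_sites"])
    if "junctions" in paths:
        inputs.junctions = pio.read_junctions(paths["junctions"])
    if "gene_models" in paths:
        inputs.gene_models = pio.read_gene_models(paths["gene_models"])
    if "expression" in paths:
        inputs.expression = pio.read_expression(paths["expression"])
    if "clinical" in paths:
        inputs.clinical = pio.read_clinical(paths["clinical"])
    return inputs


def _check_stage_dependencies(stages, inputs: CohortInputs) -> None:
    need = {
        "cna_loh": [("segments", inputs.segments)],
        "splicing": [("junctions", inputs.junctions),
                     ("gene_models", inputs.gene_models)],
        "expression": [("expression", inputs.expression)],
    }
    for stage in stages:
        for name, value in need.get(stage, []):
            present = value is not None and (
                not isinstance(value, list) or len(value) > 0)
            if not present:
                raise ConfigurationError(
                    f"stage {stage!r} requires input {name!r}, which is missing")


def run_pipeline(config: dict) -> CohortReport:
    """Run the configured stages and return the assembled report.

    ``config`` keys: ``simulation`` or ``inputs``; optional ``stages``
    (default: all), ``seed`` (overrides the simulation seed), ``out_dir``
    (write tables + summary.json there), and ``policies`` overriding
    detection/rescue/cna/loh/skipping thresholds.
    """
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {', '.join(sorted(unknown))}")
    inputs = _load_inputs(config)
    _check_stage_dependencies(stages, inputs)

    pol = config.get("policies", {})
    detection = DetectionPolicy(**pol.get("detection", {}))
    rescue_policy = RescuePolicy(**pol.get("rescue", {}))
    cna_policy = CNAPolicy(**pol.get("cna", {}))
    loh_policy = LOHPolicy(**pol.get("loh", {}))
    skip_policy = SkippingPolicy(**pol.get("skipping", {}))

    records = assign_classes(inputs.records, detection)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "n_records": len(records),
                     "stages": list(stages)}
    tables: Dict[str, pd.DataFrame] = {}

    if "classes" in stages:
        summary["classes"] = _stage_classes(records, inputs, tables)
    if "spectra" in stages:
        summary["spectra"] = _stage_spectra(records, detection, tables)
    if "cna_loh" in stages:
        summary["cna_loh"] = _stage_cna_loh(records, inputs, cna_policy,
                                            loh_policy, tables)
    if "integration" in stages:
        summary["integration"] = _stage_integration(records, inputs, detection,
                                                    rescue_policy, tables)
    if "splicing" in stages:
        summary["splicing"] = _stage_splicing(records, inputs, detection,
                                              skip_policy, tables)
    if "expression" in stages:
        summary["expression"] = _stage_expression(inputs, tables)

    report = CohortReport(summary=summary, tables=tables)
    if config.get("out_dir"):
        report.write(config["out_dir"])
    return report


def _stage_classes(records, inputs, tables) -> dict:
    summary = class_fractions(records)
    tables["classes_per_patient"] = summary.per_patient
    rows = []
    for rec in records:
        rows.append({"patient": rec.patient_id,
                     "chrom": rec.position.chromosome,
                     "pos": rec.position.position,
                     "ref": rec.ref_allele, "alt": rec.alt_allele,
                     "gene": rec.gene, "class_label": rec.class_label,
                     "class1h_15": rec.class1h_15, "class1h_30": rec.class1h_30})
    tables["classes"] = pd.DataFrame(rows)
    out = dict(summary.totals)
    if inputs.clinical:
        for attribute in ("lvi", "advanced_t"):
            try:
                counts, res = clinical_association(records, inputs.clinical,
                                                   attribute=attribute)
                out[f"association_{attribute}"] = {
                    "counts": counts, "chi2": res.value, "p": res.p_value}
            except (ContractError, ValidationError) as exc:
                out[f"association_{attribute}"] = {"error": str(exc)}
        for which in ("class1", "class3"):
            try:
                res = concordance_vs_clonality(summary, inputs.clinical,
                                               which=which)
                out[f"clonality_vs_{which}"] = res.as_dict()
            except (ContractError, ValidationError) as exc:
                out[f"clonality_vs_{which}"] = {"error": str(exc)}
    return out


def _stage_spectra(records, detection, tables) -> dict:
    out = {}
    have_flanks = all(r.flank5 is not None and r.flank3 is not None
                      for r in records if r.is_snv)
    modes = ["6-class", "tstv"] + (["96-context"] if have_flanks else [])
    for mode in modes:
        sp_pt = spectrum(records, "PT", mode, detection)
        sp_clm = spectrum(records, "CLM", mode, detection)
        comp = compare_spectra(sp_pt, sp_clm)
        key = mode.replace("-", "_")
        tables[f"spectra_{key}"] = comp
        out[key] = {
            "n_pt": sp_pt.n, "n_clm": sp_clm.n,
            "proportions_pt": sp_pt.proportions.to_dict(),
            "proportions_clm": sp_clm.proportions.to_dict(),
            "higher_in_clm": comp.loc[comp["higher_in_clm"], "category"].tolist(),
        }
    return out


def _stage_cna_loh(records, inputs, cna_policy, loh_policy, tables) -> dict:
    segments = call_cna_states(inputs.segments, cna_policy)
    cooccur = cooccurrence_frequency(records, segments)
    tables["cooccurrence"] = cooccur
    out = {"cooccurrence": cooccur.set_index("class")[
        ["frac_deletion", "frac_amplification", "n"]].to_dict("index")}
    if inputs.snp_sites:
        snps = call_loh_states(inputs.snp_sites, loh_policy)
        class1h = [r for r in records if r.class1h_15]
        profile = loh_density_profile(class1h, snps, role="CLM")
        tables["loh_profile_class1h"] = profile.bins
        out["loh_profile_class1h"] = central_enrichment_test(profile)
        out["n_loh_calls"] = int(sum(1 for s in snps if s.loh))
    return out


def _stage_integration(records, inputs, detection, rescue_policy, tables) -> dict:
    out = {}
    res = rescue_rejected(records, rescue_policy)
    out["rescue"] = {"n_rescued": len(res.rescued),
                     "n_missing_rna": res.n_missing_rna}
    tables["rescued"] = pd.DataFrame(
        [{"patient": r.patient_id, "chrom": r.position.chromosome,
          "pos": r.position.position, "gene": r.gene} for r in res.rescued])
    for role in ("PT", "CLM"):
        inter = intersect_exome_rna(records, detection, role,
                                    expression=inputs.expression)
        out[f"intersection_{role}"] = {
            "n_common": inter.n_common, "n_exome_only": inter.n_exome_only,
            "n_rna_only": inter.n_rna_only,
            "frac_common_of_exome": inter.frac_common_of_exome,
            "frac_common_of_rna": inter.frac_common_of_rna,
            "frac_exome_only_low_expression":
                inter.frac_exome_only_low_expression,
        }
    enriched, n_excl = select_rna_enriched(records)
    out["rna_enriched"] = {"n_selected": len(enriched), "n_excluded": n_excl}
    tables["rna_enriched"] = _record_table(enriched)
    candidates, n_excl = select_candidate_clm(records)
    out["candidate_clm"] = {"n_selected": len(candidates), "n_excluded": n_excl}
    tables["candidate_clm"] = _record_table(candidates)
    ma_table, trend = bin_ma_scores_by_vaf(records)
    tables["ma_bins"] = ma_table
    out["ma_trend"] = trend
    high = ma_table[ma_table["bin_left"] >= 0.6]
    w = high["n"].sum()
    out["ma_mean_above_60pct_vaf"] = (
        float((high["mean_ma_score"] * high["n"]).sum() / w) if w else None)
    if inputs.expression is not None:
        for program in (P53_PROGRAM, WNT_PROGRAM):
            for assay in ("rna", "exome"):
                key = f"coupling_{program.driver}_{assay}"
                try:
                    _, res, sign_ok = vaf_expression_correlation(
                        records, inputs.expression, program, assay=assay)
                    out[key] = {"r": res.value, "p": res.p_value,
                                "slope": res.extra.get("slope"),
                                "sign_consistent": sign_ok}
                except (ContractError, ValidationError) as exc:
                    out[key] = {"error": str(exc)}
    return out


def _stage_splicing(records, inputs, detection, skip_policy, tables) -> dict:
    models_by_transcript = {m.transcript: m for m in inputs.gene_models}
    rows = []
    n_flagged = 0
    for rec in records:
        ann = annotate_splice_site(rec, inputs.gene_models)
        if ann is None:
            continue
        model = models_by_transcript[ann.transcript]
        carriers = [f"{rec.patient_id}:{role}" for role in ("PT", "CLM")
                    if detection.detected(rec.obs(role, "exome"))]
        call = detect_exon_skipping(ann, model, inputs.junctions, carriers,
                                    skip_policy)
        n_flagged += bool(call.flagged)
        carrier_ratios = [call.skip_ratios[s] for s in carriers
                          if s in call.skip_ratios]
        rows.append({
            "patient": rec.patient_id, "gene": ann.gene,
            "transcript": ann.transcript, "side": ann.side,
            "exon_index": ann.exon_index, "offset": ann.offset,
            "evaluable": call.evaluable, "flagged": call.flagged,
            "consequence": call.consequence,
            "carrier_max_skip_ratio": max(carrier_ratios, default=float("nan")),
            "reason": call.reason})
    tables["skipping"] = pd.DataFrame(rows)
    return {"n_splice_site_mutations": len(rows), "n_flagged": n_flagged}


def _stage_expression(inputs, tables) -> dict:
    groups = [g for g in ("normal", "PT", "CLM")
              if len(inputs.expression.columns_for_role(g)) >= 2]
    sds, tests = expression_sd_distribution(inputs.expression, groups)
    tables["expression_sd"] = sds.reset_index(names="gene")
    out = {"median_sd": {g: float(sds[g].median()) for g in groups}}
    for (g1, g2), res in tests.items():
        out[f"test_{g1}_vs_{g2}"] = res
    return out


def _record_table(records) -> pd.DataFrame:
    return pd.DataFrame([
        {"patient": r.patient_id, "chrom": r.position.chromosome,
         "pos": r.position.position, "ref": r.ref_allele, "alt": r.alt_allele,
         "gene": r.gene,
         "vaf_pt_exome": r.vaf("PT", "exome"), "vaf_pt_rna": r.vaf("PT", "rna"),
         "vaf_clm_exome": r.vaf("CLM", "exome"),
         "vaf_clm_rna": r.vaf("CLM", "rna"), "ma_score": r.ma_score}
        for r in records])
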
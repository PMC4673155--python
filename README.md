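# ptclm — paired primary-tumor / liver-metastasis mutation analysis

When a colorectal cancer metastasizes to the liver, which somatic mutations
travel with it, which are left behind, and which arise anew? `ptclm` is a
pipeline for cohorts of matched **normal / primary tumor (PT) / colorectal
liver metastasis (CLM)** trios profiled by both exome and RNA sequencing. It
is aimed at cancer-genomics analysts who have somatic call tables,
copy-number segments, SNP B-allele frequencies, expression matrices and
junction counts in hand and want the downstream comparative analysis — plus
a ground-truth simulator to validate every stage end to end.

## What it computes

**Mutation classes.** Each variant with PT and CLM exome observations is
classified as *class1* (shared), *class2* (PT-only) or *class3* (CLM-only)
under an explicit detection policy (depth ≥ 10, alt reads ≥ 3, VAF ≥ 0.05);
sites too shallow to distinguish absence from dropout are *unassessable*.
*Class 1-H* marks shared mutations whose variant allele frequency (VAF =
alt/depth) rises by ≥ 15 (or 30) percentage points in the metastasis — the
footprint of clonal selection or allelic loss in transit. Classes are tested
for association with clinical attributes (chi-square) and per-patient
concordance is regressed on clone-count change.

**Exome–RNA integration.** Variants rejected by the exome caller are
*rescued* when RNA independently keeps them at more than 10× coverage; the
exome/RNA detection overlap is partitioned and exome-only calls are explained
by low expression; transcriptome-enriched mutations (RNA VAF ≥ exome VAF +
15 points in both tumors) and high-CLM-VAF candidates (CLM RNA VAF ≥ 60%
plus an enrichment delta) are selected; functional-impact scores are binned
by VAF; and a driver's per-patient VAF is regressed on the mean expression
of its target program (p53 targets: negative; WNT targets: positive).

**Substitution spectra.** Six pyrimidine-strand classes, Ts/Tv balance, and
the 96 trinucleotide contexts `X[C>A]Y`, with per-category PT-vs-CLM
two-proportion tests.

**CNA / LOH co-occurrence.** Segments with |log2 ratio| > 0.5 are deletions
or amplifications; LOH is called at normal-heterozygous SNPs whose tumor BAF
leaves [0.2, 0.8]; each mutation class gets its fraction inside deletions
and an LOH-density profile in 100-kb bins within ±1 Mb.

**Splicing.** Mutations in the two canonical intronic bases beside an exon
are tested for carrier-specific exon skipping from junction reads, with a
frameshift/premature-stop prediction from the skipped exon's coding length.

**Synthetic cohorts.** `ptclm simulate` emits every input table with known
truth, generated from the mixture model
`E[VAF] = purity·CCF·mutant_copies / (purity·CN + (1−purity)·2)` with
binomial read noise — see `docs/methods.md` for the full generative model
and its defaults.

## Worked example

```python
from ptclm import run_pipeline

report = run_pipeline({"simulation": {}, "seed": 1})
cls = report.summary["classes"]
print(f"mutations: {report.summary['n_records']}  assessable: {cls['n_assessable']}")
print(f"class fractions  shared: {100*cls['frac_class1']:.1f}%  "
      f"PT-only: {100*cls['frac_class2']:.1f}%  CLM-only: {100*cls['frac_class3']:.1f}%")
integ = report.summary["integration"]
print(f"rescued by RNA support: {integ['rescue']['n_rescued']}")
print(f"TP53 RNA-VAF vs p53-target expression: r = {integ['coupling_TP53_rna']['r']:.2f} "
      f"(p = {integ['coupling_TP53_rna']['p']:.1e})")
```

prints

```
mutations: 2037  assessable: 1976
class fractions  shared: 59.8%  PT-only: 20.4%  CLM-only: 19.8%
rescued by RNA support: 102
TP53 RNA-VAF vs p53-target expression: r = -0.86 (p = 2.0e-06)
```

A simulated 19-patient cohort carries ~2,000 somatic mutations; about 60%
are shared between primary and metastasis and the remainder split roughly
evenly between PT-specific and CLM-specific — the planted class mix
recovered by the classifier. The 102 rescued records are exactly the planted
reject-but-expressed variants. The strong negative correlation between TP53
RNA VAF and mean p53-target expression reflects the planted
allele-specific-expression coupling; the same regression on exome VAFs is
much weaker, because transcriptome skew is invisible to DNA.

The same run from a shell, with all tables written to disk:

```bash
echo "simulation: {}" > config.yaml
ptclm run-all --config config.yaml --seed 1 --out-dir report/
```

`report/` then holds `summary.json` plus per-stage TSVs (`classes.tsv`,
`spectra_6_class.tsv`, `cooccurrence.tsv`, `loh_profile_class1h.tsv`,
`rna_enriched.tsv`, `candidate_clm.tsv`, `skipping.tsv`, ...). To analyse
your own cohort, replace the `simulation` block with an `inputs` block of
file paths (formats documented in `ptclm/io.py`).

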
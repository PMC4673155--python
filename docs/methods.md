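# Methods

`ptclm` re-implements, as a reusable and tested pipeline, the downstream
analysis of paired colorectal primary tumors (PT) and colorectal liver
metastases (CLM) profiled by exome and RNA sequencing: a mutation class
taxonomy, RNA-based rescue of rejected variant calls, substitution spectra,
copy-number/LOH co-occurrence, exome-transcriptome VAF integration, and
mutation-dependent exon-skipping detection. Because the real cohort's numbers
depend on its deposited reads and caller versions, validation here is
property- and simulation-based: a synthetic-cohort generator emits all input
tables with known ground truth, and every stage is scored against that truth.

## Mutation classes

For each somatic variant with PT and CLM exome observations, the class is

- **class1** — detected in both tumors (shared),
- **class2** — detected only in the primary,
- **class3** — detected only in the metastasis,
- **unassessable** — the tumor where the variant is absent is covered below
  the depth floor, so true absence cannot be distinguished from dropout.

"Detected" is an explicit policy: depth >= 10, alt reads >= 3, VAF >= 0.05
(MuTect-like minimums; all three are `DetectionPolicy` parameters). Class
assignment uses exome observations only, because absence from RNA can reflect
low expression rather than clonal absence. **Class 1-H** is the subset of
class1 whose CLM VAF exceeds its PT VAF by at least 15 (or 30) *percentage
points* — absolute VAF differences, not ratios, which keeps the 30-point tier
meaningful for VAFs below 0.7. Unassessable records are excluded from
fractions and associations and reported separately.

Clinical association uses a Pearson chi-square on the 2x2 table of mutation
counts (class x attribute-positive/-negative patients), two-sided, without
continuity correction by default (a toggle exposes Yates). The advanced-stage
attribute groups T3 with T4. Concordance-vs-clonality regresses the
per-patient class1 (or class3) fraction on the change in externally inferred
clone-cluster counts (CLM minus PT); cluster counts are inputs, never
inferred here.

## Exome-RNA integration

- **Rescue**: a variant rejected by the exome caller is revived when the RNA
  caller independently keeps it at *more than* 10x coverage, read strictly as
  depth >= 11 (`RescuePolicy.min_rna_depth`).
- **Intersection**: per tumor, variants are partitioned into
  exome-and-RNA / exome-only / RNA-only under the same detection policy.
  Exome-only calls are annotated with whether their gene stays below
  1 log2(RPKM+1) in every sample — the low-expression explanation.
- **Transcriptome-enriched selection**: RNA VAF at least 15 points above the
  exome VAF in *both* PT and CLM (inclusive boundary).
- **Candidate CLM filter**: CLM RNA VAF >= 0.60 *and* a >= 15-point RNA-exome
  delta in PT *or* CLM (logical OR over roles). The 60% floor is applied to
  the transcriptome VAF.
- **Functional-impact binning**: Mutation Assessor scores are averaged in
  VAF bins of width 0.1; observations below 10x are skipped because a VAF
  from a handful of reads lands in an arbitrary bin; the monotone trend is
  the Spearman correlation of bin midpoint against bin mean.
- **Driver-target coupling**: the per-patient driver VAF (max over that
  patient's driver mutations; the reducer is a parameter) is regressed
  against the mean over target genes of log2(RPKM+1). The expected sign is
  negative for the p53 program (11 canonical p53 targets) and positive for
  the WNT program (19 canonical WNT targets). log2(RPKM+1) avoids -inf at
  zero expression.

## Substitution spectra

Substitutions are collapsed onto the pyrimidine reference strand (G>A counts
as C>T), giving the 6 standard classes and, with flanking bases, the 96
trinucleotide categories written `X[C>A]Y`. C>T and T>C are transitions, the
other four classes transversions. Flanks must come from explicit flank
columns or a reference; 96-context mode errors rather than guessing. Indels
and MNVs are excluded with a logged count. PT and CLM spectra are compared
per category with two-proportion z-tests, unadjusted by default
(Benjamini-Hochberg via a flag). Cohort spectra pool mutations across
patients.

## CNA and LOH

A segment is a deletion (amplification) when its log2 tumor/normal ratio is
strictly below -0.5 (above +0.5); boundary values are neutral ("more than
+-0.5" read strictly). LOH is called at a SNP heterozygous in the matched
normal (BAF in [0.3, 0.7]) whose tumor BAF lies at least 0.3 from 0.5, with
both samples at >= 20x; zero-depth sites are unevaluable, not false. The
0.3/0.3/20 thresholds are this package's explicit policy for what the
original toolchain delegated to its LOH caller.

Co-occurrence reports, per class, the fraction of mutations inside deletion
(resp. amplification) segments. Shared and CLM-specific classes are scored
against CLM segments, PT-specific mutations against PT segments — allelic
loss *during metastasis* is the event of interest for class1-H, and the
symmetric attribution for class2 mirrors it. Overlapping input segments are
rejected rather than resolved by priority. The LOH density profile pools
heterozygous SNPs within +-1 Mb of each mutation of a class into 100-kb
signed-distance bins (half-open `[left, right)`, so +1 Mb is excluded) and
reports per-bin LOH rate = LOH calls / informative heterozygous SNPs; raw
counts are emitted alongside. Central-vs-outer enrichment is tested with a
one-sided two-proportion z on pooled counts.

## Splicing and expression

RPKM = reads / (gene length/1e3) / (library size/1e6). Expression
variability is the per-gene SD of log2(RPKM+1) within a tissue group;
groups are compared with two-sided Mann-Whitney tests (the SD distribution
is skewed, so a rank test is the safer location test).

A splice-site mutation lies in the 2 canonical intronic bases (the GT/AG
dinucleotides) adjacent to any exon boundary; donor/acceptor follow the
transcription direction, so the same genomic geometry swaps sides on the
minus strand. For the exon adjacent to the mutated site, the skip ratio per
sample is

    skip_reads / (skip_reads + mean(inclusion_left, inclusion_right))

over the exon-skipping junction (k-1 -> k+1) and the two inclusion
junctions. A call is flagged only when the carrier reaches a ratio >= 0.2 at
junction depth >= 10 while the *maximum* non-carrier ratio stays below 0.05
(the most conservative baseline). Terminal exons, uncovered carriers and
sub-threshold carrier depth are unevaluable rather than negative. Only
single-exon skipping is tested. Skipping a coding exon whose coding length
is not a multiple of 3 predicts a frameshift/premature stop; a multiple of 3
an in-frame deletion; exons without coding bases are non-coding.

## The synthetic cohort generator

The generator emulates the study design: 19 patients by default, each with a
normal tissue, a PT and a CLM, profiled by exome (mean 100x) and RNA
(mean 80x). Its defaults are the study conditions: mean mathematically
estimated purities 0.466 (PT) and 0.476 (CLM); class mix
0.576/0.209/0.215; per-class deletion-superposition rates 0.058 / 0.0413 /
0.0423 and 0.20 for class1-H.

Per mutation, the expected VAF follows the standard two-population mixture

    E[VAF] = purity * CCF * mutant_copies
             / (purity * tumor_CN + (1 - purity) * 2),

with depth ~ Poisson(mean, floor 1) and alt reads ~ Binomial(depth, E[VAF]).
Class2/class3 absence is true biological absence (CCF 0), not dropout;
dropout robustness is probed separately by depth manipulation. A subclonal
tail (15% of mutations, CCF uniform on [0.5, 1]) reflects the mostly clonal
architecture of high-purity colorectal tumors while keeping detection
non-trivial. Class 1-H mutations are planted as a PT subclone (CCF 0.5) that
becomes clonal in the CLM and either sits under a planted deletion (one
mutant copy of one) or undergoes copy-neutral LOH (two mutant copies of
two) — the two mechanisms the class is meant to capture; both give an
expected CLM-PT VAF gain >= 15 points at the default purities.

Deletion segments are +-200 kb around their mutation with log2 ratio uniform
on [-1.2, -0.7]; amplifications (rate 0.03, CN 4) on [0.7, 1.2]; segments
never overlap within a sample (positions are re-drawn on collision).
Heterozygous SNPs (10 per mutation) are scattered uniformly within +-1 Mb of
each mutation for both tumor samples; normal BAF ~ Binomial(depth, 0.5)/depth,
and SNPs inside deletions (plus a 2% genome-wide background) draw tumor BAF
around 0.9 or 0.1 — deletions in the simulator are near-clonal allelic
losses, deliberately stronger than the cohort-average purity would imply so
that LOH is a property of the planted event, not of the admixture level.

Allele-specific expression multiplies the mutant-allele sampling probability
in RNA only (capped at 0.98), with a per-patient skew factor drawn uniformly
from a driver-specific range (TP53: [1, 2] on top of copy-neutral LOH; APC:
[1, 3]). Target-program expression is baseline + slope x (true driver RNA
VAF) + Gaussian noise (sigma 0.3 log2 units), slope -2 for the p53 program
and +2 for WNT — so RNA VAFs are informative about expression while exome
VAFs are decoupled, reproducing the RNA-vs-exome correlation contrast.
Functional-impact scores are 1 + 2 x (true CLM RNA VAF) + noise, clipped at
zero. Junction reads draw a Poisson total (mean 2000 per junction pair) and
split it multinomially over (skip, inclusion-left, inclusion-right) with
probabilities (psi, (1-psi)/2, (1-psi)/2); carrier PSI 0.5 against a
non-carrier background of 0.01. Junction totals are set deep, as for a
well-expressed transcript, so the planted PSI contrast dominates sampling
noise. Rescue planting forces (exome reject, RNA keep, RNA depth >= 11) on
5% of records; "decoy" rejects (another 5%) fail the rescue rule by
construction (RNA reject, or RNA depth <= 10). Expression matrices add
per-group sample noise with SD 0.30/0.45/0.60 (normal/PT/CLM), encoding the
widening transcriptome variability along progression. Exome-only planting
assigns 10% of mutations to genes with RPKM ~ 0.1 and starves their RNA
coverage.

What the generator does **not** emulate: real genome sequence (flanking
bases are uniform unless a reference is supplied), mutational-signature
structure beyond the configured 6-class weights, clone trees, RNA editing,
library-specific coverage biases, and subclonal copy number. Passing tests
therefore demonstrate that the operators implement their definitions and
recover planted structure under binomial/Poisson noise — not that the real
cohort's specific numbers would be reproduced.

## Numerical and design choices

- Coordinates are 1-based closed everywhere in I/O (VCF/segment convention).
- Merging duplicate rows for the same (patient, site, role, assay) is an
  error, not an overwrite: ambiguity signals corrupt input.
- Indels flow through class/VAF logic like SNVs but are excluded from
  spectra.
- Welch's t is the default two-sample test; constant-equal groups return
  p = 1, constant-unequal groups are flagged degenerate.
- Zero-variance regressions and zero-margin chi-square tables are flagged
  degenerate rather than returning NaN silently.
- The caller verdict is a single field per observation; when both of the
  study's callers would have reported a site, upstream merging is assumed to
  have produced one verdict.
- `run_pipeline` is a pure function of (inputs, config, seed); summary JSON
  is sorted and versioned so re-runs are byte-identical.

## Problem sizes used in validation

The test suite exercises cohorts of 19 patients x ~105 mutations (~2,000
mutations) for class-fraction, rescue and co-occurrence recovery;
100-seed repetitions use the same scale for co-occurrence, 8 patients for
the LOH-density peak, and minimal cohorts (drivers or splice events only)
for coupling power and skipping sensitivity — sizes chosen so each check
retains the power its acceptance bound needs while the whole suite stays
fast on one CPU. Criterion-level recovery of planted deletion rates is
scored against the simulator's true class labels; label-assignment accuracy
is scored separately, so each check isolates one mechanism.

## Known limitations

- The unassessable category, the detection policy, the LOH thresholds and
  the skip-ratio thresholds quantify steps the original analysis left
  qualitative; all are exposed as parameters.
- Per-patient averaging of spectra (as opposed to pooling) is available but
  not the default.
- The candidate filter's 60% VAF floor is applied to the transcriptome VAF;
  a toggle selects the exome reading.
- VAFs are raw alt/depth with no purity correction anywhere in the analysis;
  purity exists only inside the simulator.
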
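# Methods

This note documents the models, rules and numerical choices behind
`oncowga`, and what the synthetic cohort does and does not emulate.

## Scope and inputs

The package starts *after* primary analysis: alignment and variant calling
are upstream and their outputs (somatic small-variant VCF, CNA segment
table, SV breakend VCF, germline VCF) are consumed as call sets, together
with shared resources (panel-of-normals allele depths, population allele
frequencies, simple-repeat intervals, gene models, a ClinVar-style table, a
test-directory table, a 96×K signature matrix) and clinical tables
(registry, hospital episodes, treatments, mortality). Coordinates are
1-based closed internally; BED resources are converted on read; variants
are decomposed to bi-allelic records, trimmed and left-aligned on read.

## Sequencing QC gate

Thresholds are applied as strict inequalities exactly as the protocol words
them: normal yield > 85 Gb, tumor yield > 210 Gb, autosomal 15× coverage
fraction > 0.95, normal contamination < 3%, tumor contamination < 2.5%,
pair concordance required. The gate returns every violated threshold, and
is monotone: improving any single metric can only shrink the failure list.
The PCA-based fleet-quality monitoring used operationally has no published
thresholds and is represented only by the pass-through metrics record.

## Somatic filter cascade

Five additive, order-independent labels. Thresholds: population allele
frequency strictly above 1%; cohort recurrence strictly above 5%; any
overlap of the variant's reference span with a simple-repeat interval;
indels where the mean failed-base-call fraction over the 101-position
window centred on the call is at least 10%; SNVs whose Fisher's-exact Phred
score against the panel of normals is strictly below 50. Labeled variants
stay in the call set; only the high-confidence (unflagged) subset feeds TMB
and mutational catalogs.

**Panel-of-normals test.** The 2×2 table compares tumor ref/alt depths
with panel ref/alt depths aggregated over individuals not carrying the
alternate allele. "Not carrying" is implemented as an alt fraction below
`pon_carrier_min_alt_fraction` (default 0.3): het/hom germline carriers are
excluded while low-level noise depths — the signal the test exists to
detect — are retained. (A literal "alt depth = 0" reading would zero the
panel's alt column and make artifact sites undetectable.) The test is
two-sided ("significantly different" is direction-free); sidedness and the
carrier threshold are config-exposed. Sites absent from the panel
contribute a configurable default reference depth with zero alt depth.
p-values are floored at 1e-300 before the Phred transform. The
implementation path is `scipy.stats.fisher_exact`; the test suite checks it
against exact rational-arithmetic hypergeometric enumeration.

**Window rule.** The noisy-indel window is 101 positions (the call ± 50),
truncated at contig ends; per-position base-call counts are approximated by
a (fail-fraction, depth) track since read-level detail is not
reconstructable from call sets, with equal weights when no depth track is
given.

## Consequence annotation

One canonical transcript per gene (no fallback hierarchy). SNVs in the CDS
are classified by codon translation (start_lost for any change in codon 1;
stop_gained/stop_lost/missense; synonymous changes are not reportable
unless they fall in the exonic splice-region flank). Splice classes follow
the usual convention: 2 intronic bases on each side of a junction are
donor/acceptor (transcript-strand aware), intronic bases 3–8 and exonic
bases 1–3 from a junction are splice_region. Indels touching the CDS are
frameshift or in-frame by net length mod 3 (a length-preserving block
substitution counts as protein-altering); CDS overlap takes precedence
over splice classes for indels spanning a junction. "Nonsynonymous" —
used for TMB and the small-variant half of the loss scenarios — is the
curated set minus splice_region.

## CNA and SV actionability

"At least twice higher than the overall ploidy" is read as CN ≥ 2×ploidy
(config `gain_multiplier`, and a 3× reading is one config change away).
Real-valued caller CN is compared unrounded for the gain rule; the
±1-copy co-occurrence rule is stated in copies, so it uses the rounded
ploidy. Loss scenarios, in precedence order: (1) any overlapping segment
with CN = 0 (tolerance 1e-6) — no small variant required; (2) CN = 1, or
copy-neutral LOH (minor CN = 0 with total CN within 0.5 of ploidy,
tolerance config-exposed), together with a nonsynonymous small variant;
(3) an SV breakend strictly inside the CDS span together with a
nonsynonymous small variant. The purity gate (> 30%, strict) applies to
all CNA rules; ineligible cases are returned as findings with
`eligible=False` so the denominator bookkeeping stays explicit.

**Fusion frames.** Each breakend retains one side of its junction (the
breakend's own base included). A partner can be upstream only if its
retained piece contains the transcription start, downstream only if it
contains the transcription end; if no upstream/downstream assignment
exists, or a breakpoint lies outside both transcripts, the event is
untranscribed. Coding phase at a breakpoint is the retained (upstream) or
removed (downstream) CDS length mod 3; the junction is in frame iff the
two phases agree. Exonic breakpoints that split a codon, and events whose
downstream breakpoint lies in the 5′UTR (whole CDS retained under a new
promoter), are ambiguous and reportable. Upstream breakpoints in either
UTR and downstream breakpoints in the 3′UTR cannot produce a read-through
product and are discarded as out of frame. When both assignments of a
breakend pair are orientation-valid, the more optimistic status is kept
(inframe > ambiguous > out_of_frame). The suite checks the status against
brute-force spliced-sequence reconstruction over dense breakpoint grids on
both same-strand and opposite-strand partner pairs.

## Germline and pharmacogenomics

Reportable bases: (a) a ClinVar-style record with classification
pathogenic/likely pathogenic ("probably pathogenic" maps to the standard
likely-pathogenic term) and ≥ 2 review stars; (b) predicted
protein-truncating consequences (stop gained/lost, start lost, frameshift,
splice acceptor/donor) in genes whose mechanism is loss of function.
Reporting is restricted to the germline-indicated gene set for the case's
tumor type by default; pan-type reporting is a config switch, since the
source protocol does not enumerate its indicated subset in-text. The DPYD
allele table is a documented synthetic placeholder keyed to the toy DPYD
transcript; a real star-allele table is a drop-in TSV.

## Pangenomic markers

TMB = protein-altering high-confidence small variants ÷ coding megabases;
the coding footprint is the CDS union of the gene models (0.0168 Mb on the
toy reference — per-megabase values on synthetic data are therefore large,
which is immaterial to the rules being exercised). Catalogs use the
standard 96 pyrimidine-strand trinucleotide channels. Refitting is
non-negative least squares against a fixed signature matrix — a
deterministic, desk-scale stand-in for de-novo extraction machinery with
the same contract — with exposures reported as fractions of assigned mass
plus a relative L2 residual. Etiology groups follow the fixed map (APOBEC
SBS2+13; aging SBS1; HRD SBS3; MMR SBS6/15/20/21/26/44; POLE
SBS10a/10b/14; smoking SBS4+92; UV SBS7a–d); SBS14 sits in the POLE group
only. The 20% rule is applied per etiology group after grouping: groups
below 20% move to "other", and MMR deficiency is called iff the MMR group
exceeds 20% (strict). HRD classifier outputs are inputs, not
re-implementations; only their pairwise concordance (unknowns excluded
pairwise) is computed. PCR-amplified libraries carry a boolean case flag
for exclusion from cohort-level signature displays.

**Signature matrix.** The shipped matrix is synthetic: deterministic
profiles generated in code under COSMIC v3 column names, each concentrated
on the substitution classes characteristic of its namesake (C>T at NpCpG
for SBS1, TpC focus for SBS2/13, broad flat profiles for SBS3/SBS5/SBS40,
C>A for SBS4, dipyrimidine C>T for SBS7a/b, …) plus decoy signatures. The
real COSMIC matrix is a drop-in replacement with the same layout. Sparse
near-orthogonal profiles make NNLS recovery well-conditioned; recovery
accuracy statements in the tests are statements about this matrix, not
about COSMIC's (which has more collinear columns).

## Clinical linkage

Benign/in-situ registry tumors are dropped first. The cascade:
registry ICD-10 match → nearest-in-time type-matching cancer episode
(ties: earlier date) → curated operation code on the exact sampling date
(primary tumors) → flexible ICD-10 match for the configured
registry/submission pairs with |Δdate| < 7 days, strict (non-primary
tumors) → submitted ICD-10 code → unmatched. "Closest relevant" is read
as the nearest *type-matching* episode: a nearer type-discordant episode
does not block a farther matching one. Stage: metastatic submissions are
4 unconditionally; otherwise FIGO (ovarian/endometrial; I–IV ignoring
sub-letters), Dukes (colorectal; A–D → 1–4) or stage_best (first digit),
taken from the nearest eligible registry row with |diagnosis − sample| <
365 days, strict; unmapped codes warn and resolve to unknown.

## Cohort analytics

Prevalence matrices count cases with ≥ 1 finding per (tumor type, gene,
variant class), split into directory-indicated and off-directory
partitions; the CNA denominator is the purity-eligible subset.
Co-occurrence uses Fisher's exact test per gene (the source names only
"multiple-testing correction"; Benjamini–Hochberg is the default, with
Bonferroni config-exposed); genes with an empty stratum return an
undefined p and are excluded from the correction. Survival: Kaplan–Meier
per group (lifelines), a stage-stratified log-rank test (observed−expected
and covariance accumulated within stage strata; reduces to the standard
log-rank with one stratum, verified against lifelines), and a Cox model
with the group indicator plus stage as a categorical covariate.
Unknown-stage cases are excluded from stage-corrected models (no
imputation). Survival origin is the registry diagnosis date when present,
else the sample date; censoring is the last episode date. TMB groups are
the lowest vs highest quartile within the analyzed tumor-type subset,
middle quartiles excluded. Groups with zero events return an undefined HR
with an explanatory note rather than an error.

On the synthetic stage-confounded generator the stage-corrected Cox CI
achieves ~93–95% empirical coverage at n = 1,000 per arm (identical
coefficients and standard errors to R's `coxph` on the same data); the
acceptance suite asserts ≥ 90% coverage over 50 replicate seeds.

## Synthetic cohort

The generator emits everything the pipeline reads, with a JSON truth
record per case. Design choices:

- **Toy reference**: two contigs (300 kb + 200 kb) of seeded random
  sequence; ~23 cancer genes with three-exon canonical transcripts whose
  CDSs are patched to clean ORFs. Desk-scale: every stage runs in seconds.
- **Background mutations** are drawn from per-type signature mixtures
  (UV-dominated melanoma, smoking-dominated lung, HRD-flavoured ovarian,
  an MMR-deficient hypermutated colon subpopulation, …), placed at
  intergenic positions matching their trinucleotide context. Coding
  events are planted, not emergent, so truth-based prevalence and recall
  comparisons are exact. Mutation placement respects context but not
  selection, clonality or read-level error.
- **Planted events** per case: directory and off-directory coding
  variants, oncogene gains, the three loss scenarios, in-frame and
  out-of-frame fusions on both same- and opposite-strand partner pairs,
  germline findings via both reporting bases, DPYD alleles, and planted
  violations of each somatic filter rule (these carry `clean: false` in
  the truth record; recall statements apply to clean events).
- **Study conditions as defaults**: 11.9% metastatic submissions; staging
  resolving for 86.7% of cases overall (the registry stage-availability
  parameter 0.921 is derived from that figure jointly with registry
  availability 0.95 and the 365-day window hit rate 0.97); 40% HRD
  prevalence in high-grade serous ovarian cancer; 99.2% HRD-classifier
  concordance (0.8% independent disagreement); DPYD carrier probability
  7.5% (mid-range of the reported 5–10%); HR 0.37 for HRD-positive
  disease and 2.34 for high-TMB melanoma in the survival generator.
- **Survival** draws exponential times with a stage-dependent baseline
  hazard (0.06/0.12/0.25/0.60 per year for stages 1–4) so stage confounds
  marker effects — marker prevalence also rises with stage in the
  dedicated two-arm generator — and right-censors at a uniform 1–6-year
  follow-up horizon recorded as a final episode.
- **Panel of normals**: 40 individuals at 30× (well below a production
  panel; depths aggregate to the same test contract), with artifact sites
  carrying ~10% alt fractions across the panel and occasional het-like
  carriers to exercise the exclusion rule.

What passing tests on this cohort do *not* show: performance on real
genomes (alignment artifacts, subclonality, FFPE damage, panel
inflation), realistic genome-wide mutation rates, or COSMIC-matrix
collinearity effects on refitting. They do show that every rule,
threshold and cascade behaves exactly as specified on inputs whose truth
is known, at the stated problem sizes (300-case end-to-end cohort;
20,000-mutation catalogs; 2,000-case survival arms — sizes chosen to keep
a full run at desk scale).

## Error handling and degenerate inputs

Malformed records raise errors naming file and position. All-zero Fisher
tables return p = 1 (Phred 0). Empty catalogs are an error for refitting
but contribute zero to cohort summaries. Missing sample dates fail
linkage loudly; unmapped stage codes warn and return unknown. Ploidy ≤ 0
and negative depths are input errors.
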
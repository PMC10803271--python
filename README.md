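# oncowga

Post-variant-calling interpretation and real-world outcome analytics for
paired tumor–normal whole-genome sequencing (WGS) cohorts, modeled on the
analysis stack of a national cancer WGS programme. The package consumes
call sets produced upstream (small variants, copy-number segments,
structural-variant breakends, germline calls) and reproduces the
interpretation layers that turn them into clinically oriented results:

- **Sequencing QC gate** — pairs enter interpretation only with >85 Gb
  (normal) / >210 Gb (tumor) of high-quality yield, >95% of the normal
  autosomal genome at ≥15×, cross-patient contamination <3% (normal) /
  <2.5% (tumor), and a concordant pair.
- **Somatic filter cascade** — five additive labels on top of the caller's
  own filters: population germline allele frequency >1%; cohort somatic
  recurrence >5%; simple-repeat overlap; indels in windows where ≥10% of
  base calls within ±50 bp failed quality; and SNVs whose tumor allele-depth
  ratio is *not* significantly different from a panel of normals
  (two-sided Fisher's exact test, Phred score `−10·log₁₀ p < 50`).
  Flagged variants are labeled, never removed.
- **Consequence annotation** on canonical transcripts, restricted to a
  curated set (stop gained/lost, start lost, frameshift, in-frame indel,
  missense, splice acceptor/donor/region).
- **CNA/SV actionability** — oncogene gains at CN ≥ 2× ploidy; tumor-
  suppressor losses under three scenarios (homozygous deletion; LOH or
  copy-neutral LOH plus a nonsynonymous small variant; coding-region SV
  disruption plus a nonsynonymous small variant); purity >30% gate; gene
  fusions classified by reading-frame consistency across the breakpoint
  (in-frame and ambiguous events reportable, out-of-frame and
  untranscribed discarded).
- **Germline & pharmacogenomics** — ClinVar-style pathogenic/likely
  pathogenic calls with ≥2 review stars, predicted protein-truncating
  variants in loss-of-function genes, and DPYD toxicity-allele flags.
- **Pangenomic markers** — TMB (nonsynonymous high-confidence variants
  per coding megabase), 96-context mutational catalogs, non-negative
  least-squares signature refitting, etiology grouping (APOBEC, aging,
  HRD, MMR, POLE, smoking, UV) with a 20% display threshold, MMR-deficiency
  calls (MMR group >20%), and HRD-classifier concordance.
- **Clinical linkage** — registry/hospital-episode corroboration of the
  submitted tumor type (an ordered five-step cascade) and stage resolution
  (FIGO, Dukes or stage_best within 365 days; metastatic submissions are
  stage 4 by default).
- **Cohort analytics** — actionability prevalence matrices split by
  test-directory indication, CNA/small-variant co-occurrence (Fisher +
  Benjamini–Hochberg), and stage-corrected survival (Kaplan–Meier,
  stage-stratified log-rank, Cox proportional hazards with stage as a
  categorical covariate).

A first-class synthetic-cohort generator (`oncowga.simulate`) emits every
input the pipeline reads — with known planted truth — on a desk-scale toy
genome, so the whole stack runs and is tested without any external data.

## Worked example

```bash
oncowga simulate --out cohort --seed 3 --n-cases 8
oncowga run --case-dir cohort --out run
oncowga analyze --case-dir cohort --run-dir run --out analysis
```

which prints

```
wrote 8 cases to cohort
interpreted 8 cases -> run
analysis written to analysis
```

`run/filter_tally.tsv` then holds the per-case filter labels, e.g.

```
case_id   pop_af  recurrent  simple_repeat  noisy_indel  pon_artifact  total  high_confidence
CASE0000  3       2          4              2             3            326    312
```

meaning 326 somatic calls of which 312 survived the five-rule cascade
(3 common-population sites, 2 cohort-recurrent sites, 4 in simple repeats,
2 noisy-window indels and 3 panel-of-normals artifacts were labeled).
`analysis/actionability.tsv` reports, per tumor type × gene × variant
class, the fraction of cases with one or more findings, split into
directory-indicated and off-directory partitions.

The same flow is available as library calls:

```python
from oncowga.simulate import SimulationConfig, simulate_cohort
from oncowga import pipeline

cohort = simulate_cohort(SimulationConfig(n_cases=30), seed=1)
reports = pipeline.run_interpretation(cohort.cases, cohort.callsets, cohort.bundle)
print(pipeline.cases_table(reports)[["case_id", "tumor_type", "tmb", "mmr_deficient"]])
```

## Layout

```
src/oncowga/
  types.py       domain types (variants, segments, breakends, cases, findings)
  config.py      every threshold, with protocol values as defaults
  reference.py   toy genome + gene models, synthetic signature matrix, bundle I/O
  io.py          VCF/TSV/BED readers and writers, variant normalization
  qc.py          sequencing-quality gate
  somatic.py     consequence annotation + five-rule filter cascade
  cna_sv.py      CNA gain/loss scenarios, fusion frame assessment
  germline.py    predisposition reporting, pharmacogenomic flags
  markers.py     TMB, catalogs, signature refitting, etiologies, HRD concordance
  linkage.py     registry/episode corroboration, stage resolution
  analytics.py   prevalence, co-occurrence, survival
  simulate.py    synthetic cohort generator with planted truth
  pipeline.py    per-case and cohort orchestration
  cli.py         `oncowga simulate | run | analyze`
```
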
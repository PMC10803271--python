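"""End-to-end orchestration: per-case interpretation and cohort analysis.

``interpret_case`` runs the full post-calling stack on one tumor:
QC gate, consequence annotation, the five-rule somatic filter cascade,
TMB, catalog + signature refit + etiology/MMR calls, CNA gain/loss
actionability, fusion frame assessment, germline and pharmacogenomic
reporting. Cohort helpers assemble the per-case results into the tables
the analytics stage consumes, and file-based runners mirror the same flow
over an on-disk cohort directory.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analytics import gene_mutation_status
from .cna_sv import (
    assess_fusion,
    classify_gain,
    classify_loss,
    cna_eligible,
    cna_event_for_cooccurrence,
)
from .germline import classify_germline, flag_pgx
from .io import (
    ClinicalBundle,
    read_clinical_bundle,
    read_cna_tsv,
    read_germline_vcf,
    read_somatic_vcf,
    read_sv_vcf,
)
from .linkage import corroborate_diagnosis, resolve_stage
from .markers import build_catalog, classify_etiologies, compute_tmb, fit_exposures
from .qc import QcResult, qc_gate
from .reference import COOCCURRENCE_PANEL, ReferenceBundle, load_reference_bundle
from .somatic import annotate_variants, apply_somatic_filters
from .types import (
    CnaFinding,
    FusionAssessment,
    GermlineFinding,
    HrdCall,
    PgxFlag,
    QcMetrics,
    SomaticVariant,
    TumorCase,
)


@dataclass
class CaseReport:
    case: TumorCase
    qc: QcResult
    variants: list[SomaticVariant]
    high_confidence: list[SomaticVariant]
    tmb: float
    catalog: np.ndarray
    exposure: object | None
    etiology: object | None
    cna_findings: list[CnaFinding]
    fusions: list[FusionAssessment]
    germline_findings: list[GermlineFinding]
    pgx_flags: list[PgxFlag]
    hrd_calls: dict[str, str] = field(default_factory=dict)
    cooccurrence: dict[str, dict[str, bool]] = field(default_factory=dict)
    gene_mutation: dict[str, bool] = field(default_factory=dict)

    @property
    def cna_eligible(self) -> bool:
        return bool(self.case.purity > 0.30)

    def finding_rows(self) -> list[dict]:
        """One row per (gene, variant_class) finding, for the prevalence matrix."""
        rows = []
        seen = set()

        def add(gene: str, vclass: str) -> None:
            if (gene, vclass) not in seen:
                seen.add((gene, vclass))
                rows.append({"case_id": self.case.case_id, "gene": gene,
                             "variant_class": vclass})

        for v in self.variants:
            if v.gene and v.consequence is not None:
                add(v.gene, "small_variant")
        for f in self.cna_findings:
            if f.eligible:
                add(f.gene, "cna")
        for f in self.fusions:
            if f.reportable and f.downstream_gene:
                add(f.downstream_gene, "sv")
        for f in self.germline_findings:
            add(f.gene, "germline")
        return rows


def interpret_case(case: TumorCase, callsets: dict,
                   bundle: ReferenceBundle) -> CaseReport:
    cfg = bundle.config
    qc = qc_gate(callsets["qc"], cfg)

    variants = callsets["somatic"]
    annotate_variants(variants, bundle)
    variants, high_confidence = apply_somatic_filters(variants, bundle)
    tmb = compute_tmb(variants, bundle.coding_megabases)

    snvs = [v for v in high_confidence if v.vtype == "SNV"]
    catalog = build_catalog(snvs, bundle.genome)
    exposure = etiology = None
    if catalog.sum() > 0:
        exposure = fit_exposures(catalog, bundle.signatures)
        etiology = classify_etiologies(exposure, cfg)

    segments = callsets["cna"]
    svs = callsets["sv"]
    cna_findings: list[CnaFinding] = []
    for gene in bundle.genes.values():
        if gene.is_oncogene:
            for seg in segments:
                finding = classify_gain(gene, seg, case, cfg)
                if finding is not None and finding.eligible:
                    cna_findings.append(finding)
                    break
        if gene.is_tsg:
            finding = classify_loss(gene, segments, variants, svs, case, cfg)
            if finding is not None and finding.eligible:
                cna_findings.append(finding)

    fusions = [assess_fusion(sv, bundle) for sv in svs]

    germline_variants = callsets.get("germline", [])
    germline_findings = []
    for gv in germline_variants:
        finding = classify_germline(gv, bundle, case.tumor_type, cfg)
        if finding is not None:
            germline_findings.append(finding)
    pgx = flag_pgx(germline_variants, bundle)

    cooccurrence = {}
    gene_mut = {}
    for name in COOCCURRENCE_PANEL:
        gene = bundle.genes[name]
        has_sv = any(v.gene == name and v.consequence is not None
                     and v.consequence != "splice_region_variant" for v in variants)
        event = cna_event_for_cooccurrence(gene, segments, case, cfg)
        cooccurrence[name] = {
            "small_variant": has_sv,
            "cna_event": event == ("gain_event" if gene.is_oncogene else "loss_event"),
        }
        gene_mut[name] = gene_mutation_status(variants, segments, gene)

    return CaseReport(
        case=case, qc=qc, variants=variants, high_confidence=high_confidence,
        tmb=tmb, catalog=catalog, exposure=exposure, etiology=etiology,
        cna_findings=cna_findings, fusions=fusions,
        germline_findings=germline_findings, pgx_flags=pgx,
        hrd_calls=callsets.get("hrd_calls", {}),
        cooccurrence=cooccurrence, gene_mutation=gene_mut,
    )


def run_interpretation(cases: list[TumorCase], callsets: list[dict],
                       bundle: ReferenceBundle) -> list[CaseReport]:
    return [interpret_case(case, cs, bundle) for case, cs in zip(cases, callsets)]


# ---------------------------------------------------------------------------
# Cohort tables


def cases_table(reports: list[CaseReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "case_id": r.case.case_id, "tumor_type": r.case.tumor_type,
            "qc_pass": r.qc.passed, "cna_eligible": r.cna_eligible,
            "purity": r.case.purity, "ploidy": r.case.ploidy,
            "tmb": r.tmb,
            "mmr_deficient": bool(r.etiology.mmr_deficient) if r.etiology else False,
            "hrd_status": r.hrd_calls.get("classifier_b", "unknown"),
            "pcr_amplified": r.case.pcr_amplified,
            "n_variants": len(r.variants),
            "n_high_confidence": len(r.high_confidence),
        })
    return pd.DataFrame(rows)


def findings_table(reports: list[CaseReport]) -> pd.DataFrame:
    rows = [row for r in reports for row in r.finding_rows()]
    return pd.DataFrame(rows, columns=["case_id", "gene", "variant_class"])


def cooccurrence_events_table(reports: list[CaseReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        if not r.cna_eligible:
            continue
        for gene, flags in r.cooccurrence.items():
            rows.append({"case_id": r.case.case_id, "gene": gene,
                         "small_variant": flags["small_variant"],
                         "cna_event": flags["cna_event"]})
    return pd.DataFrame(rows, columns=["case_id", "gene", "small_variant", "cna_event"])


def filter_tally(reports: list[CaseReport]) -> pd.DataFrame:
    """Per-case counts of each filter flag (structured-log companion)."""
    rows = []
    for r in reports:
        counts = {"case_id": r.case.case_id}
        for flag in ("pop_af", "recurrent", "simple_repeat", "noisy_indel", "pon_artifact"):
            counts[flag] = sum(1 for v in r.variants if flag in v.filter_flags)
        counts["total"] = len(r.variants)
        counts["high_confidence"] = len(r.high_confidence)
        rows.append(counts)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical linkage and survival assembly


def link_cohort(cases: list[TumorCase], clinical: ClinicalBundle,
                bundle: ReferenceBundle) -> pd.DataFrame:
    rows = []
    for case in cases:
        sub = clinical.for_participant(case.case_id)
        outcome = corroborate_diagnosis(case, sub.registry, sub.episodes,
                                        config=bundle.config)
        stage = resolve_stage(case, sub.registry, bundle.config)
        rows.append({"case_id": case.case_id, "linkage_status": outcome.status,
                     "stage": stage if stage is not None else np.nan,
                     "evidence": outcome.evidence})
    return pd.DataFrame(rows)


def survival_frame(cases: list[TumorCase], linkage: pd.DataFrame,
                   clinical: ClinicalBundle) -> pd.DataFrame:
    """Per-case survival time/event from mortality and episode tables.

    The origin is the registry diagnosis date when available, else the
    sample date; cases without a death record are right-censored at the
    last date seen in the episode tables.
    """
    stage_by_case = linkage.set_index("case_id")["stage"]
    deaths = clinical.deaths.set_index("participant_id")["death_date"]
    rows = []
    for case in cases:
        sub = clinical.for_participant(case.case_id)
        reg = sub.registry
        origin = reg["diagnosis_date"].min() if len(reg) else case.sample_date
        if isinstance(origin, float):
            origin = case.sample_date
        if case.case_id in deaths.index:
            end, event = deaths.loc[case.case_id], 1
        else:
            episodes = sub.episodes["appointment_date"]
            end, event = (episodes.max() if len(episodes) else case.sample_date), 0
        time = max((end - origin).days, 1)
        rows.append({"case_id": case.case_id, "time": float(time), "event": event,
                     "stage": stage_by_case.get(case.case_id, np.nan)})
    return pd.DataFrame(rows)


def treated_case_ids(clinical: ClinicalBundle, treatment_class: str) -> set[str]:
    t = clinical.treatments
    return set(t.loc[t["treatment_class"] == treatment_class, "participant_id"])


# ---------------------------------------------------------------------------
# File-based cohort loading (mirrors simulate.write_cohort)


def load_cohort_dir(indir: str | Path):
    """Load an on-disk cohort into (bundle, cases, callsets, truths, clinical)."""
    indir = Path(indir)
    bundle = load_reference_bundle(indir / "reference" / "bundle.yaml")
    clinical = read_clinical_bundle(indir / "clinical")
    meta = pd.read_csv(indir / "cases.tsv", sep="\t")
    cases, callsets, truths = [], [], []
    for row in meta.itertuples():
        case = TumorCase(
            case_id=row.case_id, tumor_type=row.tumor_type,
            sample_route=row.sample_route, treatment_status=row.treatment_status,
            sample_preservation=row.sample_preservation,
            purity=float(row.purity), ploidy=float(row.ploidy),
            sample_date=datetime.date.fromisoformat(row.sample_date),
            submitted_metastatic=bool(row.submitted_metastatic),
            pcr_amplified=bool(row.pcr_amplified),
        )
        cdir = indir / "cases" / case.case_id
        callsets.append({
            "somatic": read_somatic_vcf(cdir / "somatic.vcf", bundle.genome),
            "germline": read_germline_vcf(cdir / "germline.vcf", bundle.genome),
            "cna": read_cna_tsv(cdir / "cna.tsv"),
            "sv": read_sv_vcf(cdir / "sv.vcf"),
            "qc": QcMetrics(
                normal_yield_gb=float(row.normal_yield_gb),
                tumor_yield_gb=float(row.tumor_yield_gb),
                normal_autosome_cov15_frac=float(row.normal_autosome_cov15_frac),
                normal_contamination=float(row.normal_contamination),
                tumor_contamination=float(row.tumor_contamination),
                pair_concordant=bool(row.pair_concordant),
            ),
            "hrd_calls": {"classifier_a": row.hrd_classifier_a,
                          "classifier_b": row.hrd_classifier_b},
        })
        with open(cdir / "truth.json") as fh:
            truths.append(json.load(fh))
        cases.append(case)
    return bundle, cases, callsets, truths, clinical


def hrd_calls_from_reports(reports: list[CaseReport]) -> tuple[list[HrdCall], list[HrdCall]]:
    a = [HrdCall(method="classifier_a", status=r.hrd_calls.get("classifier_a", "unknown"))
         for r in reports]
    b = [HrdCall(method="classifier_b", status=r.hrd_calls.get("classifier_b", "unknown"))
         for r in reports]
    return a, b
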
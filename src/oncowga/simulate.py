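"""Synthetic tumor-cohort generator with known ground truth.

Generates every input the pipeline consumes — somatic and germline small
variants, CNA segments, SV breakends, panel-of-normals depths, quality
tracks, clinical tables and survival times — on the desk-scale toy
reference, together with a per-case truth record listing each planted
event, so every downstream stage is testable without any external data.

Background mutations are drawn from configured signature mixtures and
placed intergenically at positions matching their trinucleotide context;
actionable coding events are planted, not emergent. Survival times are
proportional-hazards exponential draws with a stage-dependent baseline (so
stage confounds marker effects) and right-censoring via last-seen episode
dates.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cna_sv import _candidate_status  # deterministic frame bookkeeping for planting
from .io import (
    ClinicalBundle,
    normalize_variant,
    write_clinical_bundle,
    write_cna_tsv,
    write_germline_vcf,
    write_somatic_vcf,
    write_sv_vcf,
)
from .reference import (
    TUMOR_TYPES,
    ReferenceBundle,
    build_toy_reference,
    cds_genomic_positions,
    write_reference_bundle,
)
from .somatic import annotate_consequence
from .trinuc import COMPLEMENT, pyrimidine_trinuc
from .types import (
    ClinVarRecord,
    CnaSegment,
    GeneModel,
    HrdCall,
    QcMetrics,
    SomaticVariant,
    StructuralVariant,
    TumorCase,
)

_OTHER_BASES = {"A": "GCT", "C": "TAG", "G": "ACT", "T": "CAG"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort structure of the programme this pipeline
    models: tumor-type mix dominated by breast and colorectal disease,
    11.9% metastatic submissions, registry staging resolving for 86.7% of
    cases overall (metastatic defaults included), 40% HRD prevalence in
    high-grade serous ovarian cancer,
    99.2% concordance between the two HRD classifiers, DPYD toxicity
    alleles in ~7.5% of participants, and a 0.37 hazard ratio for
    HRD-positive disease under platinum treatment.
    """

    n_cases: int = 300
    tumor_type_mix: dict[str, float] = field(default_factory=lambda: {
        "breast_invasive_carcinoma": 0.28,
        "colon_adenocarcinoma": 0.24,
        "skin_cutaneous_melanoma": 0.10,
        "lung_adenocarcinoma": 0.12,
        "ovarian_high_grade_serous": 0.14,
        "glioblastoma": 0.12,
    })
    mutation_count_median: dict[str, int] = field(default_factory=lambda: {
        "breast_invasive_carcinoma": 500,
        "colon_adenocarcinoma": 400,
        "skin_cutaneous_melanoma": 2000,
        "lung_adenocarcinoma": 1200,
        "ovarian_high_grade_serous": 600,
        "glioblastoma": 300,
    })
    mutation_count_sigma: float = 0.5
    signature_priors: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "breast_invasive_carcinoma": {"SBS1": 0.40, "SBS2": 0.15, "SBS13": 0.15, "SBS3": 0.30},
        "colon_adenocarcinoma": {"SBS1": 0.60, "SBS5": 0.25, "SBS18": 0.15},
        "skin_cutaneous_melanoma": {"SBS7a": 0.35, "SBS7b": 0.25, "SBS7c": 0.10, "SBS7d": 0.05, "SBS1": 0.25},
        "lung_adenocarcinoma": {"SBS4": 0.50, "SBS92": 0.10, "SBS1": 0.25, "SBS5": 0.15},
        "ovarian_high_grade_serous": {"SBS3": 0.45, "SBS1": 0.40, "SBS5": 0.15},
        "glioblastoma": {"SBS1": 0.70, "SBS5": 0.30},
    })
    mmr_prior: dict[str, float] = field(default_factory=lambda: {
        "colon_adenocarcinoma": 0.15,
    })
    mmr_signature_mix: dict[str, float] = field(default_factory=lambda: {
        "SBS6": 0.20, "SBS15": 0.12, "SBS20": 0.10, "SBS21": 0.08,
        "SBS26": 0.08, "SBS44": 0.12, "SBS1": 0.30,
    })
    hrd_prevalence: dict[str, float] = field(default_factory=lambda: {
        "ovarian_high_grade_serous": 0.40,
        "breast_invasive_carcinoma": 0.10,
    })
    hrd_default_prevalence: float = 0.02
    hrd_classifier_disagreement: float = 0.008
    purity_beta: tuple[float, float] = (3.5, 1.5)
    ploidy_values: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.1, 3.9, 1.8)
    tumor_depth: int = 80

    # per-case planting probabilities
    p_small_variant: float = 0.55
    p_offdirectory_variant: float = 0.20
    p_gain: float = 0.15
    p_loss_hom_del: float = 0.10
    p_loss_loh: float = 0.10
    p_loss_cnloh: float = 0.05
    p_loss_sv: float = 0.05
    p_fusion_inframe: float = 0.08
    p_fusion_out_of_frame: float = 0.05
    germline_frequencies: dict[str, list[tuple[str, float]]] = field(default_factory=lambda: {
        "ovarian_high_grade_serous": [("BRCA1", 0.08), ("BRCA2", 0.05)],
        "breast_invasive_carcinoma": [("BRCA1", 0.03), ("BRCA2", 0.02)],
        "colon_adenocarcinoma": [("PMS2", 0.04)],
    })
    p_dpyd: float = 0.075

    # planted filter violations per case
    n_popaf_variants: int = 3
    n_recurrent_variants: int = 2
    n_repeat_variants: int = 2
    n_noisy_indels: int = 2
    n_clean_indels: int = 1
    n_artifact_snvs: int = 3

    # panel of normals
    pon_individuals: int = 40
    pon_depth: int = 30
    pon_noise_fraction: float = 0.10
    pon_carrier_rate: float = 0.05
    n_artifact_sites: int = 40
    n_clean_pon_sites: int = 20

    # clinical tables
    p_metastatic: float = 0.119
    registry_available: float = 0.95
    registry_mismatch_rate: float = 0.05
    # Probability a registry row carries staging. Chosen so overall stage
    # availability is ~0.867 once metastatic defaults (11.9% of cases),
    # registry availability and the 365-day diagnosis-lag window are
    # combined: 0.119 + 0.881 * 0.95 * s * 0.97 = 0.867 -> s = 0.921.
    stage_best_available: float = 0.921
    stage_distribution: dict[int, float] = field(default_factory=lambda: {
        1: 0.32, 2: 0.30, 3: 0.24, 4: 0.14})
    diagnosis_lag_scale_days: float = 90.0
    p_diagnosis_out_of_window: float = 0.03
    p_qc_fail: float = 0.02
    p_pcr_amplified: float = 0.04

    # survival
    baseline_hazard_per_year: dict[int, float] = field(default_factory=lambda: {
        1: 0.06, 2: 0.12, 3: 0.25, 4: 0.60})
    hr_hrd: float = 0.37
    hr_tmb_high: float = 2.34
    p_platinum: dict[str, float] = field(default_factory=lambda: {
        "ovarian_high_grade_serous": 0.70, "breast_invasive_carcinoma": 0.30})
    p_immunotherapy: dict[str, float] = field(default_factory=lambda: {
        "skin_cutaneous_melanoma": 0.40, "lung_adenocarcinoma": 0.30})
    followup_years: tuple[float, float] = (1.0, 6.0)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["germline_frequencies"] = {
            k: [list(t) for t in v] for k, v in self.germline_frequencies.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "germline_frequencies" in data:
            data["germline_frequencies"] = {
                k: [tuple(t) for t in v] for k, v in data["germline_frequencies"].items()}
        for key in ("stage_distribution", "baseline_hazard_per_year"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        for key in ("ploidy_values", "purity_beta", "followup_years"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Context-indexed placement on the toy genome


def _context_positions(bundle: ReferenceBundle) -> dict[str, list[tuple[str, int]]]:
    """Intergenic positions indexed by pyrimidine-normalized trinucleotide."""
    cached = getattr(bundle, "_context_positions", None)
    if cached is not None:
        return cached
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in bundle.genes.values():
        spans.setdefault(g.chrom, []).append((g.start - 10, g.end + 10))
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in bundle.genome.items():
        blocked = np.zeros(len(seq) + 2, dtype=bool)
        for s, e in spans.get(chrom, []):
            blocked[max(s, 1):e + 1] = True
        for pos in range(2, len(seq)):
            if blocked[pos]:
                continue
            trinuc = seq[pos - 2:pos + 1]
            if "N" in trinuc:
                continue
            index.setdefault(pyrimidine_trinuc(trinuc), []).append((chrom, pos))
    bundle._context_positions = index
    return index


def simulate_catalog(exposures: np.ndarray, n_mutations: int,
                     bundle: ReferenceBundle, rng: np.random.Generator,
                     purity: float = 0.7, depth: int = 80
                     ) -> tuple[np.ndarray, list[SomaticVariant]]:
    """Draw a 96-context catalog and place the SNVs on the toy genome."""
    if n_mutations < 0:
        raise ValueError("n_mutations must be non-negative")
    exposures = np.asarray(exposures, dtype=float)
    if (exposures < 0).any() or abs(exposures.sum() - 1.0) > 1e-9:
        raise ValueError("exposures must be non-negative and sum to 1")
    probs = bundle.signatures.to_numpy() @ exposures
    counts = rng.multinomial(n_mutations, probs / probs.sum())
    index = _context_positions(bundle)
    vaf = max(0.05, purity / 2)
    variants: list[SomaticVariant] = []
    from .trinuc import CONTEXTS_96
    for channel, count in zip(CONTEXTS_96, counts):
        if count == 0:
            continue
        five, mid, alt_pyr, three = channel[0], channel[2], channel[4], channel[6]
        key = five + mid + three
        sites = index.get(key, [])
        if not sites:
            raise RuntimeError(f"toy genome lacks context {key}")
        for i in rng.integers(0, len(sites), size=count):
            chrom, pos = sites[i]
            ref = bundle.genome[chrom][pos - 1]
            alt = alt_pyr if ref == mid else COMPLEMENT[alt_pyr]
            total = max(10, rng.poisson(depth))
            alt_d = max(1, rng.binomial(total, vaf))
            variants.append(SomaticVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                tumor_ref_depth=total - alt_d, tumor_alt_depth=alt_d))
    return counts, variants


# ---------------------------------------------------------------------------
# Panel of normals


def simulate_pon(n_individuals: int, sites: list[tuple[str, int, str]],
                 artifact_fraction: float, rng: np.random.Generator,
                 depth: int = 30, noise_fraction: float = 0.10,
                 carrier_rate: float = 0.0
                 ) -> tuple[dict[tuple[str, int, str], list[tuple[int, int]]],
                            list[tuple[str, int, str]]]:
    """Panel depths for the given sites; returns (sites map, artifact sites).

    Artifact sites carry low-level alternate depths across most panel
    individuals; clean sites are alt-free except for occasional germline
    carriers (het-like depths) that the carrier-exclusion rule removes.
    """
    if n_individuals < 1:
        raise ValueError("need at least one panel individual")
    n_artifacts = int(round(artifact_fraction * len(sites)))
    artifact_sites = list(sites[:n_artifacts])
    table: dict[tuple[str, int, str], list[tuple[int, int]]] = {}
    for site in sites:
        is_artifact = site in set(artifact_sites)
        depths = []
        for _ in range(n_individuals):
            total = max(5, rng.poisson(depth))
            if is_artifact:
                alt = rng.binomial(total, noise_fraction)
            elif carrier_rate > 0 and rng.random() < carrier_rate:
                alt = rng.binomial(total, 0.5)
            else:
                alt = 0
            depths.append((total - alt, alt))
        table[site] = depths
    return table, artifact_sites


# ---------------------------------------------------------------------------
# Coding-event planting helpers


def _plant_coding_snv(gene: GeneModel, bundle: ReferenceBundle,
                      desired: str, rng: np.random.Generator,
                      depth: int = 80, vaf: float = 0.4) -> SomaticVariant | None:
    """Search the CDS for a substitution annotated with ``desired``."""
    positions = cds_genomic_positions(gene)
    for _ in range(300):
        pos = positions[rng.integers(3, len(positions) - 3)]
        ref = bundle.genome[gene.chrom][pos - 1]
        alt = _OTHER_BASES[ref][rng.integers(0, 3)]
        v = SomaticVariant(chrom=gene.chrom, pos=pos, ref=ref, alt=alt)
        if annotate_consequence(v, bundle) == desired:
            total = max(10, rng.poisson(depth))
            alt_d = max(1, rng.binomial(total, vaf))
            v.tumor_ref_depth, v.tumor_alt_depth = total - alt_d, alt_d
            return v
    return None


def _plant_frameshift(gene: GeneModel, bundle: ReferenceBundle,
                      rng: np.random.Generator) -> SomaticVariant:
    positions = cds_genomic_positions(gene)
    pos = sorted(positions)[len(positions) // 2]
    anchor = bundle.genome[gene.chrom][pos - 1]
    deleted = bundle.genome[gene.chrom][pos:pos + 1]
    npos, ref, alt = normalize_variant(gene.chrom, pos, anchor + deleted, anchor,
                                       bundle.genome)
    return SomaticVariant(chrom=gene.chrom, pos=npos, ref=ref, alt=alt,
                          tumor_ref_depth=40, tumor_alt_depth=40)


def _intron_midpoints(gene: GeneModel) -> list[int]:
    return [(e1 + s2) // 2 for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:])]


def _plant_fusion(up: GeneModel, down: GeneModel, want_inframe: bool,
                  sv_id: str) -> StructuralVariant | None:
    """Breakends in introns of both partners with the requested frame status."""
    up_orient = "+" if up.strand == "+" else "-"
    down_orient = "-" if down.strand == "+" else "+"
    for pu in _intron_midpoints(up):
        for pd_ in _intron_midpoints(down):
            status = _candidate_status(up, pu, up_orient, down, pd_, down_orient)
            if (status == "inframe") == want_inframe and status in ("inframe", "out_of_frame"):
                return StructuralVariant(
                    svtype="BND",
                    breakpoint_a=(up.chrom, pu, up_orient),
                    breakpoint_b=(down.chrom, pd_, down_orient),
                    sv_id=sv_id)
    return None


# ---------------------------------------------------------------------------
# Case simulation


def _exposure_vector(bundle: ReferenceBundle, prior: dict[str, float]) -> np.ndarray:
    vec = np.zeros(len(bundle.signatures.columns))
    cols = list(bundle.signatures.columns)
    for name, w in prior.items():
        vec[cols.index(name)] = w
    return vec / vec.sum()


def _intergenic_site(bundle: ReferenceBundle, rng: np.random.Generator,
                     chrom: str | None = None) -> tuple[str, int, str, str]:
    index = _context_positions(bundle)
    keys = sorted(index)
    while True:
        key = keys[rng.integers(0, len(keys))]
        sites = index[key]
        c, p = sites[rng.integers(0, len(sites))]
        if chrom is not None and c != chrom:
            continue
        ref = bundle.genome[c][p - 1]
        return c, p, ref, _OTHER_BASES[ref][rng.integers(0, 3)]


def simulate_case(bundle: ReferenceBundle, config: SimulationConfig,
                  case_index: int, rng: np.random.Generator,
                  artifact_sites: list[tuple[str, int, str]]) -> tuple[TumorCase, dict, dict]:
    """One tumor case: metadata, call sets and the truth record."""
    types = list(config.tumor_type_mix)
    weights = np.array([config.tumor_type_mix[t] for t in types], dtype=float)
    tumor_type = types[rng.choice(len(types), p=weights / weights.sum())]
    purity = float(np.clip(rng.beta(*config.purity_beta), 0.05, 1.0))
    ploidy = float(config.ploidy_values[rng.integers(0, len(config.ploidy_values))])
    case = TumorCase(
        case_id=f"CASE{case_index:04d}",
        tumor_type=tumor_type,
        sample_route="surgical_resection" if rng.random() < 0.945 else "biopsy",
        treatment_status="naive" if rng.random() < 0.93 else "post_treatment",
        sample_preservation="fresh_frozen" if rng.random() < 0.959 else "FFPE",
        purity=purity,
        ploidy=ploidy,
        sample_date=datetime.date(2016, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 1200))),
        submitted_metastatic=bool(rng.random() < config.p_metastatic),
        pcr_amplified=bool(rng.random() < config.p_pcr_amplified),
    )
    truth: dict = {"case_id": case.case_id, "tumor_type": tumor_type, "events": [],
                   "cna_eligible": purity > bundle.config.min_cna_purity}

    # --- signature exposures and background catalog ---
    mmr_deficient = rng.random() < config.mmr_prior.get(tumor_type, 0.0)
    prior = config.mmr_signature_mix if mmr_deficient else config.signature_priors[tumor_type]
    exposures = _exposure_vector(bundle, prior)
    median = config.mutation_count_median[tumor_type]
    n_mut = int(rng.lognormal(math.log(median), config.mutation_count_sigma))
    if mmr_deficient:
        n_mut *= 4  # hypermutated
    counts, variants = simulate_catalog(exposures, n_mut, bundle, rng,
                                        purity=purity, depth=config.tumor_depth)
    truth["exposures"] = dict(zip(bundle.signatures.columns, exposures.tolist()))
    truth["n_background_mutations"] = n_mut
    truth["mmr_deficient"] = mmr_deficient

    # --- HRD status and the two classifier calls ---
    p_hrd = config.hrd_prevalence.get(tumor_type, config.hrd_default_prevalence)
    hrd = rng.random() < p_hrd
    status = "positive" if hrd else "negative"
    flipped = "negative" if hrd else "positive"
    disagree = rng.random() < config.hrd_classifier_disagreement
    hrd_calls = {"classifier_a": status, "classifier_b": flipped if disagree else status}
    truth["hrd_positive"] = hrd

    genes = bundle.genes
    segments = [CnaSegment(chrom=c, start=1, end=len(seq), total_cn=ploidy,
                           minor_cn=max(0.0, round(ploidy / 2)))
                for c, seq in bundle.genome.items()]
    svs: list[StructuralVariant] = []
    used_genes: set[str] = set()

    def pick_gene(predicate) -> GeneModel | None:
        pool = sorted(g.gene for g in genes.values()
                      if predicate(g) and g.gene not in used_genes)
        if not pool:
            return None
        g = genes[pool[rng.integers(0, len(pool))]]
        used_genes.add(g.gene)
        return g

    # --- planted directory small variant ---
    if rng.random() < config.p_small_variant:
        g = pick_gene(lambda g: tumor_type in g.directory_indications
                      and "small_variant" in g.directory_variant_classes)
        if g is not None:
            desired = "stop_gained" if g.is_tsg and not g.is_oncogene else "missense_variant"
            v = _plant_coding_snv(g, bundle, desired, rng)
            if v is not None:
                variants.append(v)
                truth["events"].append({"kind": "small_variant", "gene": g.gene,
                                        "consequence": desired, "indicated": True,
                                        "chrom": v.chrom, "pos": v.pos,
                                        "ref": v.ref, "alt": v.alt, "clean": True})
    if rng.random() < config.p_offdirectory_variant:
        g = pick_gene(lambda g: tumor_type not in g.directory_indications
                      and "small_variant" in g.directory_variant_classes)
        if g is not None:
            v = _plant_coding_snv(g, bundle, "missense_variant", rng)
            if v is not None:
                variants.append(v)
                truth["events"].append({"kind": "small_variant", "gene": g.gene,
                                        "consequence": "missense_variant",
                                        "indicated": False, "chrom": v.chrom,
                                        "pos": v.pos, "ref": v.ref, "alt": v.alt,
                                        "clean": True})

    eligible = truth["cna_eligible"]

    def add_segment(g: GeneModel, total: float, minor: float | None) -> None:
        segments.append(CnaSegment(chrom=g.chrom, start=g.start - 50, end=g.end + 50,
                                   total_cn=total, minor_cn=minor))

    # --- CNA gains and losses ---
    if rng.random() < config.p_gain:
        g = pick_gene(lambda g: g.role == "oncogene")
        if g is not None:
            cn = math.ceil(2 * ploidy) + int(rng.integers(0, 3))
            add_segment(g, float(cn), 1.0)
            truth["events"].append({"kind": "cna_gain", "gene": g.gene, "cn": cn,
                                    "indicated": tumor_type in g.directory_indications
                                    and "cna" in g.directory_variant_classes,
                                    "clean": eligible})
    for kind, prob in (("hom_del", config.p_loss_hom_del),
                       ("loh", config.p_loss_loh),
                       ("cnloh", config.p_loss_cnloh),
                       ("sv_disrupt", config.p_loss_sv)):
        if rng.random() >= prob:
            continue
        g = pick_gene(lambda g: g.role == "tsg")
        if g is None:
            continue
        scenario = {"hom_del": 1, "loh": 2, "cnloh": 2, "sv_disrupt": 3}[kind]
        companion = None
        if kind == "hom_del":
            add_segment(g, 0.0, 0.0)
        else:
            companion = _plant_coding_snv(g, bundle, "missense_variant", rng)
            if companion is None:
                continue
            variants.append(companion)
            if kind == "loh":
                add_segment(g, 1.0, 0.0)
            elif kind == "cnloh":
                add_segment(g, ploidy, 0.0)
            else:
                mid = (g.cds_start + g.cds_end) // 2
                svs.append(StructuralVariant(
                    svtype="BND", breakpoint_a=(g.chrom, mid, "+"),
                    breakpoint_b=(g.chrom, min(mid + 5000, len(bundle.genome[g.chrom]) - 10), "-"),
                    sv_id=f"{case.case_id}_disrupt_{g.gene}"))
        truth["events"].append({"kind": "cna_loss", "gene": g.gene,
                                "scenario": scenario, "mechanism": kind,
                                "indicated": tumor_type in g.directory_indications
                                and "cna" in g.directory_variant_classes,
                                "clean": eligible})

    # --- fusions ---
    pairs = [("LMNA", "NTRK1"), ("EML4", "ALK")]
    if rng.random() < config.p_fusion_inframe:
        up, down = pairs[rng.integers(0, len(pairs))]
        sv = _plant_fusion(genes[up], genes[down], True, f"{case.case_id}_fus")
        if sv is not None:
            svs.append(sv)
            truth["events"].append({"kind": "fusion", "upstream": up, "downstream": down,
                                    "status": "inframe", "gene": down, "clean": True})
    if rng.random() < config.p_fusion_out_of_frame:
        up, down = pairs[rng.integers(0, len(pairs))]
        sv = _plant_fusion(genes[up], genes[down], False, f"{case.case_id}_oof")
        if sv is not None:
            svs.append(sv)
            truth["events"].append({"kind": "fusion", "upstream": up, "downstream": down,
                                    "status": "out_of_frame", "gene": down, "clean": False})

    # --- germline findings and pharmacogenomics ---
    germline: list[SomaticVariant] = []
    for gene_name, freq in config.germline_frequencies.get(tumor_type, []):
        if rng.random() >= freq:
            continue
        g = genes[gene_name]
        if rng.random() < 0.5:
            v = _plant_coding_snv(g, bundle, "missense_variant", rng, vaf=0.5)
            if v is None:
                continue
            bundle.clinvar[v.key] = ClinVarRecord(classification="pathogenic",
                                                  review_stars=int(rng.integers(2, 4)))
            basis = "clinvar"
        else:
            v = _plant_frameshift(g, bundle, rng)
            basis = "predicted_truncating"
        germline.append(v)
        truth["events"].append({"kind": "germline", "gene": gene_name, "basis": basis,
                                "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                                "alt": v.alt, "clean": True})
    # benign germline noise: common missense without ClinVar support
    noise = _plant_coding_snv(genes["VHL"], bundle, "missense_variant", rng, vaf=0.5)
    if noise is not None and rng.random() < 0.3:
        germline.append(noise)
    if rng.random() < config.p_dpyd:
        key = sorted(bundle.pgx_alleles)[rng.integers(0, len(bundle.pgx_alleles))]
        chrom, pos, ref, alt = key
        germline.append(SomaticVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                       tumor_ref_depth=30, tumor_alt_depth=30))
        truth["events"].append({"kind": "pgx", "gene": "DPYD",
                                "allele": bundle.pgx_alleles[key][1], "clean": True})

    # --- planted filter violations (labeled, not clean) ---
    for _ in range(config.n_popaf_variants):
        c, p, ref, alt = _intergenic_site(bundle, rng)
        bundle.population_af[(c, p, ref, alt)] = float(rng.uniform(0.02, 0.3))
        variants.append(SomaticVariant(chrom=c, pos=p, ref=ref, alt=alt,
                                       tumor_ref_depth=40, tumor_alt_depth=40))
        truth["events"].append({"kind": "filtered_variant", "flag": "pop_af",
                                "chrom": c, "pos": p, "ref": ref, "alt": alt,
                                "clean": False})
    for _ in range(config.n_recurrent_variants):
        c, p, ref, alt = _intergenic_site(bundle, rng)
        bundle.cohort_recurrence[(c, p, ref, alt)] = float(rng.uniform(0.06, 0.3))
        variants.append(SomaticVariant(chrom=c, pos=p, ref=ref, alt=alt,
                                       tumor_ref_depth=40, tumor_alt_depth=40))
        truth["events"].append({"kind": "filtered_variant", "flag": "recurrent",
                                "chrom": c, "pos": p, "ref": ref, "alt": alt,
                                "clean": False})
    for _ in range(config.n_repeat_variants):
        rc, rs, re_ = bundle.repeats[rng.integers(0, len(bundle.repeats))]
        p = int(rng.integers(rs + 2, re_ - 2))
        ref = bundle.genome[rc][p - 1]
        alt = _OTHER_BASES[ref][rng.integers(0, 3)]
        variants.append(SomaticVariant(chrom=rc, pos=p, ref=ref, alt=alt,
                                       tumor_ref_depth=40, tumor_alt_depth=40))
        truth["events"].append({"kind": "filtered_variant", "flag": "simple_repeat",
                                "chrom": rc, "pos": p, "ref": ref, "alt": alt,
                                "clean": False})
    for noisy in ([True] * config.n_noisy_indels + [False] * config.n_clean_indels):
        c, p, ref, _ = _intergenic_site(bundle, rng)
        nxt = bundle.genome[c][p]
        p, nref, nalt = normalize_variant(c, p, ref + nxt, ref, bundle.genome)
        v = SomaticVariant(chrom=c, pos=p, ref=nref, alt=nalt,
                           tumor_ref_depth=40, tumor_alt_depth=40)
        variants.append(v)
        if noisy:
            lo, hi = max(0, p - 30), min(len(bundle.genome[c]), p + 30)
            bundle.quality_fail[c][lo:hi] = 0.25
            truth["events"].append({"kind": "filtered_variant", "flag": "noisy_indel",
                                    "chrom": c, "pos": p, "ref": v.ref, "alt": v.alt,
                                    "clean": False})
    for _ in range(config.n_artifact_snvs):
        c, p, alt = artifact_sites[rng.integers(0, len(artifact_sites))]
        ref = bundle.genome[c][p - 1]
        total = max(10, rng.poisson(config.tumor_depth))
        alt_d = max(1, rng.binomial(total, config.pon_noise_fraction))
        variants.append(SomaticVariant(chrom=c, pos=p, ref=ref, alt=alt,
                                       tumor_ref_depth=total - alt_d,
                                       tumor_alt_depth=alt_d))
        truth["events"].append({"kind": "filtered_variant", "flag": "pon_artifact",
                                "chrom": c, "pos": p, "ref": ref, "alt": alt,
                                "clean": False})

    # --- QC metrics ---
    fails = rng.random() < config.p_qc_fail
    qc = QcMetrics(
        normal_yield_gb=float(rng.uniform(60, 80)) if fails else float(rng.uniform(90, 140)),
        tumor_yield_gb=float(rng.uniform(215, 300)),
        normal_autosome_cov15_frac=float(rng.uniform(0.955, 0.999)),
        normal_contamination=float(rng.uniform(0.0, 0.02)),
        tumor_contamination=float(rng.uniform(0.0, 0.02)),
        pair_concordant=True,
    )
    truth["qc_fail"] = fails

    callsets = {
        "somatic": variants,
        "germline": germline,
        "cna": segments,
        "sv": svs,
        "qc": qc,
        "hrd_calls": hrd_calls,
        "catalog_background": counts,
    }
    return case, callsets, truth


# ---------------------------------------------------------------------------
# Clinical tables and survival


_ICD_BY_TYPE = {
    "breast_invasive_carcinoma": "C50.9",
    "colon_adenocarcinoma": "C18.4",
    "skin_cutaneous_melanoma": "C43.5",
    "lung_adenocarcinoma": "C34.1",
    "ovarian_high_grade_serous": "C56.0",
    "glioblastoma": "C71.9",
}
_OPCODE_BY_TYPE = {
    "breast_invasive_carcinoma": "OP_BRE",
    "colon_adenocarcinoma": "OP_COL",
    "skin_cutaneous_melanoma": "OP_MEL",
    "lung_adenocarcinoma": "OP_LUN",
    "ovarian_high_grade_serous": "OP_OVA",
    "glioblastoma": "OP_GBM",
}
_ROMAN_BY_STAGE = {1: "I", 2: "II", 3: "III", 4: "IV"}
_DUKES_BY_STAGE = {1: "A", 2: "B", 3: "C", 4: "D"}


def _draw_stage(config: SimulationConfig, rng: np.random.Generator) -> int:
    stages = sorted(config.stage_distribution)
    p = np.array([config.stage_distribution[s] for s in stages], dtype=float)
    return int(stages[rng.choice(len(stages), p=p / p.sum())])


def simulate_clinical_tables(cases: list[TumorCase], truths: list[dict],
                             config: SimulationConfig, rng: np.random.Generator,
                             tmb_high: dict[str, bool] | None = None
                             ) -> ClinicalBundle:
    """Registry/episode/treatment/mortality tables plus survival truth.

    Survival times are exponential with a stage-dependent baseline hazard
    multiplied by the HRD hazard ratio for HRD-positive cases and by the
    high-TMB hazard ratio for hypermutated melanoma; censoring happens at
    the end of a uniform follow-up window, recorded as a final episode.
    """
    registry_rows, episode_rows, treatment_rows, death_rows = [], [], [], []
    for case, truth in zip(cases, truths):
        true_stage = 4 if case.submitted_metastatic else _draw_stage(config, rng)
        truth["true_stage"] = true_stage

        has_registry = rng.random() < config.registry_available
        mismatch = has_registry and rng.random() < config.registry_mismatch_rate
        truth["registry_match"] = has_registry and not mismatch
        expected_stage: int | None = 4 if case.submitted_metastatic else None
        diagnosis_date = None
        if has_registry:
            if rng.random() < config.p_diagnosis_out_of_window:
                lag = int(rng.integers(370, 600))
            else:
                lag = min(360, int(rng.exponential(config.diagnosis_lag_scale_days)))
            diagnosis_date = case.sample_date - datetime.timedelta(days=lag)
            reg_type = case.tumor_type
            if mismatch:
                others = [t for t in TUMOR_TYPES if t != case.tumor_type]
                reg_type = others[rng.integers(0, len(others))]
            stage_known = rng.random() < config.stage_best_available
            row = {"participant_id": case.case_id, "diagnosis_date": diagnosis_date,
                   "icd10_site": _ICD_BY_TYPE[reg_type], "morphology_code": "8140/3",
                   "behavior": "malignant", "stage_best": "", "figo_stage": "",
                   "dukes_stage": ""}
            if stage_known:
                row["stage_best"] = f"{true_stage}{'a' if rng.random() < 0.5 else ''}"
                row["figo_stage"] = _ROMAN_BY_STAGE[true_stage]
                row["dukes_stage"] = _DUKES_BY_STAGE[true_stage]
                if expected_stage is None and lag < 365:
                    expected_stage = true_stage
            registry_rows.append(row)
        truth["expected_stage"] = expected_stage
        truth["expected_linkage"] = "registry_confirmed" if truth["registry_match"] else None

        # episodes: always at least one cancer episode near the sample date
        n_episodes = int(rng.integers(1, 4))
        for _ in range(n_episodes):
            offset = int(rng.integers(-60, 120))
            episode_rows.append({
                "participant_id": case.case_id,
                "appointment_date": case.sample_date + datetime.timedelta(days=offset),
                "primary_diagnosis_icd10": _ICD_BY_TYPE[case.tumor_type],
                "operation_codes": _OPCODE_BY_TYPE[case.tumor_type]
                if rng.random() < 0.3 else "",
            })
        if truth["expected_linkage"] is None:
            truth["expected_linkage"] = "hes_confirmed"

        # treatments
        if rng.random() < config.p_platinum.get(case.tumor_type, 0.05):
            treatment_rows.append({"participant_id": case.case_id,
                                   "treatment_date": case.sample_date + datetime.timedelta(days=30),
                                   "treatment_class": "platinum", "drug": "carboplatin"})
        if rng.random() < config.p_immunotherapy.get(case.tumor_type, 0.02):
            treatment_rows.append({"participant_id": case.case_id,
                                   "treatment_date": case.sample_date + datetime.timedelta(days=45),
                                   "treatment_class": "immunotherapy", "drug": "pembrolizumab"})

        # survival
        origin = diagnosis_date or case.sample_date
        rate = config.baseline_hazard_per_year[true_stage] / 365.25
        if truth.get("hrd_positive"):
            rate *= config.hr_hrd
        if tmb_high and tmb_high.get(case.case_id):
            rate *= config.hr_tmb_high
        t_event = float(rng.exponential(1.0 / rate))
        censor = float(rng.uniform(*config.followup_years)) * 365.25
        if t_event <= censor:
            death_rows.append({"participant_id": case.case_id,
                               "death_date": origin + datetime.timedelta(days=int(t_event))})
            truth["survival_days"], truth["death_observed"] = int(t_event), True
        else:
            episode_rows.append({
                "participant_id": case.case_id,
                "appointment_date": origin + datetime.timedelta(days=int(censor)),
                "primary_diagnosis_icd10": _ICD_BY_TYPE[case.tumor_type],
                "operation_codes": "",
            })
            truth["survival_days"], truth["death_observed"] = int(censor), False
        truth["survival_origin"] = origin.isoformat()

    from .io import DEATH_COLUMNS, EPISODE_COLUMNS, REGISTRY_COLUMNS, TREATMENT_COLUMNS
    return ClinicalBundle(
        registry=pd.DataFrame(registry_rows, columns=REGISTRY_COLUMNS),
        episodes=pd.DataFrame(episode_rows, columns=EPISODE_COLUMNS),
        treatments=pd.DataFrame(treatment_rows, columns=TREATMENT_COLUMNS),
        deaths=pd.DataFrame(death_rows, columns=DEATH_COLUMNS),
    )


def simulate_survival_dataset(n: int, true_hr: float, rng: np.random.Generator,
                              censoring_years: tuple[float, float] = (1.0, 6.0),
                              baseline: dict[int, float] | None = None
                              ) -> pd.DataFrame:
    """Stage-confounded two-arm survival data with a known hazard ratio.

    Marker prevalence rises with stage, and so does the baseline hazard, so
    the crude HR is biased away from ``true_hr``; a stage-corrected model
    recovers it.
    """
    baseline = baseline or {1: 0.06, 2: 0.12, 3: 0.25, 4: 0.60}
    stages = rng.choice([1, 2, 3, 4], size=n, p=[0.3, 0.3, 0.25, 0.15])
    p_marker = 0.2 + 0.12 * (stages - 1)
    marker = rng.random(n) < p_marker
    rate = np.array([baseline[s] for s in stages]) / 365.25
    rate = rate * np.where(marker, true_hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(*censoring_years, size=n) * 365.25
    return pd.DataFrame({
        "time": np.minimum(t_event, censor),
        "event": (t_event <= censor).astype(int),
        "group": np.where(marker, "marker_positive", "marker_negative"),
        "stage": stages,
    })


# ---------------------------------------------------------------------------
# Cohort orchestration


def _jsonable(obj):
    """Recursively convert numpy scalars and dates for JSON output."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, (datetime.date, datetime.datetime)):
        return obj.isoformat()
    return obj


@dataclass
class SyntheticCohort:
    bundle: ReferenceBundle
    cases: list[TumorCase]
    callsets: list[dict]
    truths: list[dict]
    clinical: ClinicalBundle
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int = 0) -> SyntheticCohort:
    """Generate a full cohort; a fixed seed gives identical output."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    bundle = build_toy_reference()

    site_pool = []
    seen = set()
    while len(site_pool) < config.n_artifact_sites + config.n_clean_pon_sites:
        c, p, ref, alt = _intergenic_site(bundle, rng)
        if (c, p) not in seen:
            seen.add((c, p))
            site_pool.append((c, p, alt))
    frac = config.n_artifact_sites / len(site_pool)
    pon_sites, artifact_sites = simulate_pon(
        config.pon_individuals, site_pool, frac, rng,
        depth=config.pon_depth, noise_fraction=config.pon_noise_fraction,
        carrier_rate=config.pon_carrier_rate)
    bundle.pon.sites = pon_sites
    bundle.pon.default_ref_depth = config.pon_individuals * config.pon_depth

    cases, callsets, truths = [], [], []
    for i in range(config.n_cases):
        case, cs, truth = simulate_case(bundle, config, i, rng, artifact_sites)
        cases.append(case)
        callsets.append(cs)
        truths.append(truth)

    # high-TMB flag for the survival generator: hypermutated melanoma
    melanoma_counts = {c.case_id: t["n_background_mutations"]
                       for c, t in zip(cases, truths)
                       if c.tumor_type == "skin_cutaneous_melanoma"}
    if melanoma_counts:
        cutoff = float(np.quantile(list(melanoma_counts.values()), 0.75))
        tmb_high = {cid: n >= cutoff for cid, n in melanoma_counts.items()}
    else:
        tmb_high = {}
    clinical = simulate_clinical_tables(cases, truths, config, rng, tmb_high)
    return SyntheticCohort(bundle=bundle, cases=cases, callsets=callsets,
                           truths=truths, clinical=clinical, config=config)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Serialize a cohort to the on-disk layout the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_reference_bundle(cohort.bundle, outdir / "reference")
    write_clinical_bundle(cohort.clinical, outdir / "clinical")
    contigs = {c: len(s) for c, s in cohort.bundle.genome.items()}

    case_rows = []
    for case, cs, truth in zip(cohort.cases, cohort.callsets, cohort.truths):
        cdir = outdir / "cases" / case.case_id
        cdir.mkdir(parents=True, exist_ok=True)
        write_somatic_vcf(cs["somatic"], cdir / "somatic.vcf", contigs)
        write_germline_vcf(cs["germline"], cdir / "germline.vcf", contigs)
        write_cna_tsv(cs["cna"], cdir / "cna.tsv")
        write_sv_vcf(cs["sv"], cdir / "sv.vcf", contigs, cohort.bundle.genome)
        with open(cdir / "truth.json", "w") as fh:
            json.dump(_jsonable(truth), fh, indent=1)
        qc = cs["qc"]
        case_rows.append({
            "case_id": case.case_id, "tumor_type": case.tumor_type,
            "sample_route": case.sample_route,
            "treatment_status": case.treatment_status,
            "sample_preservation": case.sample_preservation,
            "purity": case.purity, "ploidy": case.ploidy,
            "sample_date": case.sample_date.isoformat(),
            "submitted_metastatic": int(case.submitted_metastatic),
            "pcr_amplified": int(case.pcr_amplified),
            "normal_yield_gb": qc.normal_yield_gb,
            "tumor_yield_gb": qc.tumor_yield_gb,
            "normal_autosome_cov15_frac": qc.normal_autosome_cov15_frac,
            "normal_contamination": qc.normal_contamination,
            "tumor_contamination": qc.tumor_contamination,
            "pair_concordant": int(qc.pair_concordant),
            "hrd_classifier_a": cs["hrd_calls"]["classifier_a"],
            "hrd_classifier_b": cs["hrd_calls"]["classifier_b"],
        })
    pd.DataFrame(case_rows).to_csv(outdir / "cases.tsv", sep="\t", index=False)
    cohort.config.to_yaml(outdir / "simulation.yaml")
    return outdir


def hrd_call_lists(cohort: SyntheticCohort) -> tuple[list[HrdCall], list[HrdCall]]:
    a = [HrdCall(method="classifier_a", status=cs["hrd_calls"]["classifier_a"])
         for cs in cohort.callsets]
    b = [HrdCall(method="classifier_b", status=cs["hrd_calls"]["classifier_b"])
         for cs in cohort.callsets]
    return a, b
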
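"""Somatic small-variant interpretation.

Two responsibilities: consequence annotation on canonical transcripts
(restricted to the curated consequence vocabulary) and the five-rule
post-calling filter cascade applied on top of the caller's own filters:

1. population germline allele frequency above 1%;
2. cohort somatic recurrence above 5%;
3. overlap with a simple-repeat interval;
4. indels in noisy regions where at least 10% of base calls in a +/-50 bp
   window failed quality;
5. SNVs whose tumor allele-depth ratio is not significantly different from
   the panel-of-normals ratio (Fisher's exact test Phred score below 50).

Flagged variants are labeled, never deleted; the high-confidence subset
(used for TMB and mutational catalogs) excludes any flagged variant.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .config import PipelineConfig
from .reference import ReferenceBundle, cds_genomic_positions, transcript_base
from .trinuc import COMPLEMENT
from .types import FisherPhredResult, GeneModel, PanelOfNormals, SomaticVariant

# ---------------------------------------------------------------------------
# Consequence annotation

_CDS_INDEX_CACHE: dict[str, dict[int, int]] = {}


def _cds_index(gene: GeneModel) -> dict[int, int]:
    cached = _CDS_INDEX_CACHE.get(gene.transcript_id)
    if cached is None:
        cached = {p: i for i, p in enumerate(cds_genomic_positions(gene))}
        _CDS_INDEX_CACHE[gene.transcript_id] = cached
    return cached


def _intron_splice_class(gene: GeneModel, lo: int, hi: int) -> str | None:
    """Splice class for an intronic interval [lo, hi] (donor > acceptor > region)."""
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        if hi <= e1 or lo >= s2:
            continue
        ilo, ihi = e1 + 1, s2 - 1
        a, b = max(lo, ilo), min(hi, ihi)
        if a > b:
            continue
        d_left = (a - e1, b - e1)      # distance range into intron from the left exon
        d_right = (s2 - b, s2 - a)     # ... from the right exon
        donor, acceptor = (d_left, d_right) if gene.strand == "+" else (d_right, d_left)
        if donor[0] <= 2:
            return "splice_donor_variant"
        if acceptor[0] <= 2:
            return "splice_acceptor_variant"
        if d_left[0] <= 8 or d_right[0] <= 8:  # 3-8 bp intronic flank
            return "splice_region_variant"
    return None


def _exonic_splice_region(gene: GeneModel, lo: int, hi: int) -> bool:
    """True if [lo, hi] lies within the 3 exonic bases flanking a junction."""
    for i, (s, e) in enumerate(gene.exons):
        if hi < s or lo > e:
            continue
        if i > 0 and lo - s <= 2:
            return True
        if i < len(gene.exons) - 1 and e - hi <= 2:
            return True
    return False


def _in_exon(gene: GeneModel, lo: int, hi: int) -> bool:
    return any(lo <= e and hi >= s for s, e in gene.exons)


def _snv_consequence(variant: SomaticVariant, gene: GeneModel,
                     genome: dict[str, str]) -> str | None:
    pos, alt = variant.pos, variant.alt
    idx = _cds_index(gene).get(pos)
    if idx is not None:
        positions = cds_genomic_positions(gene)
        codon_i, within = divmod(idx, 3)
        codon_pos = positions[3 * codon_i: 3 * codon_i + 3]
        ref_codon = "".join(transcript_base(genome, gene, p) for p in codon_pos)
        alt_base = COMPLEMENT[alt] if gene.strand == "-" else alt
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
        if codon_i == 0:
            if alt_codon != "ATG":
                return "start_lost"
            return None
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == "*" and ref_aa != "*":
            return "stop_gained"
        if ref_aa == "*" and alt_aa != "*":
            return "stop_lost"
        if ref_aa != alt_aa:
            return "missense_variant"
        return "splice_region_variant" if _exonic_splice_region(gene, pos, pos) else None
    if _in_exon(gene, pos, pos):  # UTR
        return "splice_region_variant" if _exonic_splice_region(gene, pos, pos) else None
    return _intron_splice_class(gene, pos, pos)


def _indel_consequence(variant: SomaticVariant, gene: GeneModel) -> str | None:
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    net = len(alt) - len(ref)
    if len(ref) > 1:  # deletion / complex: affected reference bases after the anchor
        lo, hi = pos + 1, pos + len(ref) - 1
    else:  # pure insertion between pos and pos+1
        lo, hi = pos, pos + 1
    cds = _cds_index(gene)
    if any(p in cds for p in range(lo, hi + 1)):
        if net % 3 != 0:
            return "frameshift_variant"
        if net > 0:
            return "inframe_insertion"
        if net < 0:
            return "inframe_deletion"
        return "missense_variant"  # balanced substitution block
    if _in_exon(gene, lo, hi):
        return "splice_region_variant" if _exonic_splice_region(gene, lo, hi) else None
    return _intron_splice_class(gene, lo, hi)


def annotate_consequence(variant: SomaticVariant, bundle: ReferenceBundle) -> str | None:
    """Consequence on the canonical transcript, or None if not reportable.

    Returns one of the curated consequence types; variants outside every
    transcript, deep intronic variants and synonymous changes return None.
    """
    gene = bundle.gene_at(variant.chrom, variant.pos)
    if gene is None:
        return None
    if variant.vtype == "SNV":
        return _snv_consequence(variant, gene, bundle.genome)
    return _indel_consequence(variant, gene)


def annotate_variants(variants: list[SomaticVariant], bundle: ReferenceBundle) -> None:
    """Attach gene, transcript and consequence in place."""
    for v in variants:
        gene = bundle.gene_at(v.chrom, v.pos)
        if gene is None:
            continue
        v.gene = gene.gene
        v.transcript_id = gene.transcript_id
        v.consequence = annotate_consequence(v, bundle)


# ---------------------------------------------------------------------------
# Panel-of-normals Fisher / Phred artifact test


@lru_cache(maxsize=200_000)
def _fisher_p(tumor_ref: int, tumor_alt: int, panel_ref: int, panel_alt: int,
              alternative: str) -> float:
    table = [[tumor_ref, tumor_alt], [panel_ref, panel_alt]]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def phred_from_p(p: float) -> float:
    return -10.0 * math.log10(max(p, 1e-300))


def aggregate_panel_depths(pon: PanelOfNormals, site: tuple[str, int, str],
                           carrier_min_alt_fraction: float = 0.3) -> tuple[int, int]:
    """Sum panel allele depths over non-carrier individuals at a site.

    Individuals whose alt fraction is at least ``carrier_min_alt_fraction``
    are treated as germline carriers of the alternate allele and excluded;
    low-level noise depths from the remaining individuals are what the test
    compares against. Sites absent from the panel contribute the configured
    default reference depth and zero alt depth.
    """
    depths = pon.sites.get(site)
    if depths is None:
        return pon.default_ref_depth, 0
    ref_sum = alt_sum = 0
    for r, a in depths:
        total = r + a
        if total > 0 and a / total >= carrier_min_alt_fraction:
            continue
        ref_sum += r
        alt_sum += a
    return ref_sum, alt_sum


def pon_fisher_phred(tumor_ref: int, tumor_alt: int, pon: PanelOfNormals,
                     site: tuple[str, int, str],
                     config: PipelineConfig | None = None) -> FisherPhredResult:
    """Fisher's exact test of tumor allele-depth ratio against the panel.

    A low Phred score means the tumor ratio resembles the panel's noise
    ratio at this site, i.e. a likely systematic mapping/calling artifact.
    """
    cfg = config or PipelineConfig()
    if tumor_ref < 0 or tumor_alt < 0:
        raise ValueError("tumor depths must be non-negative")
    panel_ref, panel_alt = aggregate_panel_depths(pon, site, cfg.pon_carrier_min_alt_fraction)
    p = _fisher_p(tumor_ref, tumor_alt, panel_ref, panel_alt, cfg.pon_fisher_alternative)
    return FisherPhredResult(
        p_value=p, phred=phred_from_p(p),
        table=((tumor_ref, tumor_alt), (panel_ref, panel_alt)),
    )


# ---------------------------------------------------------------------------
# Noisy-window rule for indels


def noisy_window_fraction(chrom: str, pos: int, quality_fail: dict[str, np.ndarray],
                          radius: int = 50,
                          depth: dict[str, np.ndarray] | None = None) -> float:
    """Fraction of base calls failed in the window [pos-radius, pos+radius].

    The window is truncated at contig ends. With no depth track, positions
    carry equal base-call weight.
    """
    track = quality_fail[chrom]
    lo = max(pos - radius, 1)
    hi = min(pos + radius, len(track))
    window = track[lo - 1:hi]
    if depth is not None:
        w = depth[chrom][lo - 1:hi]
        total = w.sum()
        return float((window * w).sum() / total) if total > 0 else 0.0
    return float(window.mean()) if len(window) else 0.0


# ---------------------------------------------------------------------------
# Filter cascade


def apply_somatic_filters(variants: list[SomaticVariant], bundle: ReferenceBundle
                          ) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Set filter flags on each variant; return (all, high-confidence).

    Rules are independent and additive, so the outcome does not depend on
    evaluation order. Flagged variants are retained and labeled.
    """
    cfg = bundle.config
    for v in variants:
        if v.population_af == 0.0:
            v.population_af = bundle.population_af.get(v.key, 0.0)
        if v.cohort_recurrence == 0.0:
            v.cohort_recurrence = bundle.cohort_recurrence.get(v.key, 0.0)
        if v.population_af > cfg.max_population_af:
            v.filter_flags.add("pop_af")
        if v.cohort_recurrence > cfg.max_cohort_recurrence:
            v.filter_flags.add("recurrent")
        if bundle.in_repeat(v.chrom, v.pos, v.pos + len(v.ref) - 1):
            v.filter_flags.add("simple_repeat")
        if v.vtype == "indel":
            frac = noisy_window_fraction(v.chrom, v.pos, bundle.quality_fail,
                                         radius=cfg.noisy_window_radius)
            if frac >= cfg.noisy_window_min_fraction:
                v.filter_flags.add("noisy_indel")
        else:
            result = pon_fisher_phred(v.tumor_ref_depth, v.tumor_alt_depth,
                                      bundle.pon, (v.chrom, v.pos, v.alt), cfg)
            if result.phred < cfg.pon_min_phred:
                v.filter_flags.add("pon_artifact")
    high_confidence = [v for v in variants if v.is_high_confidence]
    return variants, high_confidence
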
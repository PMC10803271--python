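"""Copy-number and structural-variant actionability.

Gains in oncogenes are reported when the total copy number reaches twice
the overall tumor ploidy. Losses in tumor suppressors are reported under
three scenarios: (1) homozygous deletion (CN = 0); (2) LOH (CN = 1) or
copy-neutral LOH together with a nonsynonymous somatic small variant;
(3) an SV breakpoint disrupting the coding region together with a
nonsynonymous small variant. Cases with tumor purity of 30% or less are
ineligible for CNA actionability.

Fusion assessment walks both partner transcripts: a junction is in frame
when the coding phase (cumulative CDS length, mod 3) is preserved across
it; out-of-frame and untranscribed events are discarded; events with a
breakpoint in the downstream partner's 5'UTR, or an exonic breakpoint that
splits a codon, are ambiguous and reportable.
"""

from __future__ import annotations

from .config import PipelineConfig
from .reference import ReferenceBundle, cds_genomic_positions
from .types import (
    PROTEIN_ALTERING_CONSEQUENCES,
    CnaFinding,
    CnaSegment,
    FusionAssessment,
    GeneModel,
    SomaticVariant,
    StructuralVariant,
    TumorCase,
)

_CN_ZERO_TOL = 1e-6


def cna_eligible(case: TumorCase, config: PipelineConfig | None = None) -> bool:
    cfg = config or PipelineConfig()
    return case.purity > cfg.min_cna_purity


def _overlapping(gene: GeneModel, segments: list[CnaSegment]) -> list[CnaSegment]:
    return [s for s in segments if s.overlaps(gene.chrom, gene.start, gene.end)]


def _has_nonsynonymous(gene: GeneModel, variants: list[SomaticVariant]) -> bool:
    return any(v.gene == gene.gene and v.consequence in PROTEIN_ALTERING_CONSEQUENCES
               for v in variants)


def _disrupts_cds(gene: GeneModel, svs: list[StructuralVariant]) -> bool:
    for sv in svs:
        for chrom, pos, _ in (sv.breakpoint_a, sv.breakpoint_b):
            if chrom == gene.chrom and gene.cds_start < pos < gene.cds_end:
                return True
    return False


def classify_gain(gene: GeneModel, segment: CnaSegment, case: TumorCase,
                  config: PipelineConfig | None = None) -> CnaFinding | None:
    """Oncogene gain: CN at least ``gain_multiplier`` times the ploidy."""
    cfg = config or PipelineConfig()
    if case.ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if not gene.is_oncogene or not segment.overlaps(gene.chrom, gene.start, gene.end):
        return None
    if not cna_eligible(case, cfg):
        return CnaFinding(gene=gene.gene, kind="gain", eligible=False,
                          reason=f"tumor purity {case.purity:.2f} not above {cfg.min_cna_purity:.2f}")
    if segment.total_cn >= cfg.gain_multiplier * case.ploidy:
        return CnaFinding(gene=gene.gene, kind="gain",
                          reason=f"CN {segment.total_cn:g} >= {cfg.gain_multiplier:g}x ploidy {case.ploidy:g}")
    return None


def classify_loss(gene: GeneModel, segments: list[CnaSegment],
                  small_variants: list[SomaticVariant],
                  svs: list[StructuralVariant], case: TumorCase,
                  config: PipelineConfig | None = None) -> CnaFinding | None:
    """Tumor-suppressor loss under scenarios 1 > 2 > 3 (first match wins)."""
    cfg = config or PipelineConfig()
    if not gene.is_tsg:
        return None
    overlapping = _overlapping(gene, segments)
    if not cna_eligible(case, cfg):
        if overlapping or _disrupts_cds(gene, svs):
            return CnaFinding(gene=gene.gene, kind="loss", eligible=False,
                              reason=f"tumor purity {case.purity:.2f} not above {cfg.min_cna_purity:.2f}")
        return None
    if any(s.total_cn <= _CN_ZERO_TOL for s in overlapping):
        return CnaFinding(gene=gene.gene, kind="loss", scenario=1,
                          reason="homozygous deletion (CN = 0)")
    nonsyn = _has_nonsynonymous(gene, small_variants)
    if nonsyn:
        for s in overlapping:
            loh = abs(s.total_cn - 1.0) <= _CN_ZERO_TOL
            cn_loh = (s.minor_cn is not None and abs(s.minor_cn) <= _CN_ZERO_TOL
                      and abs(s.total_cn - case.ploidy) <= cfg.cn_neutral_tolerance)
            if loh or cn_loh:
                return CnaFinding(gene=gene.gene, kind="loss", scenario=2,
                                  reason="LOH or copy-neutral LOH with nonsynonymous small variant")
        if _disrupts_cds(gene, svs):
            return CnaFinding(gene=gene.gene, kind="loss", scenario=3,
                              reason="SV disrupting CDS with nonsynonymous small variant")
    return None


# ---------------------------------------------------------------------------
# Fusion frame assessment


def _upstream_compatible(gene: GeneModel, orient: str) -> bool:
    # the retained piece must contain the transcription start
    return (gene.strand == "+") == (orient == "+")


def _retained_cds_length(gene: GeneModel, pos: int, retain_left: bool) -> int:
    positions = cds_genomic_positions(gene)
    if retain_left:
        return sum(1 for p in positions if p <= pos)
    return sum(1 for p in positions if p >= pos)


def _in_cds_exon(gene: GeneModel, pos: int) -> bool:
    return (gene.cds_start <= pos <= gene.cds_end
            and any(s <= pos <= e for s, e in gene.exons))


def _in_utr5(gene: GeneModel, pos: int) -> bool:
    if not gene.contains(pos):
        return False
    return pos < gene.cds_start if gene.strand == "+" else pos > gene.cds_end


def _in_utr3(gene: GeneModel, pos: int) -> bool:
    if not gene.contains(pos):
        return False
    return pos > gene.cds_end if gene.strand == "+" else pos < gene.cds_start


def _candidate_status(up: GeneModel, up_pos: int, up_orient: str,
                      down: GeneModel, down_pos: int, down_orient: str) -> str:
    if _in_utr5(down, down_pos):
        return "ambiguous"  # whole downstream CDS retained
    if _in_utr3(down, down_pos) or _in_utr3(up, up_pos):
        return "out_of_frame"  # no downstream coding left / upstream stop precedes junction
    if _in_utr5(up, up_pos):
        return "out_of_frame"  # downstream CDS truncated with no start codon upstream
    lu = _retained_cds_length(up, up_pos, retain_left=(up_orient == "+"))
    # CDS bases of the downstream partner lost upstream of the junction
    ld_total = len(cds_genomic_positions(down))
    ld = ld_total - _retained_cds_length(down, down_pos, retain_left=(down_orient == "+"))
    undefined = (_in_cds_exon(up, up_pos) and lu % 3 != 0) or \
                (_in_cds_exon(down, down_pos) and ld % 3 != 0)
    if undefined:
        return "ambiguous"  # exonic breakpoint splitting a codon
    return "inframe" if lu % 3 == ld % 3 else "out_of_frame"


_STATUS_RANK = {"inframe": 0, "ambiguous": 1, "out_of_frame": 2, "untranscribed": 3}


def assess_fusion(sv: StructuralVariant, bundle: ReferenceBundle) -> FusionAssessment:
    """Classify an SV junction as inframe / out_of_frame / ambiguous / untranscribed."""
    (c1, p1, o1), (c2, p2, o2) = sv.breakpoint_a, sv.breakpoint_b
    g1, g2 = bundle.gene_at(c1, p1), bundle.gene_at(c2, p2)
    if g1 is None or g2 is None or g1.gene == g2.gene:
        return FusionAssessment(status="untranscribed",
                                upstream_gene=g1.gene if g1 else None,
                                downstream_gene=g2.gene if g2 else None)
    candidates = []
    for (gu, pu, ou), (gd, pd, od) in (((g1, p1, o1), (g2, p2, o2)),
                                       ((g2, p2, o2), (g1, p1, o1))):
        if _upstream_compatible(gu, ou) and not _upstream_compatible(gd, od):
            status = _candidate_status(gu, pu, ou, gd, pd, od)
            candidates.append(FusionAssessment(status=status, upstream_gene=gu.gene,
                                               downstream_gene=gd.gene))
    if not candidates:
        return FusionAssessment(status="untranscribed", upstream_gene=g1.gene,
                                downstream_gene=g2.gene)
    return min(candidates, key=lambda a: _STATUS_RANK[a.status])


# ---------------------------------------------------------------------------
# Copy-number events for the co-occurrence analysis


def cna_event_for_cooccurrence(gene: GeneModel, segments: list[CnaSegment],
                               case: TumorCase,
                               config: PipelineConfig | None = None) -> str | None:
    """Gain/loss of at least one copy relative to the rounded ploidy.

    Oncogenes are tested for gain, tumor suppressors for loss; dual-role
    genes are tested for gain first. Requires the CNA purity gate.
    """
    cfg = config or PipelineConfig()
    if not cna_eligible(case, cfg):
        return None
    overlapping = _overlapping(gene, segments)
    if not overlapping:
        return None
    ploidy = round(case.ploidy)
    if gene.is_oncogene and max(s.total_cn for s in overlapping) >= ploidy + 1:
        return "gain_event"
    if gene.is_tsg and min(s.total_cn for s in overlapping) <= ploidy - 1:
        return "loss_event"
    return None
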
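"""CNA gain/loss actionability and fusion frame assessment."""

import pytest

from oncowga.cna_sv import (
    assess_fusion,
    classify_gain,
    classify_loss,
    cna_event_for_cooccurrence,
)
from oncowga.config import PipelineConfig
from oncowga.types import CnaSegment, SomaticVariant, StructuralVariant, TumorCase


def _case(purity=0.6, ploidy=2.0):
    return TumorCase(case_id="C1", tumor_type="breast_invasive_carcinoma",
                     purity=purity, ploidy=ploidy)


def _segment(gene, total_cn, minor_cn=None, pad=50):
    return CnaSegment(chrom=gene.chrom, start=gene.start - pad, end=gene.end + pad,
                      total_cn=total_cn, minor_cn=minor_cn)


def _missense(bundle, gene):
    from oncowga.simulate import _plant_coding_snv
    import numpy as np
    v = _plant_coding_snv(gene, bundle, "missense_variant", np.random.default_rng(5))
    v.gene = gene.gene
    v.consequence = "missense_variant"
    return v


# ---------------------------------------------------------------------------
# Gains


def test_gain_at_twice_ploidy_is_reported(bundle):
    gene = bundle.genes["KRAS"]
    finding = classify_gain(gene, _segment(gene, 4.0), _case(ploidy=2.0))
    assert finding is not None and finding.kind == "gain" and finding.eligible


def test_gain_below_twice_ploidy_is_not_reported(bundle):
    gene = bundle.genes["KRAS"]
    assert classify_gain(gene, _segment(gene, 6.0), _case(ploidy=3.1)) is None  # 6 < 6.2


def test_gain_in_low_purity_case_is_ineligible(bundle):
    gene = bundle.genes["KRAS"]
    finding = classify_gain(gene, _segment(gene, 10.0), _case(purity=0.25))
    assert finding is not None and not finding.eligible
    assert "purity" in finding.reason


def test_purity_threshold_is_strict(bundle):
    gene = bundle.genes["KRAS"]
    finding = classify_gain(gene, _segment(gene, 10.0), _case(purity=0.30))
    assert finding is not None and not finding.eligible


def test_gain_multiplier_is_configurable(bundle):
    gene = bundle.genes["KRAS"]
    cfg = PipelineConfig(gain_multiplier=3.0)
    assert classify_gain(gene, _segment(gene, 4.0), _case(ploidy=2.0), cfg) is None
    assert classify_gain(gene, _segment(gene, 6.0), _case(ploidy=2.0), cfg) is not None


def test_gain_requires_oncogene_role(bundle):
    tsg = bundle.genes["RB1"]
    assert classify_gain(tsg, _segment(tsg, 8.0), _case()) is None


# ---------------------------------------------------------------------------
# Losses


def test_homozygous_deletion_is_scenario_1_without_small_variant(bundle):
    gene = bundle.genes["PTEN"]
    finding = classify_loss(gene, [_segment(gene, 0.0, 0.0)], [], [], _case())
    assert finding is not None and finding.scenario == 1


def test_loh_without_small_variant_is_not_reported(bundle):
    gene = bundle.genes["PTEN"]
    assert classify_loss(gene, [_segment(gene, 1.0, 0.0)], [], [], _case()) is None


def test_loh_with_missense_is_scenario_2(bundle):
    gene = bundle.genes["PTEN"]
    v = _missense(bundle, gene)
    finding = classify_loss(gene, [_segment(gene, 1.0, 0.0)], [v], [], _case())
    assert finding is not None and finding.scenario == 2


def test_copy_neutral_loh_with_missense_is_scenario_2(bundle):
    gene = bundle.genes["PTEN"]
    v = _missense(bundle, gene)
    finding = classify_loss(gene, [_segment(gene, 2.0, 0.0)], [v], [], _case(ploidy=2.0))
    assert finding is not None and finding.scenario == 2


def test_sv_disruption_with_missense_is_scenario_3(bundle):
    gene = bundle.genes["PTEN"]
    v = _missense(bundle, gene)
    mid = (gene.cds_start + gene.cds_end) // 2
    sv = StructuralVariant("BND", (gene.chrom, mid, "+"), (gene.chrom, mid + 9000, "-"))
    finding = classify_loss(gene, [_segment(gene, 2.0, 1.0)], [v], [sv], _case())
    assert finding is not None and finding.scenario == 3


def test_loss_precedence_hom_del_wins(bundle):
    gene = bundle.genes["PTEN"]
    v = _missense(bundle, gene)
    mid = (gene.cds_start + gene.cds_end) // 2
    sv = StructuralVariant("BND", (gene.chrom, mid, "+"), (gene.chrom, mid + 9000, "-"))
    segments = [_segment(gene, 0.0, 0.0), _segment(gene, 1.0, 0.0)]
    finding = classify_loss(gene, segments, [v], [sv], _case())
    assert finding.scenario == 1


def test_splice_region_variant_does_not_support_loss(bundle):
    gene = bundle.genes["PTEN"]
    v = SomaticVariant(gene.chrom, gene.exons[0][1] + 5, "A", "G",
                       gene=gene.gene, consequence="splice_region_variant")
    assert classify_loss(gene, [_segment(gene, 1.0, 0.0)], [v], [], _case()) is None


# ---------------------------------------------------------------------------
# Fusion assessment: examples plus brute-force sequence oracle


def _breakends(up, down):
    up_orient = "+" if up.strand == "+" else "-"
    down_orient = "-" if down.strand == "+" else "+"
    return up_orient, down_orient


def test_matching_intronic_phases_are_inframe(bundle):
    up, down = bundle.genes["LMNA"], bundle.genes["NTRK1"]
    uo, do = _breakends(up, down)
    # intron 1 in both partners: identical cumulative CDS length (130 bases)
    pu = (up.exons[0][1] + up.exons[1][0]) // 2
    pd = (down.exons[0][1] + down.exons[1][0]) // 2
    sv = StructuralVariant("BND", (up.chrom, pu, uo), (down.chrom, pd, do))
    result = assess_fusion(sv, bundle)
    assert result.status == "inframe" and result.reportable
    assert result.upstream_gene == "LMNA" and result.downstream_gene == "NTRK1"


def test_mismatched_intronic_phases_are_out_of_frame(bundle):
    up, down = bundle.genes["LMNA"], bundle.genes["NTRK1"]
    uo, do = _breakends(up, down)
    pu = (up.exons[0][1] + up.exons[1][0]) // 2   # cumulative 130 (phase 1)
    pd = (down.exons[1][1] + down.exons[2][0]) // 2  # cumulative 530 (phase 2)
    sv = StructuralVariant("BND", (up.chrom, pu, uo), (down.chrom, pd, do))
    result = assess_fusion(sv, bundle)
    assert result.status == "out_of_frame" and not result.reportable


def test_downstream_5utr_breakpoint_is_ambiguous_and_reportable(bundle):
    up, down = bundle.genes["LMNA"], bundle.genes["NTRK1"]
    uo, do = _breakends(up, down)
    pu = (up.exons[0][1] + up.exons[1][0]) // 2
    pd = down.cds_start - 20                      # exon-1 5'UTR of the downstream partner
    sv = StructuralVariant("BND", (up.chrom, pu, uo), (down.chrom, pd, do))
    result = assess_fusion(sv, bundle)
    assert result.status == "ambiguous" and result.reportable


def test_incompatible_orientations_are_untranscribed(bundle):
    up, down = bundle.genes["LMNA"], bundle.genes["NTRK1"]
    pu = (up.exons[0][1] + up.exons[1][0]) // 2
    pd = (down.exons[0][1] + down.exons[1][0]) // 2
    # both breakends retain the left piece: no 5'->3' read-through exists
    sv = StructuralVariant("BND", (up.chrom, pu, "+"), (down.chrom, pd, "+"))
    assert assess_fusion(sv, bundle).status == "untranscribed"


def test_intergenic_breakpoint_is_untranscribed(bundle):
    up = bundle.genes["LMNA"]
    pu = (up.exons[0][1] + up.exons[1][0]) // 2
    sv = StructuralVariant("BND", (up.chrom, pu, "+"), ("chr2", 180_000, "-"))
    assert assess_fusion(sv, bundle).status == "untranscribed"


def test_opposite_strand_partners_fuse_inframe(bundle):
    """EML4 (+) joined to ALK (-) with compatible phase is in frame."""
    up, down = bundle.genes["EML4"], bundle.genes["ALK"]
    uo, do = _breakends(up, down)
    found = set()
    for pu in [(up.exons[i][1] + up.exons[i + 1][0]) // 2 for i in range(2)]:
        for pd in [(down.exons[i][1] + down.exons[i + 1][0]) // 2 for i in range(2)]:
            sv = StructuralVariant("BND", (up.chrom, pu, uo), (down.chrom, pd, do))
            found.add(assess_fusion(sv, bundle).status)
    assert "inframe" in found and "out_of_frame" in found


def test_fusion_status_matches_sequence_oracle(bundle):
    """Across a grid of breakpoint placements on a 3x3-exon pair, the frame
    call agrees with brute-force transcript-sequence reconstruction."""
    from _oracles import fusion_grid_mismatches
    mismatches, checked = fusion_grid_mismatches(bundle, "LMNA", "NTRK1", stride=41)
    assert checked > 1300
    assert mismatches == []


def test_reportable_set_excludes_discarded_statuses(small_cohort, small_reports):
    for report in small_reports:
        for fusion in report.fusions:
            assert fusion.reportable == (fusion.status in ("inframe", "ambiguous"))


# ---------------------------------------------------------------------------
# Co-occurrence copy-number events


@pytest.mark.parametrize("gene_name, ploidy, cn, expected", [
    ("KRAS", 2.0, 3.0, "gain_event"),     # oncogene +1 copy
    ("KRAS", 2.0, 2.0, None),
    ("PTEN", 4.2, 3.0, "loss_event"),     # rounded ploidy 4, one copy lost
    ("PTEN", 2.0, 1.0, "loss_event"),
    ("PTEN", 2.0, 2.0, None),
])
def test_cna_event_for_cooccurrence(bundle, gene_name, ploidy, cn, expected):
    gene = bundle.genes[gene_name]
    event = cna_event_for_cooccurrence(gene, [_segment(gene, cn)], _case(ploidy=ploidy))
    assert event == expected


def test_cna_event_requires_purity_gate(bundle):
    gene = bundle.genes["KRAS"]
    event = cna_event_for_cooccurrence(gene, [_segment(gene, 5.0)], _case(purity=0.2))
    assert event is None
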
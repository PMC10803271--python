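"""Somatic interpretation: consequences, PoN Fisher test, filter cascade."""

import math
from fractions import Fraction

import numpy as np
import pytest
from Bio.Seq import Seq

from oncowga.config import PipelineConfig
from oncowga.reference import cds_genomic_positions, spliced_cds
from oncowga.somatic import (
    annotate_consequence,
    apply_somatic_filters,
    noisy_window_fraction,
    pon_fisher_phred,
)
from oncowga.types import PanelOfNormals, SomaticVariant

# ---------------------------------------------------------------------------
# Consequence annotation


def _mutant_protein_oracle(bundle, gene, pos, alt):
    """Independent classification of a CDS SNV by full-protein translation."""
    genome = dict(bundle.genome)
    seq = genome[gene.chrom]
    genome[gene.chrom] = seq[:pos - 1] + alt + seq[pos:]
    ref_protein = str(Seq(spliced_cds(bundle.genome, gene)).translate())
    alt_protein = str(Seq(spliced_cds(genome, gene)).translate())
    if alt_protein[0] != "M":
        return "start_lost"
    if ref_protein == alt_protein:
        return None  # synonymous (exonic splice-region flank aside)
    idx = next(i for i, (a, b) in enumerate(zip(ref_protein, alt_protein)) if a != b)
    if alt_protein[idx] == "*":
        return "stop_gained"
    if ref_protein[idx] == "*":
        return "stop_lost"
    return "missense_variant"


@pytest.mark.parametrize("gene_name", ["TP53", "EGFR", "BRCA2", "PIK3CA"])
def test_cds_snv_consequences_match_protein_oracle(bundle, gene_name, rng):
    """Coding SNV classes agree with brute-force translation of the mutant CDS
    on plus- and minus-strand transcripts."""
    gene = bundle.genes[gene_name]
    positions = cds_genomic_positions(gene)
    checked = 0
    for _ in range(120):
        pos = positions[rng.integers(0, len(positions))]
        ref = bundle.genome[gene.chrom][pos - 1]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        got = annotate_consequence(SomaticVariant(gene.chrom, pos, ref, alt), bundle)
        expected = _mutant_protein_oracle(bundle, gene, pos, alt)
        if expected is None and got == "splice_region_variant":
            continue  # synonymous change in the exonic junction flank
        assert got == expected, (gene_name, pos, ref, alt)
        checked += 1
    assert checked > 80


def test_indel_consequences_by_length(bundle):
    gene = bundle.genes["TP53"]
    positions = sorted(cds_genomic_positions(gene))
    pos = positions[30]
    anchor = bundle.genome[gene.chrom][pos - 1]
    ins3 = SomaticVariant(gene.chrom, pos, anchor, anchor + "TGG")
    ins2 = SomaticVariant(gene.chrom, pos, anchor, anchor + "TG")
    del3 = SomaticVariant(gene.chrom, pos, bundle.genome[gene.chrom][pos - 1:pos + 3], anchor)
    del1 = SomaticVariant(gene.chrom, pos, bundle.genome[gene.chrom][pos - 1:pos + 1], anchor)
    assert annotate_consequence(ins3, bundle) == "inframe_insertion"
    assert annotate_consequence(ins2, bundle) == "frameshift_variant"
    assert annotate_consequence(del3, bundle) == "inframe_deletion"
    assert annotate_consequence(del1, bundle) == "frameshift_variant"


@pytest.mark.parametrize("gene_name", ["TP53", "EGFR"])
@pytest.mark.parametrize("offset, expected", [
    (1, "donor"), (2, "donor"), (3, "splice_region_variant"),
    (8, "splice_region_variant"), (9, None), (50, None),
])
def test_intronic_splice_classes(bundle, gene_name, offset, expected):
    """Distances into the intron: 1-2 bp = donor/acceptor, 3-8 bp = region."""
    gene = bundle.genes[gene_name]
    exon1_end, exon2_start = gene.exons[0][1], gene.exons[1][0]
    after_exon1 = exon1_end + offset       # intron start side
    before_exon2 = exon2_start - offset    # intron end side
    if expected == "donor":
        left, right = ("splice_donor_variant", "splice_acceptor_variant")
        if gene.strand == "-":
            left, right = right, left
    else:
        left = right = expected
    for pos, want in ((after_exon1, left), (before_exon2, right)):
        ref = bundle.genome[gene.chrom][pos - 1]
        alt = "A" if ref != "A" else "G"
        v = SomaticVariant(gene.chrom, pos, ref, alt)
        assert annotate_consequence(v, bundle) == want, (gene_name, offset, pos)


def test_variant_outside_transcripts_is_unannotated(bundle):
    v = SomaticVariant("chr1", 250_000, bundle.genome["chr1"][249_999], "A")
    if v.ref == "A":
        v.alt = "C"
    assert annotate_consequence(v, bundle) is None


# ---------------------------------------------------------------------------
# Fisher / Phred oracle


def _fisher_two_sided_exact(a, b, c, d):
    """Exact two-sided Fisher p by hypergeometric enumeration with rationals."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
           for k in range(lo, hi + 1)}
    cutoff = pmf[a]
    return sum(p for p in pmf.values() if p <= cutoff + cutoff * Fraction(1, 10**9))


def _phred(p):
    return -10.0 * math.log10(max(float(p), 1e-300))


def _direct_result(a, b, c, d):
    pon = PanelOfNormals(sites={("chr1", 1, "T"): [(c, d)]})
    cfg = PipelineConfig(pon_carrier_min_alt_fraction=1.1)  # keep all individuals
    return pon_fisher_phred(a, b, pon, ("chr1", 1, "T"), cfg)


def test_fisher_phred_matches_enumeration_small_tables():
    for a in range(0, 9):
        for b in range(0, 9):
            for c in range(0, 9):
                for d in range(0, 9):
                    res = _direct_result(a, b, c, d)
                    expected = _phred(_fisher_two_sided_exact(a, b, c, d))
                    assert res.phred == pytest.approx(expected, abs=1e-6), (a, b, c, d)


def test_fisher_phred_matches_enumeration_larger_tables(rng):
    for _ in range(150):
        a, b, c, d = rng.integers(0, 51, size=4)
        if a + b + c + d > 200:
            continue
        res = _direct_result(int(a), int(b), int(c), int(d))
        expected = _phred(_fisher_two_sided_exact(int(a), int(b), int(c), int(d)))
        assert res.phred == pytest.approx(expected, abs=1e-6)


def test_true_somatic_site_scores_high():
    pon = PanelOfNormals(sites={}, default_ref_depth=10_000)
    res = pon_fisher_phred(50, 50, pon, ("chr1", 99, "T"))
    assert res.p_value < 1e-5 and res.phred > 50
    assert res.table == ((50, 50), (10_000, 0))


def test_matching_ratio_scores_near_zero():
    res = _direct_result(99, 1, 9900, 100)
    assert res.p_value > 0.5
    assert res.phred < 3


def test_all_zero_table_is_defined():
    res = _direct_result(0, 0, 0, 0)
    assert res.p_value == 1.0 and res.phred == 0.0


def test_carrier_individuals_are_excluded():
    site = ("chr1", 5, "T")
    depths = [(30, 0)] * 10 + [(15, 15)] * 3      # 3 het-like carriers
    pon = PanelOfNormals(sites={site: depths})
    res = pon_fisher_phred(40, 40, pon, site)
    assert res.table[1] == (300, 0)               # carriers dropped entirely
    assert res.phred > 50


def test_artifact_site_scores_below_threshold():
    site = ("chr1", 7, "T")
    depths = [(27, 3)] * 30                        # ~10% noise across the panel
    pon = PanelOfNormals(sites={site: depths})
    res = pon_fisher_phred(72, 8, pon, site)       # tumor ratio matches the noise
    assert res.phred < 50


def test_removing_artifact_individuals_never_lowers_true_site_phred(rng):
    """For a het-like somatic site, dropping noisy panel individuals can only
    sharpen the contrast (phred non-decreasing)."""
    site = ("chr1", 9, "T")
    noisy = [(27, 3)] * 10
    clean = [(30, 0)] * 30
    full = PanelOfNormals(sites={site: clean + noisy})
    reduced = PanelOfNormals(sites={site: clean})
    p_full = pon_fisher_phred(40, 40, full, site).phred
    p_reduced = pon_fisher_phred(40, 40, reduced, site).phred
    assert p_reduced >= p_full - 1e-9


# ---------------------------------------------------------------------------
# Noisy-window rule


def test_noisy_window_uniform_fraction():
    track = {"chr1": np.full(1000, 0.2)}
    assert noisy_window_fraction("chr1", 500, track) == pytest.approx(0.2)


def test_noisy_window_all_clean():
    track = {"chr1": np.zeros(1000)}
    assert noisy_window_fraction("chr1", 500, track) == 0.0


def test_noisy_window_ten_of_101_positions_is_below_threshold():
    track = {"chr1": np.zeros(1000)}
    track["chr1"][500:510] = 1.0  # 10 fully-failed positions in the window
    frac = noisy_window_fraction("chr1", 480, track)
    assert frac == pytest.approx(10 / 101)
    assert frac < 0.10


def test_noisy_window_truncates_at_contig_end():
    track = {"chr1": np.full(60, 0.5)}
    assert noisy_window_fraction("chr1", 5, track) == pytest.approx(0.5)
    # window [1, 55] despite radius 50 on both sides
    track["chr1"][:10] = 0.0
    assert noisy_window_fraction("chr1", 5, track) == pytest.approx(45 * 0.5 / 55)


# ---------------------------------------------------------------------------
# Filter cascade vs brute-force enumeration


def _expected_flags(v, bundle):
    """Rule-by-rule oracle, evaluated independently of the cascade."""
    flags = set()
    if bundle.population_af.get(v.key, v.population_af) > 0.01:
        flags.add("pop_af")
    if bundle.cohort_recurrence.get(v.key, v.cohort_recurrence) > 0.05:
        flags.add("recurrent")
    span = range(v.pos, v.pos + len(v.ref))
    for chrom, s, e in bundle.repeats:
        if chrom == v.chrom and any(s <= p <= e for p in span):
            flags.add("simple_repeat")
    if v.vtype == "indel":
        track = bundle.quality_fail[v.chrom]
        lo, hi = max(v.pos - 50, 1), min(v.pos + 50, len(track))
        if track[lo - 1:hi].mean() >= 0.10:
            flags.add("noisy_indel")
    else:
        if pon_fisher_phred(v.tumor_ref_depth, v.tumor_alt_depth, bundle.pon,
                            (v.chrom, v.pos, v.alt), bundle.config).phred < 50:
            flags.add("pon_artifact")
    return flags


def test_filter_cascade_matches_rule_oracle(small_cohort):
    """Flag assignment on a full synthetic case equals independent
    per-rule enumeration, and the high-confidence set is exactly the
    unflagged subset."""
    bundle = small_cohort.bundle
    variants = [v for v in small_cohort.callsets[0]["somatic"]]
    flagged, high_conf = apply_somatic_filters(variants, bundle)
    assert len(flagged) >= 10
    for v in flagged:
        assert v.filter_flags == _expected_flags(v, bundle), v.key
    assert high_conf == [v for v in flagged if not v.filter_flags]


def test_flagged_variants_are_retained_not_deleted(small_cohort):
    bundle = small_cohort.bundle
    variants = list(small_cohort.callsets[1]["somatic"])
    flagged, high_conf = apply_somatic_filters(variants, bundle)
    assert len(flagged) == len(variants)
    assert len(high_conf) < len(flagged)
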
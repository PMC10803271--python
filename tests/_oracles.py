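"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the implementation's code paths: the Fisher oracle
enumerates the hypergeometric distribution with exact rationals, and the
fusion oracle reconstructs spliced transcript sequences base by base.
"""

import math
from fractions import Fraction

from oncowga.cna_sv import assess_fusion
from oncowga.reference import cds_genomic_positions
from oncowga.types import StructuralVariant


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p for [[a, b], [c, d]] by exact enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
           for k in range(lo, hi + 1)}
    cutoff = pmf[a]
    return sum(p for p in pmf.values() if p <= cutoff + cutoff * Fraction(1, 10**9))


def phred(p) -> float:
    return -10.0 * math.log10(max(float(p), 1e-300))


def _retained_exonic(genome, gene, breakpoint, keep_five_prime):
    """Spliced-transcript bases retained on one side of a genomic breakpoint.

    Walks exons in genomic order and complements for minus-strand genes;
    the breakend base itself belongs to its own retained side. Returns
    (retained transcript sequence, retained CDS length).
    """
    from oncowga.trinuc import COMPLEMENT
    exonic = [(p, genome[gene.chrom][p - 1])
              for s, e in gene.exons for p in range(s, e + 1)]
    if gene.strand == "-":
        exonic = [(p, COMPLEMENT[b]) for p, b in reversed(exonic)]
    if gene.strand == "+":
        retained = [t for t in exonic
                    if (t[0] <= breakpoint if keep_five_prime else t[0] >= breakpoint)]
    else:
        retained = [t for t in exonic
                    if (t[0] >= breakpoint if keep_five_prime else t[0] <= breakpoint)]
    cds = [t for t in retained if gene.cds_start <= t[0] <= gene.cds_end]
    return "".join(b for _, b in retained), len(cds)


def expected_fusion_status(bundle, up, pu, down, pd_):
    """Frame status from brute-force sequence reconstruction."""
    genome = bundle.genome
    _, lu = _retained_exonic(genome, up, pu, keep_five_prime=True)
    _, kept_down = _retained_exonic(genome, down, pd_, keep_five_prime=False)
    up_total = len(cds_genomic_positions(up))
    down_total = len(cds_genomic_positions(down))
    ld = down_total - kept_down
    in_cds_up = up.cds_start <= pu <= up.cds_end
    in_cds_down = down.cds_start <= pd_ <= down.cds_end
    in_exon_up = any(s <= pu <= e for s, e in up.exons)
    in_exon_down = any(s <= pd_ <= e for s, e in down.exons)
    if kept_down == 0 and not in_cds_down:
        return "out_of_frame"          # downstream 3'UTR: no coding left
    if ld == 0 and not in_cds_down:
        return "ambiguous"             # downstream 5'UTR: whole CDS retained
    if lu == 0 and not in_cds_up:
        return "out_of_frame"          # upstream 5'UTR: no start codon retained
    if lu == up_total and not in_cds_up:
        return "out_of_frame"          # upstream 3'UTR: stop precedes junction
    if (in_exon_up and in_cds_up and lu % 3) or \
            (in_exon_down and in_cds_down and ld % 3):
        return "ambiguous"             # codon-splitting exonic breakpoint
    return "inframe" if lu % 3 == ld % 3 else "out_of_frame"


def fusion_grid_mismatches(bundle, up_name, down_name, stride):
    """Compare assess_fusion with the sequence oracle over a breakpoint grid."""
    up, down = bundle.genes[up_name], bundle.genes[down_name]
    up_orient = "+" if up.strand == "+" else "-"
    down_orient = "-" if down.strand == "+" else "+"
    mismatches, checked = [], 0
    for pu in range(up.start + 5, up.end - 5, stride):
        for pd_ in range(down.start + 5, down.end - 5, stride):
            sv = StructuralVariant("BND", (up.chrom, pu, up_orient),
                                   (down.chrom, pd_, down_orient))
            got = assess_fusion(sv, bundle).status
            expected = expected_fusion_status(bundle, up, pu, down, pd_)
            if got != expected:
                mismatches.append((pu, pd_, got, expected))
            checked += 1
    return mismatches, checked
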
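"""Germline cancer-predisposition reporting and pharmacogenomic flagging.

Germline variants are reported for genes indicated for germline testing
when either (a) a ClinVar-style table classifies them pathogenic or likely
pathogenic with at least two review stars, or (b) they are predicted
protein-truncating in a gene whose mechanism of pathogenicity is loss of
function. Pharmacogenomic flags are raised for listed toxicity alleles
(e.g. DPYD variants guiding fluoropyrimidine dosing).
"""

from __future__ import annotations

from .config import PipelineConfig
from .reference import ReferenceBundle
from .somatic import annotate_consequence
from .types import TRUNCATING_CONSEQUENCES, GermlineFinding, PgxFlag, SomaticVariant


def classify_germline(variant: SomaticVariant, bundle: ReferenceBundle,
                      tumor_type: str,
                      config: PipelineConfig | None = None) -> GermlineFinding | None:
    """Return a reportable germline finding for this variant, or None."""
    cfg = config or bundle.config
    gene = bundle.gene_at(variant.chrom, variant.pos)
    if gene is None or not gene.germline_indications:
        return None
    if cfg.germline_tumor_type_restricted and tumor_type not in gene.germline_indications:
        return None
    record = bundle.clinvar.get(variant.key)
    if (record is not None
            and record.classification in ("pathogenic", "likely_pathogenic")
            and record.review_stars >= cfg.min_clinvar_stars):
        return GermlineFinding(gene=gene.gene, variant=variant.key, basis="clinvar")
    consequence = variant.consequence or annotate_consequence(variant, bundle)
    if gene.lof_mechanism and consequence in TRUNCATING_CONSEQUENCES:
        return GermlineFinding(gene=gene.gene, variant=variant.key,
                               basis="predicted_truncating")
    return None


def flag_pgx(germline_variants: list[SomaticVariant],
             bundle: ReferenceBundle) -> list[PgxFlag]:
    """Flag listed pharmacogenomic toxicity alleles, ordered by position."""
    flags = []
    for v in sorted(germline_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        hit = bundle.pgx_alleles.get(v.key)
        if hit is not None:
            gene, allele, recommendation = hit
            flags.append(PgxFlag(gene=gene, variant=v.key, allele=allele,
                                 recommendation=recommendation))
    return flags
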
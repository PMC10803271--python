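"""Domain types shared across the interpretation pipeline.

Coordinates are 1-based and closed throughout (VCF convention); BED inputs
are converted on read.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

# Curated consequence vocabulary: only variants annotated with one of these
# on the canonical transcript are reportable.
CURATED_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
    }
)

# "Nonsynonymous" consequences used for TMB and for the small-variant half of
# the loss scenarios: the curated set minus the splice-region flank.
PROTEIN_ALTERING_CONSEQUENCES = CURATED_CONSEQUENCES - {"splice_region_variant"}

# Predicted protein-truncating consequences for germline loss-of-function
# reporting (missense and in-frame events excluded).
TRUNCATING_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

FILTER_FLAGS = frozenset(
    {"pop_af", "recurrent", "simple_repeat", "noisy_indel", "pon_artifact"}
)

VARIANT_CLASSES = ("small_variant", "cna", "sv", "germline")

STAGES = (1, 2, 3, 4)


@dataclass
class QcMetrics:
    """Sequencing-quality metrics for one tumor-normal pair."""

    normal_yield_gb: float
    tumor_yield_gb: float
    normal_autosome_cov15_frac: float
    normal_contamination: float
    tumor_contamination: float
    pair_concordant: bool

    def __post_init__(self) -> None:
        if self.normal_yield_gb < 0 or self.tumor_yield_gb < 0:
            raise ValueError("sequencing yields must be non-negative")
        for name in (
            "normal_autosome_cov15_frac",
            "normal_contamination",
            "tumor_contamination",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SomaticVariant:
    """One somatic small-variant call with tumor allele depths.

    ``ref``/``alt`` follow the anchored VCF convention after normalization
    (left-aligned, trimmed, bi-allelic).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_ref_depth: int = 0
    tumor_alt_depth: int = 0
    gene: str | None = None
    transcript_id: str | None = None
    consequence: str | None = None
    population_af: float = 0.0
    cohort_recurrence: float = 0.0
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tumor_ref_depth < 0 or self.tumor_alt_depth < 0:
            raise ValueError("allele depths must be non-negative")
        bad = set(self.filter_flags) - FILTER_FLAGS
        if bad:
            raise ValueError(f"unknown filter flags: {sorted(bad)}")
        if self.consequence is not None and self.consequence not in CURATED_CONSEQUENCES:
            raise ValueError(f"consequence outside the curated set: {self.consequence}")

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_high_confidence(self) -> bool:
        return not self.filter_flags


@dataclass
class GeneModel:
    """Canonical-transcript gene model with cancer-role metadata.

    ``exons`` are 1-based closed intervals ordered by genomic coordinate;
    ``cds_start``/``cds_end`` are genomic coordinates (cds_start < cds_end
    regardless of strand). Genes with an ambiguous or unknown role carry
    role ``both`` and participate in both oncogene and tumor-suppressor
    rules.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    role: str = "both"
    lof_mechanism: bool = False
    directory_indications: set[str] = field(default_factory=set)
    directory_variant_classes: set[str] = field(default_factory=set)
    germline_indications: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.role not in ("oncogene", "tsg", "both"):
            raise ValueError(f"bad role {self.role!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon {s}-{e} reversed")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons overlap or are unordered")
            prev_end = e
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise ValueError("CDS outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_oncogene(self) -> bool:
        return self.role in ("oncogene", "both")

    @property
    def is_tsg(self) -> bool:
        return self.role in ("tsg", "both")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class PanelOfNormals:
    """Per-site allele depths across a panel of non-tumor genomes.

    ``sites`` maps (chrom, pos, alt) to a list of (ref_depth, alt_depth)
    pairs, one per panel individual. Sites absent from the panel are treated
    as alt-free at ``default_ref_depth`` aggregated reference depth.
    """

    sites: dict[tuple[str, int, str], list[tuple[int, int]]] = field(default_factory=dict)
    default_ref_depth: int = 1500

    def __post_init__(self) -> None:
        for key, depths in self.sites.items():
            for r, a in depths:
                if r < 0 or a < 0:
                    raise ValueError(f"negative panel depth at {key}")


@dataclass
class TumorCase:
    """Sample plus case metadata for one sequenced tumor."""

    case_id: str
    tumor_type: str
    sample_route: str = "surgical_resection"
    treatment_status: str = "naive"
    sample_preservation: str = "fresh_frozen"
    purity: float = 0.7
    ploidy: float = 2.0
    sample_date: datetime.date = datetime.date(2017, 6, 1)
    submitted_metastatic: bool = False
    stage: int | None = None
    pcr_amplified: bool = False
    submitted_icd10: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.sample_route not in ("surgical_resection", "biopsy"):
            raise ValueError(f"bad sample_route {self.sample_route!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"bad stage {self.stage!r}")


@dataclass
class CnaSegment:
    """Copy-number segment with total and minor-allele copy number."""

    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start after end")
        if self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")
        if self.minor_cn is not None and self.minor_cn > self.total_cn + 1e-9:
            raise ValueError("minor_cn exceeds total_cn")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


# Breakend orientation: "+" means the retained segment lies to the LEFT of
# the breakpoint (the junction is at its right end); "-" means the retained
# segment lies to the RIGHT.
Breakend = tuple[str, int, str]


@dataclass
class StructuralVariant:
    """A structural-variant event reduced to its two breakends."""

    svtype: str
    breakpoint_a: Breakend
    breakpoint_b: Breakend
    sv_id: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in ("BND", "DEL", "DUP", "INV"):
            raise ValueError(f"bad svtype {self.svtype!r}")
        for chrom, pos, orient in (self.breakpoint_a, self.breakpoint_b):
            if orient not in "+-":
                raise ValueError(f"bad breakend orientation {orient!r}")


@dataclass
class FisherPhredResult:
    """Panel-of-normals artifact test result on the Phred scale."""

    p_value: float
    phred: float
    table: tuple[tuple[int, int], tuple[int, int]]


@dataclass
class CnaFinding:
    gene: str
    kind: str  # gain | loss
    scenario: int | None = None  # losses: 1 hom-del, 2 LOH/cnLOH+SNV, 3 SV+SNV
    eligible: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "loss" and self.eligible and self.scenario not in (1, 2, 3):
            raise ValueError("loss findings carry a scenario in {1,2,3}")


@dataclass
class FusionAssessment:
    status: str  # inframe | out_of_frame | untranscribed | ambiguous
    upstream_gene: str | None = None
    downstream_gene: str | None = None

    @property
    def reportable(self) -> bool:
        return self.status in ("inframe", "ambiguous")


@dataclass
class ClinVarRecord:
    classification: str  # pathogenic | likely_pathogenic | other
    review_stars: int

    def __post_init__(self) -> None:
        if not 0 <= self.review_stars <= 4:
            raise ValueError("review stars must be in [0, 4]")


@dataclass
class GermlineFinding:
    gene: str
    variant: tuple[str, int, str, str]
    basis: str  # clinvar | predicted_truncating
    reportable: bool = True


@dataclass
class PgxFlag:
    gene: str
    variant: tuple[str, int, str, str]
    allele: str
    recommendation: str


@dataclass
class SignatureExposure:
    """Per-signature contribution fractions from a non-negative refit."""

    fractions: dict[str, float]
    residual: float  # relative L2 reconstruction residual
    n_mutations: int

    def __post_init__(self) -> None:
        for name, f in self.fractions.items():
            if f < -1e-12:
                raise ValueError(f"negative exposure for {name}")


@dataclass
class EtiologyResult:
    groups: dict[str, float]
    other_fraction: float
    mmr_deficient: bool


@dataclass
class HrdCall:
    method: str
    status: str  # positive | negative | unknown
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad HRD status {self.status!r}")


@dataclass
class LinkageOutcome:
    status: str
    matched_tumor_type: str | None = None
    evidence: str = ""

    STATUSES = (
        "registry_confirmed",
        "hes_confirmed",
        "operation_code_confirmed",
        "flexible_match_confirmed",
        "gmc_code_confirmed",
        "unmatched",
    )

    def __post_init__(self) -> None:
        if self.status not in self.STATUSES:
            raise ValueError(f"bad linkage status {self.status!r}")
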
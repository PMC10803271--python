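"""Reference resources: genome, gene models, signature matrix, panels.

The bundle collects everything the interpretation stages need besides the
per-case call sets. A desk-scale toy reference (a few hundred kilobases,
~20 cancer genes with canonical three-exon transcripts) is built
programmatically so trinucleotide contexts, consequence annotation and
coding footprints are computable quickly and reproducibly.

The single-base-substitution signature matrix shipped here is SYNTHETIC: it
uses the COSMIC v3 column names required by the etiology map (SBS1, SBS2,
SBS3, ...) but the 96-channel profiles are generated deterministically in
code, concentrated on each signature's characteristic substitution classes.
The real COSMIC matrix is a drop-in replacement with the same layout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .trinuc import COMPLEMENT, CONTEXTS_96
from .types import ClinVarRecord, GeneModel, PanelOfNormals

# ---------------------------------------------------------------------------
# Synthetic signature matrix


SIGNATURE_NAMES = (
    "SBS1", "SBS2", "SBS3", "SBS4", "SBS5", "SBS6",
    "SBS7a", "SBS7b", "SBS7c", "SBS7d",
    "SBS10a", "SBS10b", "SBS13", "SBS14", "SBS15", "SBS18",
    "SBS20", "SBS21", "SBS26", "SBS40", "SBS44", "SBS92",
)

# Characteristic channel selectors (substitution, 5' flank, 3' flank; None =
# any). Most of each profile's mass lands on these channels, echoing the
# real signatures' dominant peaks; the rest is a low seeded background.
_SIGNATURE_BLOCKS: dict[str, list[tuple[str, str | None, str | None]]] = {
    "SBS1": [("C>T", None, "G")],                      # deamination at NpCpG
    "SBS2": [("C>T", "T", None)],                      # APOBEC TpC
    "SBS3": [],                                        # broad, featureless (HRD)
    "SBS4": [("C>A", None, None)],                     # tobacco
    "SBS5": [],                                        # broad clock-like
    "SBS6": [("C>T", "G", None)],
    "SBS7a": [("C>T", "C", None), ("C>T", "T", "C")],  # UV dipyrimidine
    "SBS7b": [("C>T", "C", "C")],
    "SBS7c": [("T>A", "C", None), ("T>A", "T", None)],
    "SBS7d": [("T>C", "C", None), ("T>C", "T", None)],
    "SBS10a": [("C>A", "T", "T")],                     # POLE hotspot
    "SBS10b": [("C>T", "T", "G")],
    "SBS13": [("C>G", "T", None)],                     # APOBEC TpC
    "SBS14": [("C>A", None, "T")],
    "SBS15": [("C>T", None, "T")],
    "SBS18": [("C>A", None, "A")],
    "SBS20": [("C>A", "G", None)],
    "SBS21": [("T>C", "G", None)],
    "SBS26": [("T>C", None, "G")],
    "SBS40": [],
    "SBS44": [("C>A", "C", None), ("C>T", "C", "T")],
    "SBS92": [("T>C", "A", None)],
}


def _channel_mask(selectors: list[tuple[str, str | None, str | None]]) -> np.ndarray:
    mask = np.zeros(96, dtype=bool)
    for sub, five, three in selectors:
        for i, ctx in enumerate(CONTEXTS_96):
            if f"[{sub}]" not in ctx:
                continue
            if five is not None and ctx[0] != five:
                continue
            if three is not None and ctx[-1] != three:
                continue
            mask[i] = True
    return mask


def synthetic_signature_matrix(names: tuple[str, ...] = SIGNATURE_NAMES) -> pd.DataFrame:
    """Deterministic synthetic 96xK signature matrix (columns sum to 1)."""
    cols = {}
    for name in names:
        seed = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
        rng = np.random.default_rng(seed)
        profile = rng.gamma(0.4, size=96) * 0.02
        mask = _channel_mask(_SIGNATURE_BLOCKS.get(name, []))
        if mask.any():
            profile[mask] += rng.gamma(2.0, size=int(mask.sum())) * (4.0 / mask.sum())
        else:  # broad signatures: smooth, dense profile
            profile = 0.5 + rng.gamma(3.0, size=96) * 0.2
        cols[name] = profile / profile.sum()
    return pd.DataFrame(cols, index=list(CONTEXTS_96))


def validate_signature_matrix(matrix: pd.DataFrame) -> None:
    if list(matrix.index) != list(CONTEXTS_96):
        raise ValueError("signature matrix must be indexed by the 96 contexts in standard order")
    sums = matrix.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValueError(f"signature columns not summing to 1: {list(bad.index)}")


# ---------------------------------------------------------------------------
# Toy genome and gene models


TUMOR_TYPES = (
    "breast_invasive_carcinoma",
    "colon_adenocarcinoma",
    "skin_cutaneous_melanoma",
    "lung_adenocarcinoma",
    "ovarian_high_grade_serous",
    "glioblastoma",
)

_ALL = set(TUMOR_TYPES)

# gene, chrom, strand, role, lof_mechanism, somatic directory {type: classes},
# germline-indicated tumor types
_GENE_TABLE: list[tuple] = [
    ("TP53", "chr1", "+", "tsg", True,
     {t: {"small_variant", "cna"} for t in _ALL}, set()),
    ("KRAS", "chr1", "+", "oncogene", False,
     {"colon_adenocarcinoma": {"small_variant", "cna"}, "lung_adenocarcinoma": {"small_variant"}}, set()),
    ("PIK3CA", "chr1", "+", "oncogene", False,
     {"breast_invasive_carcinoma": {"small_variant"}}, set()),
    ("BRAF", "chr1", "+", "oncogene", False,
     {"skin_cutaneous_melanoma": {"small_variant"}, "colon_adenocarcinoma": {"small_variant"}}, set()),
    ("EGFR", "chr1", "-", "oncogene", False,
     {"lung_adenocarcinoma": {"small_variant", "cna"}, "glioblastoma": {"small_variant", "cna"}}, set()),
    ("PTEN", "chr1", "+", "tsg", True,
     {"glioblastoma": {"small_variant", "cna"}, "breast_invasive_carcinoma": {"cna"}}, set()),
    ("CDKN2A", "chr1", "+", "tsg", False,
     {"glioblastoma": {"cna"}, "skin_cutaneous_melanoma": {"cna"}}, set()),
    ("RB1", "chr1", "+", "tsg", True,
     {"breast_invasive_carcinoma": {"small_variant", "cna"}}, set()),
    ("APC", "chr1", "+", "tsg", True,
     {"colon_adenocarcinoma": {"small_variant"}}, set()),
    ("NRAS", "chr1", "+", "oncogene", False,
     {"skin_cutaneous_melanoma": {"small_variant"}}, set()),
    ("CTNNB1", "chr1", "+", "oncogene", False,
     {"colon_adenocarcinoma": {"small_variant"}}, set()),
    ("FGFR2", "chr1", "+", "oncogene", False,
     {"breast_invasive_carcinoma": {"small_variant", "cna"}}, set()),
    ("KIT", "chr1", "+", "oncogene", False,
     {"skin_cutaneous_melanoma": {"small_variant", "cna"}}, set()),
    ("ERBB2", "chr1", "+", "oncogene", False,
     {"breast_invasive_carcinoma": {"cna"}}, set()),
    ("BRCA1", "chr2", "+", "tsg", True,
     {"ovarian_high_grade_serous": {"small_variant", "cna", "germline"},
      "breast_invasive_carcinoma": {"small_variant", "germline"}},
     {"ovarian_high_grade_serous", "breast_invasive_carcinoma"}),
    ("BRCA2", "chr2", "-", "tsg", True,
     {"ovarian_high_grade_serous": {"small_variant", "germline"},
      "breast_invasive_carcinoma": {"small_variant", "germline"}},
     {"ovarian_high_grade_serous", "breast_invasive_carcinoma"}),
    ("PMS2", "chr2", "+", "tsg", True,
     {"colon_adenocarcinoma": {"germline"}}, {"colon_adenocarcinoma"}),
    ("VHL", "chr2", "+", "tsg", True, {}, set()),
    ("NTRK1", "chr2", "+", "oncogene", False,
     {t: {"sv"} for t in _ALL}, set()),
    ("LMNA", "chr2", "+", "both", False, {}, set()),
    ("ALK", "chr2", "-", "oncogene", False,
     {"lung_adenocarcinoma": {"sv"}}, set()),
    ("EML4", "chr2", "+", "both", False, {}, set()),
    ("DPYD", "chr2", "+", "both", False, {}, set()),
]

# Oncogenes are tested for copy gain and tumor suppressors for copy loss in
# the co-occurrence analysis.
COOCCURRENCE_PANEL = (
    "EGFR", "KIT", "BRAF", "KRAS", "NRAS", "CTNNB1", "FGFR2",
    "TP53", "RB1", "CDKN2A", "APC", "PTEN",
)

_CONTIG_LENGTHS = {"chr1": 300_000, "chr2": 200_000}
_EXON_LENGTHS = (250, 400, 350)
_INTRON_LENGTHS = (300, 250)
_UTR5, _UTR3 = 120, 150


def _make_gene(gene: str, chrom: str, start: int, strand: str, role: str,
               lof: bool, directory: dict, germline: set) -> GeneModel:
    exons = []
    pos = start
    for length, intron in zip(_EXON_LENGTHS, (*_INTRON_LENGTHS, 0)):
        exons.append((pos, pos + length - 1))
        pos += length + intron
    a, b = (_UTR5, _UTR3) if strand == "+" else (_UTR3, _UTR5)
    cds_start = exons[0][0] + a
    cds_end = exons[-1][1] - b
    # trim at the 3' end so the CDS length is a codon multiple
    extra = sum(min(e, cds_end) - max(s, cds_start) + 1
                for s, e in exons if s <= cds_end and e >= cds_start) % 3
    if strand == "+":
        cds_end -= extra
    else:
        cds_start += extra
    classes = set().union(*directory.values()) if directory else set()
    return GeneModel(
        gene=gene, transcript_id=f"TOY_{gene}_T1", chrom=chrom, strand=strand,
        exons=exons, cds_start=cds_start, cds_end=cds_end, role=role,
        lof_mechanism=lof,
        directory_indications=set(directory),
        directory_variant_classes=classes,
        germline_indications=set(germline),
    )


def cds_genomic_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in transcript (5'->3') order."""
    positions = [
        p
        for s, e in gene.exons
        for p in range(max(s, gene.cds_start), min(e, gene.cds_end) + 1)
        if s <= gene.cds_end and e >= gene.cds_start
    ]
    return positions[::-1] if gene.strand == "-" else positions


def transcript_base(genome: dict[str, str], gene: GeneModel, pos: int) -> str:
    base = genome[gene.chrom][pos - 1]
    return COMPLEMENT[base] if gene.strand == "-" else base


def spliced_cds(genome: dict[str, str], gene: GeneModel) -> str:
    return "".join(transcript_base(genome, gene, p) for p in cds_genomic_positions(gene))


_STOPS = {"TAA", "TAG", "TGA"}


def _patch_cds(genome: dict[str, list[str]], gene: GeneModel) -> None:
    """Force a clean ORF: ATG start, TAA stop, no internal stop codons."""
    positions = cds_genomic_positions(gene)
    seq = [
        COMPLEMENT[genome[gene.chrom][p - 1]] if gene.strand == "-" else genome[gene.chrom][p - 1]
        for p in positions
    ]
    n = len(seq) // 3
    seq[0:3] = "ATG"
    seq[3 * (n - 1): 3 * n] = "TAA"
    for i in range(1, n - 1):
        if "".join(seq[3 * i: 3 * i + 3]) in _STOPS:
            seq[3 * i: 3 * i + 3] = "CTG"
    for p, b in zip(positions, seq):
        genome[gene.chrom][p - 1] = COMPLEMENT[b] if gene.strand == "-" else b


@dataclass
class ReferenceBundle:
    """All shared resources for a pipeline run."""

    genome: dict[str, str]
    genes: dict[str, GeneModel]
    repeats: list[tuple[str, int, int]]          # 1-based closed intervals
    signatures: pd.DataFrame                     # 96 x K, columns sum to 1
    pon: PanelOfNormals = field(default_factory=PanelOfNormals)
    population_af: dict[tuple, float] = field(default_factory=dict)
    cohort_recurrence: dict[tuple, float] = field(default_factory=dict)
    clinvar: dict[tuple, ClinVarRecord] = field(default_factory=dict)
    pgx_alleles: dict[tuple, tuple[str, str, str]] = field(default_factory=dict)
    # per-contig fraction of base calls failed at each position (index pos-1)
    quality_fail: dict[str, np.ndarray] = field(default_factory=dict)
    coding_megabases: float = 0.0
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        validate_signature_matrix(self.signatures)
        if self.coding_megabases <= 0:
            self.coding_megabases = self.compute_coding_megabases()
        if self.coding_megabases <= 0:
            raise ValueError("coding footprint must be positive")
        for chrom, seq in self.genome.items():
            if chrom not in self.quality_fail:
                self.quality_fail[chrom] = np.zeros(len(seq))

    def compute_coding_megabases(self) -> float:
        total = 0
        for g in self.genes.values():
            for s, e in g.exons:
                lo, hi = max(s, g.cds_start), min(e, g.cds_end)
                if lo <= hi:
                    total += hi - lo + 1
        return total / 1e6

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        for g in self.genes.values():
            if g.chrom == chrom and g.contains(pos):
                return g
        return None

    def in_repeat(self, chrom: str, pos: int, end: int | None = None) -> bool:
        end = end if end is not None else pos
        return any(c == chrom and s <= end and pos <= e for c, s, e in self.repeats)


DEFAULT_REPEATS = [
    ("chr1", 150_001, 151_000),
    ("chr1", 200_001, 200_200),
    ("chr2", 150_001, 150_300),
]

_DPYD_ALLELES = (("DPYD*2A", 60), ("DPYD*13", 130), ("DPYD c.2846A>T", 205))


def build_toy_reference(genome_seed: int = 7, config: PipelineConfig | None = None) -> ReferenceBundle:
    """Construct the desk-scale reference bundle.

    The genome is random sequence with gene loci patched to hold clean open
    reading frames; the DPYD pharmacogenomic allele table is a documented
    synthetic placeholder keyed to positions inside the toy DPYD CDS.
    """
    rng = np.random.default_rng(genome_seed)
    genome_lists = {
        chrom: list("".join(rng.choice(list("ACGT"), size=n)))
        for chrom, n in _CONTIG_LENGTHS.items()
    }
    genes: dict[str, GeneModel] = {}
    offsets = {"chr1": 10_000, "chr2": 10_000}
    for gene, chrom, strand, role, lof, directory, germline in _GENE_TABLE:
        gm = _make_gene(gene, chrom, offsets[chrom], strand, role, lof, directory, germline)
        offsets[chrom] += 4_000
        genes[gene] = gm
        _patch_cds(genome_lists, gm)
    genome = {c: "".join(s) for c, s in genome_lists.items()}

    pgx = {}
    dpyd = genes["DPYD"]
    cds_pos = cds_genomic_positions(dpyd)
    for allele, idx in _DPYD_ALLELES:
        pos = cds_pos[idx]
        ref = genome["chr2"][pos - 1]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        pgx[("chr2", pos, ref, alt)] = ("DPYD", allele,
                                        "fluoropyrimidine dose reduction or omission")

    return ReferenceBundle(
        genome=genome,
        genes=genes,
        repeats=list(DEFAULT_REPEATS),
        signatures=synthetic_signature_matrix(),
        pgx_alleles=pgx,
        config=config or PipelineConfig(),
    )


# ---------------------------------------------------------------------------
# Bundle serialization (plain-text resources + a YAML manifest)


def write_reference_bundle(bundle: ReferenceBundle, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in bundle.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    rows = []
    for g in bundle.genes.values():
        rows.append({
            "gene": g.gene, "transcript_id": g.transcript_id, "chrom": g.chrom,
            "strand": g.strand,
            "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
            "cds_start": g.cds_start, "cds_end": g.cds_end, "role": g.role,
            "lof_mechanism": int(g.lof_mechanism),
            "directory_indications": "|".join(sorted(g.directory_indications)),
            "directory_variant_classes": "|".join(sorted(g.directory_variant_classes)),
            "germline_indications": "|".join(sorted(g.germline_indications)),
        })
    pd.DataFrame(rows).to_csv(outdir / "gene_models.tsv", sep="\t", index=False)

    with open(outdir / "simple_repeats.bed", "w") as fh:  # BED: 0-based half-open
        for chrom, s, e in bundle.repeats:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    bundle.signatures.rename_axis("context").to_csv(outdir / "signatures.synthetic.tsv", sep="\t")

    def _write_af(table: dict[tuple, float], name: str) -> None:
        df = pd.DataFrame(
            [{"chrom": c, "pos": p, "ref": r, "alt": a, "af": v}
             for (c, p, r, a), v in sorted(table.items())]
        )
        if df.empty:
            df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "af"])
        df.to_csv(outdir / name, sep="\t", index=False)

    _write_af(bundle.population_af, "population_af.tsv")
    _write_af(bundle.cohort_recurrence, "cohort_recurrence.tsv")

    pon_rows = []
    for (chrom, pos, alt), depths in sorted(bundle.pon.sites.items()):
        pon_rows.append({
            "chrom": chrom, "pos": pos, "alt": alt,
            "ref_depths": ",".join(str(r) for r, _ in depths),
            "alt_depths": ",".join(str(a) for _, a in depths),
        })
    pd.DataFrame(pon_rows, columns=["chrom", "pos", "alt", "ref_depths", "alt_depths"]).to_csv(
        outdir / "panel_of_normals.tsv", sep="\t", index=False)

    cv_rows = [{"chrom": c, "pos": p, "ref": r, "alt": a,
                "classification": rec.classification, "review_stars": rec.review_stars}
               for (c, p, r, a), rec in sorted(bundle.clinvar.items())]
    pd.DataFrame(cv_rows, columns=["chrom", "pos", "ref", "alt", "classification", "review_stars"]).to_csv(
        outdir / "clinvar.tsv", sep="\t", index=False)

    pgx_rows = [{"chrom": c, "pos": p, "ref": r, "alt": a, "gene": g,
                 "allele": al, "recommendation": rec}
                for (c, p, r, a), (g, al, rec) in sorted(bundle.pgx_alleles.items())]
    pd.DataFrame(pgx_rows, columns=["chrom", "pos", "ref", "alt", "gene", "allele", "recommendation"]).to_csv(
        outdir / "pgx_alleles.synthetic.tsv", sep="\t", index=False)

    qf_rows = []
    for chrom, track in bundle.quality_fail.items():
        nz = np.flatnonzero(track)
        if len(nz) == 0:
            continue
        # run-length encode contiguous equal-fraction stretches
        start = nz[0]
        for i in range(1, len(nz) + 1):
            if i == len(nz) or nz[i] != nz[i - 1] + 1 or track[nz[i]] != track[start]:
                qf_rows.append({"chrom": chrom, "start": int(start + 1),
                                "end": int(nz[i - 1] + 1), "fail_fraction": float(track[start])})
                if i < len(nz):
                    start = nz[i]
    pd.DataFrame(qf_rows, columns=["chrom", "start", "end", "fail_fraction"]).to_csv(
        outdir / "quality_fail.tsv", sep="\t", index=False)

    manifest = {
        "genome": "genome.fa",
        "gene_models": "gene_models.tsv",
        "simple_repeats": "simple_repeats.bed",
        "signatures": "signatures.synthetic.tsv",
        "population_af": "population_af.tsv",
        "cohort_recurrence": "cohort_recurrence.tsv",
        "panel_of_normals": "panel_of_normals.tsv",
        "clinvar": "clinvar.tsv",
        "pgx_alleles": "pgx_alleles.synthetic.tsv",
        "quality_fail": "quality_fail.tsv",
        "pon_default_ref_depth": bundle.pon.default_ref_depth,
        "config": bundle.config.to_dict(),
    }
    with open(outdir / "bundle.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir / "bundle.yaml"


def _read_fasta(path: Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def load_reference_bundle(manifest_path: str | Path) -> ReferenceBundle:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent

    def _p(key: str) -> Path:
        path = base / manifest[key]
        if not path.exists():
            raise FileNotFoundError(f"missing resource {key!r}: {path}")
        return path

    genome = _read_fasta(_p("genome"))

    genes = {}
    for _, row in pd.read_csv(_p("gene_models"), sep="\t").iterrows():
        def _split(v):
            return set(str(v).split("|")) if isinstance(v, str) and v else set()
        genes[row["gene"]] = GeneModel(
            gene=row["gene"], transcript_id=row["transcript_id"], chrom=row["chrom"],
            strand=row["strand"],
            exons=[tuple(map(int, x.split("-"))) for x in row["exons"].split(";")],
            cds_start=int(row["cds_start"]), cds_end=int(row["cds_end"]),
            role=row["role"], lof_mechanism=bool(row["lof_mechanism"]),
            directory_indications=_split(row["directory_indications"]),
            directory_variant_classes=_split(row["directory_variant_classes"]),
            germline_indications=_split(row["germline_indications"]),
        )

    repeats = []
    with open(_p("simple_repeats")) as fh:
        for line in fh:
            if line.strip():
                chrom, s, e = line.split()[:3]
                repeats.append((chrom, int(s) + 1, int(e)))  # BED -> 1-based closed

    signatures = pd.read_csv(_p("signatures"), sep="\t", index_col="context")

    def _read_af(key: str) -> dict:
        df = pd.read_csv(_p(key), sep="\t")
        return {(r.chrom, int(r.pos), r.ref, r.alt): float(r.af) for r in df.itertuples()}

    pon_sites = {}
    df = pd.read_csv(_p("panel_of_normals"), sep="\t")
    for r in df.itertuples():
        refs = [int(x) for x in str(r.ref_depths).split(",")] if str(r.ref_depths) else []
        alts = [int(x) for x in str(r.alt_depths).split(",")] if str(r.alt_depths) else []
        pon_sites[(r.chrom, int(r.pos), r.alt)] = list(zip(refs, alts))

    clinvar = {}
    for r in pd.read_csv(_p("clinvar"), sep="\t").itertuples():
        clinvar[(r.chrom, int(r.pos), r.ref, r.alt)] = ClinVarRecord(
            classification=r.classification, review_stars=int(r.review_stars))

    pgx = {}
    for r in pd.read_csv(_p("pgx_alleles"), sep="\t").itertuples():
        pgx[(r.chrom, int(r.pos), r.ref, r.alt)] = (r.gene, r.allele, r.recommendation)

    quality_fail = {chrom: np.zeros(len(seq)) for chrom, seq in genome.items()}
    for r in pd.read_csv(_p("quality_fail"), sep="\t").itertuples():
        quality_fail[r.chrom][int(r.start) - 1:int(r.end)] = float(r.fail_fraction)

    cfg_map = dict(manifest.get("config") or {})
    if "flexible_match_pairs" in cfg_map:
        cfg_map["flexible_match_pairs"] = {k: set(v) for k, v in cfg_map["flexible_match_pairs"].items()}
    config = PipelineConfig().override(cfg_map)

    return ReferenceBundle(
        genome=genome, genes=genes, repeats=repeats, signatures=signatures,
        pon=PanelOfNormals(sites=pon_sites,
                           default_ref_depth=int(manifest.get("pon_default_ref_depth", 1500))),
        population_af=_read_af("population_af"),
        cohort_recurrence=_read_af("cohort_recurrence"),
        clinvar=clinvar, pgx_alleles=pgx, quality_fail=quality_fail,
        config=config,
    )
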
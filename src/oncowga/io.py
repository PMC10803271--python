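"""Readers and writers for the call-set and clinical-table formats.

Small variants and SVs travel as VCF 4.2 (breakends in BND bracket
notation), CNA segments and clinical tables as TSV with documented headers.
On read, small variants are decomposed to bi-allelic records, trimmed and
left-aligned against the reference; all internal coordinates are 1-based
closed.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import pysam

from .types import CnaSegment, SomaticVariant, StructuralVariant


class MalformedRecordError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Variant normalization


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      genome: dict[str, str] | None = None) -> tuple[int, str, str]:
    """Trim shared bases and left-align an indel (vt-style normalization)."""
    if not ref or not alt:
        raise MalformedRecordError(f"empty allele at {chrom}:{pos}")
    ref, alt = ref.upper(), alt.upper()
    if genome is not None:
        while True:
            if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
                ref, alt = ref[:-1], alt[:-1]
            elif not ref or not alt:
                if pos <= 1:
                    break
                pos -= 1
                base = genome[chrom][pos - 1].upper()
                ref, alt = base + ref, base + alt
            else:
                break
    else:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# Small-variant VCF


def _vcf_header(contigs: dict[str, int], somatic: bool) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in contigs.items()]
    for flag in ("pop_af", "recurrent", "simple_repeat", "noisy_indel", "pon_artifact"):
        lines.append(f'##FILTER=<ID={flag},Description="Internal somatic filter: {flag}">')
    lines.append('##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population germline allele frequency">')
    lines.append('##INFO=<ID=REC,Number=1,Type=Float,Description="Cohort somatic recurrence frequency">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    sample = "TUMOR" if somatic else "NORMAL"
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    return "\n".join(lines) + "\n"


def write_somatic_vcf(variants: list[SomaticVariant], path: str | Path,
                      contigs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, somatic=True))
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            filt = ";".join(sorted(v.filter_flags)) if v.filter_flags else "PASS"
            info = f"POP_AF={v.population_af:g};REC={v.cohort_recurrence:g}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}"
                     f"\tAD\t{v.tumor_ref_depth},{v.tumor_alt_depth}\n")


def _info_float(rec, key: str) -> float:
    try:
        return float(rec.info.get(key, 0.0) or 0.0)
    except (KeyError, ValueError, TypeError):
        return 0.0


def read_somatic_vcf(path: str | Path, genome: dict[str, str] | None = None) -> list[SomaticVariant]:
    """Read, decompose and normalize somatic small-variant calls."""
    out: list[SomaticVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                depths = None
                if rec.samples and "AD" in rec.format:
                    depths = rec.samples[0].get("AD")
                for i, alt in enumerate(rec.alts or ()):
                    pos, ref, alt_n = normalize_variant(rec.chrom, rec.pos, rec.ref, alt, genome)
                    ref_d = int(depths[0]) if depths else 0
                    alt_d = int(depths[i + 1]) if depths and len(depths) > i + 1 else 0
                    flags = set(rec.filter.keys()) - {"PASS", "."}
                    out.append(SomaticVariant(
                        chrom=rec.chrom, pos=pos, ref=ref, alt=alt_n,
                        tumor_ref_depth=ref_d, tumor_alt_depth=alt_d,
                        population_af=_info_float(rec, "POP_AF"),
                        cohort_recurrence=_info_float(rec, "REC"),
                        filter_flags=flags,
                    ))
            except (ValueError, KeyError, TypeError) as exc:
                raise MalformedRecordError(
                    f"{path}: bad record at {rec.chrom}:{rec.pos}: {exc}") from exc
    return out


def write_germline_vcf(variants: list[SomaticVariant], path: str | Path,
                       contigs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, somatic=False))
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tAD"
                     f"\t{v.tumor_ref_depth},{v.tumor_alt_depth}\n")


read_germline_vcf = read_somatic_vcf


# ---------------------------------------------------------------------------
# CNA segments (TSV)

CNA_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]


def write_cna_tsv(segments: list[CnaSegment], path: str | Path) -> None:
    rows = [{"chrom": s.chrom, "start": s.start, "end": s.end,
             "total_cn": s.total_cn,
             "minor_cn": "" if s.minor_cn is None else s.minor_cn}
            for s in segments]
    pd.DataFrame(rows, columns=CNA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cna_tsv(path: str | Path) -> list[CnaSegment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CNA_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedRecordError(f"{path}: missing CNA columns {sorted(missing)}")
    segs = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            minor = None if pd.isna(r.minor_cn) else float(r.minor_cn)
            segs.append(CnaSegment(chrom=r.chrom, start=int(r.start), end=int(r.end),
                                   total_cn=float(r.total_cn), minor_cn=minor))
        except (ValueError, TypeError) as exc:
            raise MalformedRecordError(f"{path}: line {i}: {exc}") from exc
    return segs


# ---------------------------------------------------------------------------
# Structural variants (VCF with BND bracket notation)


def _sv_header(contigs: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in contigs.items()]
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    lines.append('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    lines.append('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">')
    lines.append('##ALT=<ID=DEL,Description="Deletion">')
    lines.append('##ALT=<ID=DUP,Description="Duplication">')
    lines.append('##ALT=<ID=INV,Description="Inversion">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def _bnd_alt(base: str, here_orient: str, mate: tuple[str, int, str]) -> str:
    mchrom, mpos, morient = mate
    bracket = "]" if morient == "+" else "["
    locus = f"{bracket}{mchrom}:{mpos}{bracket}"
    return base + locus if here_orient == "+" else locus + base


def write_sv_vcf(svs: list[StructuralVariant], path: str | Path,
                 contigs: dict[str, int], genome: dict[str, str] | None = None) -> None:
    def base_at(chrom: str, pos: int) -> str:
        return genome[chrom][pos - 1] if genome else "N"

    with open(path, "w") as fh:
        fh.write(_sv_header(contigs))
        for i, sv in enumerate(svs):
            sv_id = sv.sv_id or f"SV{i:04d}"
            (c1, p1, o1), (c2, p2, o2) = sv.breakpoint_a, sv.breakpoint_b
            if sv.svtype == "BND":
                fh.write(f"{c1}\t{p1}\t{sv_id}_1\t{base_at(c1, p1)}\t"
                         f"{_bnd_alt(base_at(c1, p1), o1, sv.breakpoint_b)}\t.\tPASS\t"
                         f"SVTYPE=BND;MATEID={sv_id}_2\n")
                fh.write(f"{c2}\t{p2}\t{sv_id}_2\t{base_at(c2, p2)}\t"
                         f"{_bnd_alt(base_at(c2, p2), o2, sv.breakpoint_a)}\t.\tPASS\t"
                         f"SVTYPE=BND;MATEID={sv_id}_1\n")
            else:
                fh.write(f"{c1}\t{p1}\t{sv_id}\t{base_at(c1, p1)}\t<{sv.svtype}>\t.\tPASS\t"
                         f"SVTYPE={sv.svtype};END={p2}\n")


_BND_RE = re.compile(r"^(?P<pre>[ACGTN]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<b2>[\[\]])(?P<post>[ACGTN]*)$")


def read_sv_vcf(path: str | Path) -> list[StructuralVariant]:
    svs: list[StructuralVariant] = []
    seen_mates: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE", "BND")
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            if svtype == "BND":
                if rid in seen_mates:
                    continue
                mate_id = rec.info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                if mate_id:
                    seen_mates.add(mate_id)
                m = _BND_RE.match(rec.alts[0])
                if not m:
                    raise MalformedRecordError(
                        f"{path}: unparsable breakend ALT {rec.alts[0]!r} at {rec.chrom}:{rec.pos}")
                here_orient = "+" if m.group("pre") else "-"
                mate_orient = "+" if m.group("b1") == "]" else "-"
                svs.append(StructuralVariant(
                    svtype="BND",
                    breakpoint_a=(rec.chrom, rec.pos, here_orient),
                    breakpoint_b=(m.group("chrom"), int(m.group("pos")), mate_orient),
                    sv_id=rid.rsplit("_", 1)[0] if rid.endswith(("_1", "_2")) else rid,
                ))
            else:
                end = int(rec.info["END"]) if "END" in rec.info else rec.stop
                orients = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}[svtype]
                svs.append(StructuralVariant(
                    svtype=svtype,
                    breakpoint_a=(rec.chrom, rec.pos, orients[0]),
                    breakpoint_b=(rec.chrom, end, orients[1]),
                    sv_id=rid,
                ))
    return svs


# ---------------------------------------------------------------------------
# Clinical tables (TSV)

from dataclasses import dataclass, field  # noqa: E402

REGISTRY_COLUMNS = ["participant_id", "diagnosis_date", "icd10_site", "morphology_code",
                    "behavior", "stage_best", "figo_stage", "dukes_stage"]
EPISODE_COLUMNS = ["participant_id", "appointment_date", "primary_diagnosis_icd10",
                   "operation_codes"]
TREATMENT_COLUMNS = ["participant_id", "treatment_date", "treatment_class", "drug"]
DEATH_COLUMNS = ["participant_id", "death_date"]

_DATE_COLUMNS = {"diagnosis_date", "appointment_date", "treatment_date", "death_date"}


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class ClinicalBundle:
    """Registry, episode, treatment and mortality tables for a cohort."""

    registry: pd.DataFrame = field(default_factory=lambda: _empty(REGISTRY_COLUMNS))
    episodes: pd.DataFrame = field(default_factory=lambda: _empty(EPISODE_COLUMNS))
    treatments: pd.DataFrame = field(default_factory=lambda: _empty(TREATMENT_COLUMNS))
    deaths: pd.DataFrame = field(default_factory=lambda: _empty(DEATH_COLUMNS))

    def for_participant(self, participant_id: str) -> "ClinicalBundle":
        return ClinicalBundle(*[
            df[df["participant_id"] == participant_id]
            for df in (self.registry, self.episodes, self.treatments, self.deaths)
        ])


_CLINICAL_FILES = {
    "registry": ("registry.tsv", REGISTRY_COLUMNS),
    "episodes": ("episodes.tsv", EPISODE_COLUMNS),
    "treatments": ("treatments.tsv", TREATMENT_COLUMNS),
    "deaths": ("deaths.tsv", DEATH_COLUMNS),
}


def write_clinical_bundle(bundle: ClinicalBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, (name, _) in _CLINICAL_FILES.items():
        write_clinical_table(getattr(bundle, attr), outdir / name)


def read_clinical_bundle(indir: str | Path) -> ClinicalBundle:
    indir = Path(indir)
    return ClinicalBundle(**{
        attr: read_clinical_table(indir / name, columns)
        for attr, (name, columns) in _CLINICAL_FILES.items()
    })


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {sorted(missing)}")
    for col in set(df.columns) & _DATE_COLUMNS:
        df[col] = pd.to_datetime(df[col]).dt.date
    return df
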
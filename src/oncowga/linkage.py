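"""Linkage of cases to registry and hospital-episode data.

The submitted tumor type is corroborated by an ordered cascade: registry
entry first; otherwise the nearest-in-time hospital episode with a primary
cancer diagnosis mapping to the submitted type; otherwise three fallback
approaches (curated operation codes on the exact sampling date; flexible
ICD-10 matching within 7 days for a restricted set of registry/submission
pairs; the submission's own ICD-10 code). Benign and in-situ registry
tumors are excluded before the cascade.

Stage comes from the registry: metastatic submissions are stage 4 by
default; otherwise FIGO staging for ovarian/endometrial indications, Dukes
staging for colorectal adenocarcinomas, and stage_best elsewhere, provided
the diagnosis date lies within 365 days of sampling.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .config import PipelineConfig
from .types import LinkageOutcome, TumorCase

# Toy ICD-10 site -> tumor-type map (3-character prefixes). "colorectal" is a
# registry-only label used by the flexible-match pair table.
DEFAULT_ICD10_MAP: dict[str, str] = {
    "C50": "breast_invasive_carcinoma",
    "C18": "colon_adenocarcinoma",
    "C43": "skin_cutaneous_melanoma",
    "C34": "lung_adenocarcinoma",
    "C56": "ovarian_high_grade_serous",
    "C71": "glioblastoma",
    "C20": "colorectal",
}

# Curated operation-code map (toy defaults, editable resource).
DEFAULT_OPCODE_MAP: dict[str, str] = {
    "OP_BRE": "breast_invasive_carcinoma",
    "OP_COL": "colon_adenocarcinoma",
    "OP_MEL": "skin_cutaneous_melanoma",
    "OP_LUN": "lung_adenocarcinoma",
    "OP_OVA": "ovarian_high_grade_serous",
    "OP_GBM": "glioblastoma",
}

FIGO_TYPES = {"ovarian_high_grade_serous", "endometrial_carcinoma"}
DUKES_TYPES = {"colon_adenocarcinoma", "rectum_adenocarcinoma"}

_DUKES = {"A": 1, "B": 2, "C": 3, "D": 4}
_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


def map_icd10(code: str | None, icd10_map: dict[str, str]) -> str | None:
    if not code or not isinstance(code, str):
        return None
    return icd10_map.get(code.strip()[:3].upper())


def _clean_registry(registry: pd.DataFrame) -> pd.DataFrame:
    keep = ~registry["behavior"].isin(["benign", "in_situ"])
    return registry[keep].sort_values(["diagnosis_date", "icd10_site"], kind="stable")


def corroborate_diagnosis(case: TumorCase, registry: pd.DataFrame,
                          episodes: pd.DataFrame,
                          icd10_map: dict[str, str] | None = None,
                          opcode_map: dict[str, str] | None = None,
                          config: PipelineConfig | None = None) -> LinkageOutcome:
    """Corroborate the submitted tumor type; rows are for one participant."""
    if case.sample_date is None:
        raise ValueError(f"case {case.case_id}: missing sample date")
    icd10_map = icd10_map if icd10_map is not None else DEFAULT_ICD10_MAP
    opcode_map = opcode_map if opcode_map is not None else DEFAULT_OPCODE_MAP
    cfg = config or PipelineConfig()
    registry = _clean_registry(registry)

    # 1. registry confirmation
    for row in registry.itertuples():
        if map_icd10(row.icd10_site, icd10_map) == case.tumor_type:
            return LinkageOutcome(status="registry_confirmed",
                                  matched_tumor_type=case.tumor_type,
                                  evidence=f"registry {row.icd10_site}")

    # 2. nearest type-matching cancer episode (ties: earlier date wins)
    cancer = episodes[episodes["primary_diagnosis_icd10"].map(
        lambda c: map_icd10(c, icd10_map) is not None).astype(bool)]
    matching = cancer[cancer["primary_diagnosis_icd10"].map(
        lambda c: map_icd10(c, icd10_map) == case.tumor_type).astype(bool)]
    if len(matching):
        best = min(matching.itertuples(),
                   key=lambda r: (abs((r.appointment_date - case.sample_date).days),
                                  r.appointment_date))
        return LinkageOutcome(status="hes_confirmed", matched_tumor_type=case.tumor_type,
                              evidence=f"episode {best.primary_diagnosis_icd10} "
                                       f"on {best.appointment_date}")

    # 3a. curated operation code on the exact sampling date (primary tumors)
    if not case.submitted_metastatic:
        for row in episodes.sort_values("appointment_date", kind="stable").itertuples():
            if row.appointment_date != case.sample_date:
                continue
            codes = str(row.operation_codes).split(",") if pd.notna(row.operation_codes) else []
            if any(opcode_map.get(c.strip()) == case.tumor_type for c in codes):
                return LinkageOutcome(status="operation_code_confirmed",
                                      matched_tumor_type=case.tumor_type,
                                      evidence=f"operation on {row.appointment_date}")

    # 3b. flexible ICD-10 match for restricted registry/submission pairs
    if case.submitted_metastatic:
        registry_types = {map_icd10(r.icd10_site, icd10_map) for r in registry.itertuples()}
        allowed = any(case.tumor_type in cfg.flexible_match_pairs.get(rt, set())
                      for rt in registry_types if rt)
        if allowed and any(
                abs((r.appointment_date - case.sample_date).days) < cfg.flexible_match_max_days
                for r in cancer.itertuples()):
            return LinkageOutcome(status="flexible_match_confirmed",
                                  matched_tumor_type=case.tumor_type,
                                  evidence="registry/submission pair with episode within 7 days")

    # 3c. submitted ICD-10 / morphology codes
    if map_icd10(case.submitted_icd10, icd10_map) == case.tumor_type:
        return LinkageOutcome(status="gmc_code_confirmed",
                              matched_tumor_type=case.tumor_type,
                              evidence=f"submitted code {case.submitted_icd10}")

    return LinkageOutcome(status="unmatched")


def _parse_stage_best(value) -> int | None:
    s = str(value).strip()
    return int(s[0]) if s[:1] in "1234" else None


def _parse_figo(value) -> int | None:
    s = str(value).strip().upper().rstrip("ABC")
    return _ROMAN.get(s)


def _parse_dukes(value) -> int | None:
    return _DUKES.get(str(value).strip().upper()[:1])


def resolve_stage(case: TumorCase, registry: pd.DataFrame,
                  config: PipelineConfig | None = None) -> int | None:
    """Resolve stage 1-4 (None = unknown) from the registry."""
    cfg = config or PipelineConfig()
    if case.submitted_metastatic:
        return 4
    if case.tumor_type in FIGO_TYPES:
        column, parse = "figo_stage", _parse_figo
    elif case.tumor_type in DUKES_TYPES:
        column, parse = "dukes_stage", _parse_dukes
    else:
        column, parse = "stage_best", _parse_stage_best
    registry = _clean_registry(registry)
    candidates = []
    for row in registry.itertuples():
        value = getattr(row, column)
        if pd.isna(value) or str(value).strip() == "":
            continue
        delta = abs((row.diagnosis_date - case.sample_date).days)
        if delta < cfg.stage_max_days:
            candidates.append((delta, row.diagnosis_date, value))
    if not candidates:
        return None
    _, _, value = min(candidates, key=lambda c: (c[0], c[1]))
    stage = parse(value)
    if stage is None:
        warnings.warn(f"case {case.case_id}: unmapped {column} code {value!r}",
                      stacklevel=2)
    return stage
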
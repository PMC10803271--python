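"""Pangenomic markers: TMB, mutational catalogs, signature refitting,
etiology grouping, MMR status and HRD classifier concordance.

TMB is the number of nonsynonymous high-confidence somatic small variants
per megabase of coding sequence. Per-tumor 96-context catalogs are refit
against a fixed signature matrix by non-negative least squares; exposures
are grouped into etiologies (APOBEC: SBS2+13; aging: SBS1; HRD: SBS3; MMR
deficiency: SBS6, 15, 20, 21, 26, 44; POLE: SBS10a, 10b, 14; smoking:
SBS4+92; UV: SBS7a-d). SBS14 sits in the POLE group only, to avoid double
counting. Groups contributing less than 20% are reassigned to "other"; a
tumor is MMR-deficient when the MMR group exceeds 20%.

HRD classifiers themselves are upstream inputs; only their pairwise
concordance is computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .config import PipelineConfig
from .trinuc import CONTEXT_INDEX, context_label
from .types import (
    PROTEIN_ALTERING_CONSEQUENCES,
    EtiologyResult,
    HrdCall,
    SignatureExposure,
    SomaticVariant,
)

ETIOLOGY_SIGNATURES: dict[str, frozenset[str]] = {
    "apobec": frozenset({"SBS2", "SBS13"}),
    "aging": frozenset({"SBS1"}),
    "hrd": frozenset({"SBS3"}),
    "mmr": frozenset({"SBS6", "SBS15", "SBS20", "SBS21", "SBS26", "SBS44"}),
    "pole": frozenset({"SBS10a", "SBS10b", "SBS14"}),
    "smoking": frozenset({"SBS4", "SBS92"}),
    "uv": frozenset({"SBS7a", "SBS7b", "SBS7c", "SBS7d"}),
}


def compute_tmb(variants: list[SomaticVariant], coding_megabases: float) -> float:
    """Nonsynonymous, unflagged small variants per coding megabase."""
    if coding_megabases <= 0:
        raise ValueError("coding footprint must be positive")
    n = sum(1 for v in variants
            if v.is_high_confidence and v.consequence in PROTEIN_ALTERING_CONSEQUENCES)
    return n / coding_megabases


def build_catalog(snvs: list[SomaticVariant], genome: dict[str, str]) -> np.ndarray:
    """96-context catalog of SNVs (pyrimidine-strand convention; indels skipped)."""
    counts = np.zeros(96, dtype=int)
    for v in snvs:
        if v.vtype != "SNV":
            continue
        seq = genome[v.chrom]
        if not 2 <= v.pos <= len(seq) - 1:
            raise ValueError(f"site {v.chrom}:{v.pos} too close to a contig end")
        trinuc = seq[v.pos - 2: v.pos + 1].upper()
        if trinuc[1] != v.ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: genome {trinuc[1]}, variant {v.ref}")
        counts[CONTEXT_INDEX[context_label(trinuc, v.alt)]] += 1
    return counts


def fit_exposures(catalog: np.ndarray, signatures: pd.DataFrame) -> SignatureExposure:
    """Non-negative least-squares refit of a catalog against the matrix.

    Exposures are returned as fractions of the assigned (fitted) mass; the
    relative L2 reconstruction residual is reported alongside.
    """
    catalog = np.asarray(catalog, dtype=float)
    total = catalog.sum()
    if total <= 0:
        raise ValueError("catalog is empty")
    coef, rnorm = optimize.nnls(signatures.to_numpy(), catalog)
    assigned = coef.sum()
    fractions = {name: (c / assigned if assigned > 0 else 0.0)
                 for name, c in zip(signatures.columns, coef)}
    return SignatureExposure(fractions=fractions,
                             residual=rnorm / np.linalg.norm(catalog),
                             n_mutations=int(round(total)))


class SignatureRefitter:
    """Small fit-style wrapper around :func:`fit_exposures`."""

    def __init__(self, signatures: pd.DataFrame):
        self.signatures = signatures

    def fit(self, catalog: np.ndarray) -> SignatureExposure:
        return fit_exposures(catalog, self.signatures)


def classify_etiologies(exposure: SignatureExposure,
                        config: PipelineConfig | None = None) -> EtiologyResult:
    """Group exposures by etiology, apply the 20% display rule, call MMR."""
    cfg = config or PipelineConfig()
    raw = {etiology: sum(exposure.fractions.get(s, 0.0) for s in sigs)
           for etiology, sigs in ETIOLOGY_SIGNATURES.items()}
    grouped_mass = sum(raw.values())
    other = max(0.0, 1.0 - grouped_mass)  # signatures outside every etiology
    groups = {}
    for etiology, frac in raw.items():
        if frac < cfg.etiology_other_threshold:
            other += frac
        else:
            groups[etiology] = frac
    mmr_deficient = raw["mmr"] > cfg.mmr_threshold
    return EtiologyResult(groups=groups, other_fraction=other,
                          mmr_deficient=mmr_deficient)


def hrd_concordance(calls_a: list[HrdCall], calls_b: list[HrdCall]
                    ) -> tuple[float, int, int]:
    """Fraction of cases on which two HRD classifiers agree.

    Returns (fraction, n_matching, n_compared); cases where either call is
    unknown are excluded pairwise.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call lists must cover the same cases")
    pairs = [(a.status, b.status) for a, b in zip(calls_a, calls_b)
             if a.status != "unknown" and b.status != "unknown"]
    if not pairs:
        raise ValueError("no comparable cases")
    matches = sum(1 for a, b in pairs if a == b)
    return matches / len(pairs), matches, len(pairs)
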
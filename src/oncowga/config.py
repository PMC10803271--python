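"""Pipeline thresholds.

Every threshold printed in the study protocol is a default here and can be
overridden from a YAML/JSON mapping. Inequalities are applied exactly as
worded: "more than" / "lower than" are strict, "at least" is inclusive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- sequencing QC gate ---
    min_normal_yield_gb: float = 85.0
    min_tumor_yield_gb: float = 210.0
    min_autosome_cov15_frac: float = 0.95
    max_normal_contamination: float = 0.03
    max_tumor_contamination: float = 0.025

    # --- somatic filter cascade ---
    max_population_af: float = 0.01       # flag if AF > 1%
    max_cohort_recurrence: float = 0.05   # flag if recurrence > 5%
    noisy_window_radius: int = 50         # bases either side of an indel
    noisy_window_min_fraction: float = 0.10  # flag if >= 10% base calls failed
    pon_min_phred: float = 50.0           # flag SNVs with Fisher Phred < 50
    pon_fisher_alternative: str = "two-sided"
    pon_default_ref_depth: int = 1500     # aggregated panel ref depth at sites absent from the panel
    # Panel individuals whose alt fraction at the site is at least this are
    # treated as germline carriers of the alternate allele and excluded from
    # the aggregated panel depths.
    pon_carrier_min_alt_fraction: float = 0.3

    # --- CNA / SV actionability ---
    min_cna_purity: float = 0.30          # strict: purity must exceed 30%
    gain_multiplier: float = 2.0          # gain if CN >= multiplier * ploidy
    cn_neutral_tolerance: float = 0.5     # |total_cn - ploidy| for copy-neutral LOH

    # --- germline reporting ---
    min_clinvar_stars: int = 2
    germline_tumor_type_restricted: bool = True

    # --- pangenomic markers ---
    etiology_other_threshold: float = 0.20  # groups below this go to "other"
    mmr_threshold: float = 0.20             # MMR-deficient if MMR group > 20%

    # --- clinical linkage ---
    flexible_match_max_days: int = 7      # strict: |delta| < 7 days
    stage_max_days: int = 365             # strict: |delta| < 365 days
    # Registry-vs-submission pairs allowed the flexible (approach 2) match:
    # registry tumor type -> set of submitted tumor types.
    flexible_match_pairs: dict[str, set[str]] = field(
        default_factory=lambda: {
            "colorectal": {"hepato_pancreatobiliary", "endometrial_carcinoma", "lung_adenocarcinoma"},
        }
    )

    # --- cohort analytics ---
    multiple_testing_method: str = "fdr_bh"  # or "bonferroni"
    survival_alpha: float = 0.05

    def override(self, mapping: dict) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        names = {f.name for f in dataclasses.fields(self)}
        bad = set(mapping) - names
        if bad:
            raise KeyError(f"unknown config keys: {sorted(bad)}")
        return dataclasses.replace(self, **mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "flexible_match_pairs" in data:
            data["flexible_match_pairs"] = {
                k: set(v) for k, v in data["flexible_match_pairs"].items()
            }
        return cls().override(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flexible_match_pairs"] = {
            k: sorted(v) for k, v in d["flexible_match_pairs"].items()
        }
        return d
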
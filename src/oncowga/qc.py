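"""Sequencing-quality gate for tumor-normal pairs.

A pair enters interpretation only if the normal genome yields more than
85 Gb and the tumor more than 210 Gb of high-quality data, more than 95% of
the normal autosomal genome is covered at 15x or more, cross-patient
contamination is below 3% (normal) and 2.5% (tumor), and the pair is
concordant (same patient). All comparisons are strict, as worded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import PipelineConfig
from .types import QcMetrics


@dataclass
class QcResult:
    passed: bool
    reasons: list[str]


def qc_gate(metrics: QcMetrics, config: PipelineConfig | None = None) -> QcResult:
    """Evaluate the QC gate; ``reasons`` lists every violated threshold."""
    cfg = config or PipelineConfig()
    reasons = []
    if not metrics.normal_yield_gb > cfg.min_normal_yield_gb:
        reasons.append("normal_yield")
    if not metrics.tumor_yield_gb > cfg.min_tumor_yield_gb:
        reasons.append("tumor_yield")
    if not metrics.normal_autosome_cov15_frac > cfg.min_autosome_cov15_frac:
        reasons.append("autosome_cov15")
    if not metrics.normal_contamination < cfg.max_normal_contamination:
        reasons.append("normal_contamination")
    if not metrics.tumor_contamination < cfg.max_tumor_contamination:
        reasons.append("tumor_contamination")
    if not metrics.pair_concordant:
        reasons.append("pair_concordance")
    return QcResult(passed=not reasons, reasons=reasons)
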
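"""Cohort-level analytics.

Three outputs: (a) actionability prevalence per tumor type, gene and
variant class, split by whether the finding is in a gene indicated for
testing in that tumor type; (b) per-gene co-occurrence of copy-number
events with somatic small variants (Fisher's exact test with
Benjamini-Hochberg correction); (c) survival stratification with
Kaplan-Meier estimates, a stage-stratified log-rank test and a Cox
proportional-hazards model with stage as a categorical covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .types import (
    PROTEIN_ALTERING_CONSEQUENCES,
    CnaSegment,
    GeneModel,
    SomaticVariant,
)

# ---------------------------------------------------------------------------
# Actionability prevalence


def summarize_actionability(cases: pd.DataFrame, findings: pd.DataFrame,
                            genes: dict[str, GeneModel]) -> pd.DataFrame:
    """Prevalence of findings per (tumor_type, gene, variant_class).

    ``cases``: one row per case with columns case_id, tumor_type,
    cna_eligible (bool). ``findings``: one row per finding with columns
    case_id, gene, variant_class. The denominator for CNA findings is the
    purity-eligible subset of the type; fractions are split into
    indicated (gene/class in the test directory for that type) and
    non-indicated. A combined ``any_indicated`` row per tumor type gives
    the fraction of cases with one or more indicated findings.
    """
    merged = findings.merge(cases, on="case_id", how="left")
    rows = []
    any_indicated: dict[str, set] = {}
    for (tumor_type, gene_name, vclass), grp in merged.groupby(
            ["tumor_type", "gene", "variant_class"]):
        gene = genes.get(gene_name)
        indicated = bool(gene is not None
                         and tumor_type in gene.directory_indications
                         and vclass in gene.directory_variant_classes)
        of_type = cases[cases["tumor_type"] == tumor_type]
        if vclass == "cna":
            denominator = int(of_type["cna_eligible"].sum())
        else:
            denominator = len(of_type)
        n_with = grp["case_id"].nunique()
        rows.append({"tumor_type": tumor_type, "gene": gene_name,
                     "variant_class": vclass, "indicated": indicated,
                     "n_cases": denominator, "n_with": n_with,
                     "fraction": n_with / denominator if denominator else np.nan})
        if indicated:
            any_indicated.setdefault(tumor_type, set()).update(grp["case_id"])
    out = pd.DataFrame(rows, columns=["tumor_type", "gene", "variant_class",
                                      "indicated", "n_cases", "n_with", "fraction"])
    combined = []
    for tumor_type, of_type in cases.groupby("tumor_type"):
        hits = any_indicated.get(tumor_type, set())
        combined.append({"tumor_type": tumor_type, "gene": "ANY",
                         "variant_class": "any_indicated", "indicated": True,
                         "n_cases": len(of_type), "n_with": len(hits),
                         "fraction": len(hits) / len(of_type)})
    return pd.concat([out, pd.DataFrame(combined)], ignore_index=True)


# ---------------------------------------------------------------------------
# Co-occurrence of CNAs and small variants


def cooccurrence_test(events: pd.DataFrame,
                      config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-gene association between small variants and CNA events.

    ``events``: one row per (case, gene) with boolean columns small_variant
    and cna_event. Cases are split by small-variant status and the CNA
    frequency is compared between the two strata by Fisher's exact test;
    q-values are Benjamini-Hochberg across testable genes.
    """
    cfg = config or PipelineConfig()
    rows = []
    for gene, grp in events.groupby("gene"):
        with_sv = grp[grp["small_variant"]]
        without_sv = grp[~grp["small_variant"]]
        a = int(with_sv["cna_event"].sum())
        b = len(with_sv) - a
        c = int(without_sv["cna_event"].sum())
        d = len(without_sv) - c
        if len(with_sv) == 0 or len(without_sv) == 0:
            p = np.nan
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]])[1])
        rows.append({"gene": gene, "n_with_sv": len(with_sv),
                     "n_without_sv": len(without_sv),
                     "cna_frac_with": a / len(with_sv) if len(with_sv) else np.nan,
                     "cna_frac_without": c / len(without_sv) if len(without_sv) else np.nan,
                     "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    testable = out["p_value"].notna()
    if testable.any():
        out.loc[testable, "q_value"] = multipletests(
            out.loc[testable, "p_value"], method=cfg.multiple_testing_method)[1]
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene mutation status for survival stratification


def gene_mutation_status(variants: list[SomaticVariant],
                         segments: list[CnaSegment], gene: GeneModel) -> bool:
    """Mutated: protein-altering small variant, or homozygous deletion (TSGs)."""
    if any(v.gene == gene.gene and v.consequence in PROTEIN_ALTERING_CONSEQUENCES
           for v in variants):
        return True
    if gene.is_tsg:
        return any(s.overlaps(gene.chrom, gene.start, gene.end) and s.total_cn <= 1e-6
                   for s in segments)
    return False


# ---------------------------------------------------------------------------
# Survival analysis


@dataclass
class SurvivalStratification:
    grouping: str
    group_sizes: dict[str, int]
    hazard_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    cox_p: float | None
    logrank_p: float | None
    notes: str = ""
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)


def stratified_logrank(time: np.ndarray, event: np.ndarray, group: np.ndarray,
                       strata: np.ndarray | None = None) -> tuple[float, float]:
    """Log-rank test for k groups, optionally stratified.

    Observed-minus-expected vectors and their covariance are accumulated
    within each stratum and summed; the statistic is chi-squared with k-1
    degrees of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    strata = np.zeros(len(time)) if strata is None else np.asarray(strata)
    z = np.zeros(k - 1)
    v = np.zeros((k - 1, k - 1))
    for s in np.unique(strata):
        m = strata == s
        t, e, g = time[m], event[m], group[m]
        for t_i in np.unique(t[e]):
            at_risk = t >= t_i
            n = at_risk.sum()
            d = (e & (t == t_i)).sum()
            if n < 2 or d == 0:
                continue
            n_j = np.array([(at_risk & (g == lab)).sum() for lab in labels], dtype=float)
            d_j = np.array([(e & (t == t_i) & (g == lab)).sum() for lab in labels], dtype=float)
            expected = d * n_j / n
            z += (d_j - expected)[:-1]
            if n > 1:
                factor = d * (n - d) / (n - 1)
                for a in range(k - 1):
                    for b in range(k - 1):
                        delta = 1.0 if a == b else 0.0
                        v[a, b] += factor * (n_j[a] / n) * (delta - n_j[b] / n)
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    return chi2, float(stats.chi2.sf(chi2, k - 1))


def km_curves(df: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier curve data per group (time, at-risk, survival, CI)."""
    frames = []
    for label, grp in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(label))
        curve = pd.DataFrame({
            "group": str(label),
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_low": kmf.confidence_interval_.iloc[:, 0].to_numpy(),
            "ci_high": kmf.confidence_interval_.iloc[:, 1].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(
                kmf.survival_function_.index).to_numpy(),
        })
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def survival_analysis(df: pd.DataFrame, grouping: str = "group",
                      config: PipelineConfig | None = None) -> SurvivalStratification:
    """Two-group stage-corrected survival comparison.

    ``df`` carries time (days), event (1 = death observed), group (two
    labels; the lexicographically smaller is the reference) and stage
    (1-4 or NaN). Unknown-stage cases are excluded from the stage-corrected
    model and the stratified log-rank test.
    """
    cfg = config or PipelineConfig()
    df = df.copy()
    labels = sorted(df["group"].astype(str).unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    sizes = df.groupby("group").size().to_dict()
    events_per_group = df.groupby("group")["event"].sum()
    curves = km_curves(df)
    if (events_per_group == 0).any():
        empty = [str(g) for g, n in events_per_group.items() if n == 0]
        return SurvivalStratification(
            grouping=grouping, group_sizes=sizes, hazard_ratio=None,
            ci_low=None, ci_high=None, cox_p=None, logrank_p=None,
            notes=f"no events in group(s) {empty}; HR undefined", curves=curves)

    staged = df.dropna(subset=["stage"]).copy()
    staged["stage"] = staged["stage"].astype(int)
    staged["exposed"] = (staged["group"].astype(str) == labels[1]).astype(int)
    chi2, logrank_p = stratified_logrank(staged["time"].to_numpy(),
                                         staged["event"].to_numpy(),
                                         staged["exposed"].to_numpy(),
                                         staged["stage"].to_numpy())
    cph = CoxPHFitter()
    cph.fit(staged[["time", "event", "exposed", "stage"]], duration_col="time",
            event_col="event", formula="exposed + C(stage)")
    hr = float(np.exp(cph.params_["exposed"]))
    ci = cph.confidence_intervals_.loc["exposed"]
    return SurvivalStratification(
        grouping=grouping, group_sizes=sizes, hazard_ratio=hr,
        ci_low=float(np.exp(ci.iloc[0])), ci_high=float(np.exp(ci.iloc[1])),
        cox_p=float(cph.summary.loc["exposed", "p"]), logrank_p=logrank_p,
        notes=f"{len(staged)} of {len(df)} cases with known stage analyzed",
        curves=curves)


def tmb_quartile_groups(tmb: pd.Series) -> tuple[pd.Series, dict[str, float]]:
    """Label lowest/highest TMB quartile within a tumor-type subset.

    Returns per-case labels ("low", "high" or None for the middle two
    quartiles) and the median TMB of each labelled group.
    """
    q1, q3 = np.quantile(tmb, [0.25, 0.75])
    labels = pd.Series(index=tmb.index, dtype=object)
    labels[tmb <= q1] = "low"
    labels[tmb >= q3] = "high"
    medians = {"low": float(tmb[labels == "low"].median()),
               "high": float(tmb[labels == "high"].median())}
    return labels, medians
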
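"""Cohort analytics: prevalence, co-occurrence, survival machinery."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from oncowga.analytics import (
    cooccurrence_test,
    gene_mutation_status,
    km_curves,
    stratified_logrank,
    summarize_actionability,
    survival_analysis,
    tmb_quartile_groups,
)
from oncowga.types import CnaSegment, SomaticVariant

# ---------------------------------------------------------------------------
# Actionability prevalence


def _cases_frame():
    rows = []
    for i in range(100):
        rows.append({"case_id": f"B{i}", "tumor_type": "breast_invasive_carcinoma",
                     "cna_eligible": i < 80})
    for i in range(50):
        rows.append({"case_id": f"G{i}", "tumor_type": "glioblastoma",
                     "cna_eligible": True})
    return pd.DataFrame(rows)


def test_prevalence_fractions_and_directory_split(bundle):
    cases = _cases_frame()
    findings = pd.DataFrame(
        [{"case_id": f"B{i}", "gene": "PIK3CA", "variant_class": "small_variant"}
         for i in range(60)]
        + [{"case_id": f"G{i}", "gene": "PIK3CA", "variant_class": "small_variant"}
           for i in range(5)])
    matrix = summarize_actionability(cases, findings, bundle.genes)
    breast = matrix[(matrix["tumor_type"] == "breast_invasive_carcinoma")
                    & (matrix["gene"] == "PIK3CA")].iloc[0]
    assert breast["indicated"] and breast["fraction"] == pytest.approx(0.60)
    gbm = matrix[(matrix["tumor_type"] == "glioblastoma")
                 & (matrix["gene"] == "PIK3CA")].iloc[0]
    assert not gbm["indicated"]                     # off-directory partition
    assert gbm["fraction"] == pytest.approx(0.10)
    any_breast = matrix[(matrix["tumor_type"] == "breast_invasive_carcinoma")
                        & (matrix["variant_class"] == "any_indicated")].iloc[0]
    assert any_breast["fraction"] == pytest.approx(0.60)
    any_gbm = matrix[(matrix["tumor_type"] == "glioblastoma")
                     & (matrix["variant_class"] == "any_indicated")].iloc[0]
    assert any_gbm["fraction"] == 0.0


def test_cna_denominator_is_purity_eligible_subset(bundle):
    cases = _cases_frame()
    findings = pd.DataFrame(
        [{"case_id": f"B{i}", "gene": "RB1", "variant_class": "cna"}
         for i in range(40)])
    matrix = summarize_actionability(cases, findings, bundle.genes)
    row = matrix[(matrix["gene"] == "RB1") & (matrix["variant_class"] == "cna")].iloc[0]
    assert row["n_cases"] == 80
    assert row["fraction"] == pytest.approx(0.5)


def test_prevalence_invariant_to_case_order(bundle):
    cases = _cases_frame()
    findings = pd.DataFrame(
        [{"case_id": f"B{i}", "gene": "TP53", "variant_class": "small_variant"}
         for i in range(30)])
    a = summarize_actionability(cases, findings, bundle.genes)
    b = summarize_actionability(cases.sample(frac=1, random_state=1),
                                findings.sample(frac=1, random_state=2),
                                bundle.genes)
    key = ["tumor_type", "gene", "variant_class"]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    assert (merged["fraction_a"] == merged["fraction_b"]).all()


# ---------------------------------------------------------------------------
# Co-occurrence


def _events(gene, n_sv_cna, n_sv_only, n_cna_only, n_neither, gene_name="G"):
    rows = []
    for i, (sv, cna) in enumerate(
            [(True, True)] * n_sv_cna + [(True, False)] * n_sv_only
            + [(False, True)] * n_cna_only + [(False, False)] * n_neither):
        rows.append({"case_id": f"c{i}", "gene": gene_name,
                     "small_variant": sv, "cna_event": cna})
    return pd.DataFrame(rows)


def _fisher_oracle(a, b, c, d):
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
           for k in range(lo, hi + 1)}
    cutoff = pmf[a]
    return float(sum(p for p in pmf.values() if p <= cutoff + cutoff * Fraction(1, 10**9)))


def test_planted_association_is_significant():
    events = _events("G", 40, 10, 10, 140)
    result = cooccurrence_test(events)
    assert result.loc[0, "cna_frac_with"] == pytest.approx(0.8)
    assert result.loc[0, "cna_frac_without"] == pytest.approx(10 / 150)
    assert result.loc[0, "q_value"] < 0.05


def test_fisher_p_matches_brute_force_enumeration():
    events = _events("G", 40, 10, 10, 140)
    result = cooccurrence_test(events)
    assert result.loc[0, "p_value"] == pytest.approx(
        _fisher_oracle(40, 10, 10, 140), rel=1e-9)


def test_empty_stratum_is_flagged_not_crashed():
    events = _events("G", 0, 0, 10, 30)  # nobody carries a small variant
    result = cooccurrence_test(events)
    assert np.isnan(result.loc[0, "p_value"])
    assert np.isnan(result.loc[0, "q_value"])


def test_bh_qvalues_bound_and_monotone(rng):
    frames = []
    for g in range(12):
        a, b, c, d = rng.integers(2, 40, size=4)
        frames.append(_events("G", int(a), int(b), int(c), int(d), gene_name=f"G{g:02d}"))
    result = cooccurrence_test(pd.concat(frames, ignore_index=True))
    assert (result["q_value"] >= result["p_value"] - 1e-12).all()
    ordered = result.sort_values("p_value")
    assert ordered["q_value"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# Gene mutation status for survival


def test_gene_mutation_status_rules(bundle):
    tp53 = bundle.genes["TP53"]
    kras = bundle.genes["KRAS"]
    missense = SomaticVariant(tp53.chrom, tp53.cds_start + 9, "A", "T",
                              gene="TP53", consequence="missense_variant")
    splice_region = SomaticVariant(tp53.chrom, tp53.exons[0][1] + 5, "A", "T",
                                   gene="TP53", consequence="splice_region_variant")
    hom_del = CnaSegment(tp53.chrom, tp53.start - 10, tp53.end + 10, 0.0, 0.0)
    kras_del = CnaSegment(kras.chrom, kras.start - 10, kras.end + 10, 0.0, 0.0)
    assert gene_mutation_status([missense], [], tp53)
    assert not gene_mutation_status([splice_region], [], tp53)
    assert gene_mutation_status([], [hom_del], tp53)       # TSG homozygous deletion
    assert not gene_mutation_status([], [kras_del], kras)  # oncogene deletion ignored


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, Cox


def test_km_matches_hand_computed_product_limit():
    # classic 5-subject fixture: deaths at 6, 10, 15; censored at 7, 19
    df = pd.DataFrame({"time": [6, 7, 10, 15, 19],
                       "event": [1, 0, 1, 1, 0],
                       "group": ["a"] * 5})
    curves = km_curves(df)
    surv = dict(zip(curves["time"], curves["survival"]))
    assert surv[6] == pytest.approx(4 / 5)
    assert surv[10] == pytest.approx(4 / 5 * 2 / 3)
    assert surv[15] == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)
    assert surv[19] == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)  # censoring: no drop


def test_unstratified_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test
    n = 120
    time = rng.exponential(100, size=n)
    group = rng.integers(0, 2, size=n)
    time[group == 1] *= 1.6
    event = rng.random(n) < 0.8
    chi2, p = stratified_logrank(time, event, group)
    ref = logrank_test(time[group == 0], time[group == 1],
                       event[group == 0], event[group == 1])
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
    assert p == pytest.approx(ref.p_value, rel=1e-6)


def test_survival_analysis_recovers_confounded_hr(rng):
    from oncowga.simulate import simulate_survival_dataset
    df = simulate_survival_dataset(2000, 0.5, rng)
    result = survival_analysis(df)
    assert result.ci_low < 0.5 < result.ci_high
    assert result.hazard_ratio == pytest.approx(0.5, abs=0.12)
    assert result.logrank_p < 0.01


def test_stage_correction_removes_confounding_bias(rng):
    """The crude HR is pulled toward 1 by stage confounding; the corrected
    model recovers the truth."""
    from lifelines import CoxPHFitter
    from oncowga.simulate import simulate_survival_dataset
    df = simulate_survival_dataset(4000, 0.5, rng)
    crude = CoxPHFitter()
    work = df.assign(exposed=(df["group"] == "marker_positive").astype(int))
    crude.fit(work[["time", "event", "exposed"]], "time", "event")
    crude_hr = float(np.exp(crude.params_["exposed"]))
    corrected = survival_analysis(df).hazard_ratio
    assert abs(corrected - 0.5) < abs(crude_hr - 0.5)


def test_no_events_in_group_reports_undefined_hr():
    df = pd.DataFrame({"time": [10.0, 20, 30, 40],
                       "event": [0, 0, 1, 1],
                       "group": ["a", "a", "b", "b"],
                       "stage": [1, 2, 1, 2]})
    result = survival_analysis(df)
    assert result.hazard_ratio is None
    assert "no events" in result.notes


def test_all_censored_input_reports_undefined_hr():
    df = pd.DataFrame({"time": [10.0, 20, 30, 40],
                       "event": [0, 0, 0, 0],
                       "group": ["a", "b", "a", "b"],
                       "stage": [1, 1, 2, 2]})
    result = survival_analysis(df)
    assert result.hazard_ratio is None


def test_tmb_quartile_labels():
    tmb = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8])
    labels, medians = tmb_quartile_groups(tmb)
    assert (labels == "low").sum() == 2
    assert (labels == "high").sum() == 2
    assert labels.isna().sum() == 4
    assert medians["low"] < medians["high"]
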
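"""TMB, mutational catalogs, signature refitting, etiologies, HRD concordance."""

import numpy as np
import pytest

from oncowga.markers import (
    ETIOLOGY_SIGNATURES,
    build_catalog,
    classify_etiologies,
    compute_tmb,
    fit_exposures,
    hrd_concordance,
)
from oncowga.reference import synthetic_signature_matrix
from oncowga.trinuc import CONTEXT_INDEX
from oncowga.types import HrdCall, SignatureExposure, SomaticVariant

# ---------------------------------------------------------------------------
# TMB


def _nonsyn(n):
    return [SomaticVariant("chr1", 100 + i, "A", "T", 30, 30,
                           consequence="missense_variant") for i in range(n)]


def test_tmb_worked_example():
    assert compute_tmb(_nonsyn(76), 20.0) == pytest.approx(3.8)


def test_tmb_zero_variants():
    assert compute_tmb([], 20.0) == 0.0


def test_tmb_excludes_flagged_and_non_protein_altering():
    variants = _nonsyn(10)
    for v in variants[:4]:
        v.filter_flags.add("pon_artifact")
    variants.append(SomaticVariant("chr1", 990, "A", "T", 30, 30,
                                   consequence="splice_region_variant"))
    assert compute_tmb(variants, 1.0) == pytest.approx(6.0)


def test_tmb_requires_positive_footprint():
    with pytest.raises(ValueError):
        compute_tmb(_nonsyn(3), 0.0)


# ---------------------------------------------------------------------------
# Catalog construction


def test_catalog_counts_pyrimidine_context():
    genome = {"chr1": "AAACGTTT"}
    v = SomaticVariant("chr1", 4, "C", "T")  # ACG context
    catalog = build_catalog([v], genome)
    assert catalog.sum() == 1
    assert catalog[CONTEXT_INDEX["A[C>T]G"]] == 1


def test_purine_reference_is_reverse_complemented():
    genome = {"chr1": "AACGTTTT"}
    v = SomaticVariant("chr1", 4, "G", "A")  # CGT -> revcomp ACG, G>A -> C>T
    catalog = build_catalog([v], genome)
    assert catalog[CONTEXT_INDEX["A[C>T]G"]] == 1


def test_catalog_strand_involution(bundle, rng):
    """Complementing the genome and flipping alleles leaves the catalog fixed."""
    from oncowga.trinuc import COMPLEMENT
    genome = bundle.genome
    variants = []
    for _ in range(50):
        pos = int(rng.integers(100, 1000))
        ref = genome["chr1"][pos - 1]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        variants.append(SomaticVariant("chr1", pos, ref, alt))
    from oncowga.trinuc import revcomp
    length = len(genome["chr1"])
    flipped_genome = {"chr1": revcomp(genome["chr1"])}
    flipped = [SomaticVariant("chr1", length - v.pos + 1,
                              COMPLEMENT[v.ref], COMPLEMENT[v.alt])
               for v in variants]
    a = build_catalog(variants, genome)
    b = build_catalog(flipped, flipped_genome)
    assert (a == b).all()


def test_catalog_reference_mismatch_errors():
    genome = {"chr1": "AAACGTTT"}
    with pytest.raises(ValueError, match="mismatch"):
        build_catalog([SomaticVariant("chr1", 4, "T", "A")], genome)


def test_simulated_catalog_round_trips_through_builder(bundle, rng):
    from oncowga.simulate import simulate_catalog
    exposures = np.zeros(len(bundle.signatures.columns))
    exposures[list(bundle.signatures.columns).index("SBS1")] = 1.0
    counts, variants = simulate_catalog(exposures, 2000, bundle, rng)
    rebuilt = build_catalog(variants, bundle.genome)
    assert (rebuilt == counts).all()


def test_indels_are_excluded_from_catalog():
    genome = {"chr1": "AAACGTTT"}
    catalog = build_catalog([SomaticVariant("chr1", 4, "CG", "C")], genome)
    assert catalog.sum() == 0


# ---------------------------------------------------------------------------
# Signature refitting


def test_exact_single_signature_recovered():
    sigs = synthetic_signature_matrix()
    catalog = 1000 * sigs["SBS1"].to_numpy()
    exposure = fit_exposures(catalog, sigs)
    assert exposure.fractions["SBS1"] == pytest.approx(1.0, abs=1e-9)
    assert exposure.residual == pytest.approx(0.0, abs=1e-9)


def test_two_signature_mixture_recovered(rng):
    sigs = synthetic_signature_matrix()
    truth = 0.7 * sigs["SBS7a"].to_numpy() + 0.3 * sigs["SBS1"].to_numpy()
    catalog = rng.multinomial(20_000, truth)
    exposure = fit_exposures(catalog, sigs)
    assert exposure.fractions["SBS7a"] == pytest.approx(0.7, abs=0.05)
    assert exposure.fractions["SBS1"] == pytest.approx(0.3, abs=0.05)


def test_residual_non_increasing_with_more_signatures(rng):
    sigs = synthetic_signature_matrix()
    catalog = rng.multinomial(5000, 0.5 * sigs["SBS4"].to_numpy()
                              + 0.5 * sigs["SBS2"].to_numpy())
    subsets = [["SBS4"], ["SBS4", "SBS2"], ["SBS4", "SBS2", "SBS1", "SBS5"],
               list(sigs.columns)]
    residuals = [fit_exposures(catalog, sigs[cols]).residual for cols in subsets]
    assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(residuals, residuals[1:]))


def test_zero_catalog_errors():
    sigs = synthetic_signature_matrix()
    with pytest.raises(ValueError, match="empty"):
        fit_exposures(np.zeros(96), sigs)


# ---------------------------------------------------------------------------
# Etiology grouping and MMR status


def _exposure(fracs):
    return SignatureExposure(fractions=fracs, residual=0.0, n_mutations=1000)


def test_mmr_group_above_threshold_calls_deficiency():
    result = classify_etiologies(_exposure({"SBS6": 0.15, "SBS15": 0.10, "SBS1": 0.75}))
    assert result.mmr_deficient
    assert result.groups["mmr"] == pytest.approx(0.25)


def test_mmr_threshold_is_strict():
    result = classify_etiologies(_exposure({"SBS6": 0.20, "SBS1": 0.80}))
    assert not result.mmr_deficient


def test_small_groups_are_reassigned_to_other():
    result = classify_etiologies(_exposure({"SBS6": 0.15, "SBS10a": 0.30, "SBS1": 0.55}))
    assert "mmr" not in result.groups          # 15% < 20% display rule
    assert result.groups["pole"] == pytest.approx(0.30)
    assert result.other_fraction == pytest.approx(0.15)
    assert not result.mmr_deficient


def test_sbs14_counts_toward_pole_not_mmr():
    result = classify_etiologies(_exposure({"SBS14": 0.5, "SBS1": 0.5}))
    assert result.groups["pole"] == pytest.approx(0.5)
    assert not result.mmr_deficient
    assert "SBS14" not in ETIOLOGY_SIGNATURES["mmr"]
    assert "SBS14" in ETIOLOGY_SIGNATURES["pole"]


def test_unmapped_signatures_fall_into_other():
    result = classify_etiologies(_exposure({"SBS5": 0.6, "SBS7a": 0.4}))
    assert result.groups == {"uv": pytest.approx(0.4)}
    assert result.other_fraction == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# HRD concordance


def _calls(statuses, method="m"):
    return [HrdCall(method=method, status=s) for s in statuses]


def test_hrd_concordance_cohort_counts():
    a = _calls(["positive"] * 2000 + ["negative"] * 8854)
    b = _calls(["positive"] * 2000 + ["negative"] * 8764 + ["positive"] * 90)
    fraction, matches, compared = hrd_concordance(a, b)
    assert (matches, compared) == (10_764, 10_854)
    assert round(100 * fraction, 1) == 99.2


def test_identical_call_lists_are_fully_concordant():
    a = _calls(["positive", "negative", "negative"])
    assert hrd_concordance(a, a)[0] == 1.0


def test_unknowns_are_excluded_pairwise():
    a = _calls(["positive", "unknown", "negative"])
    b = _calls(["negative", "positive", "negative"])
    fraction, matches, compared = hrd_concordance(a, b)
    assert compared == 2 and matches == 1


def test_empty_comparison_errors():
    with pytest.raises(ValueError):
        hrd_concordance(_calls(["unknown"]), _calls(["positive"]))


def test_planted_disagreement_rate_recovered(rng):
    truth = rng.random(1000) < 0.3
    a = _calls(["positive" if t else "negative" for t in truth])
    flip = rng.random(1000) < 0.05
    b = _calls(["positive" if (t != f) else "negative"
                for t, f in zip(truth, flip)])
    fraction, _, compared = hrd_concordance(a, b)
    assert compared == 1000
    assert fraction == pytest.approx(0.95, abs=0.02)
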
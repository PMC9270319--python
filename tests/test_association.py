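"""Case-control pipeline: design construction, homozygote scan,
risk-combination table and genomic inflation."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tyrhap.association import (
    CHI2_1_MEDIAN,
    build_design,
    haplotype_homozygote_scan,
    lambda_from_chi2,
    lambda_gc,
    lambda_gc_from_matrix,
    risk_category,
    risk_combination_table,
)
from tyrhap.cohort import VariantSite
from tyrhap.simulate import (
    PenetranceModel,
    SimulationConfig,
    null_marker_panel,
    simulate_cohort,
)

from conftest import make_call, make_subject


def boosted_config(seed, n=4000, caa=0.10, caa_logor=math.log(50.0), baseline=0.05,
                   protective=None):
    """Single-population cohort with an inflated high-risk haplotype
    frequency so recessive exposures are well populated at modest n."""
    base = {
        "[C;C;G]": 0.28, "[T;C;G]": 0.24, "[C;A;G]": 0.14, "[T;A;G]": 0.08,
        "[C;C;A]": 0.12, "[T;C;A]": 0.04, "[C;A;A]": caa, "[T;A;A]": 0.0,
    }
    total_others = sum(v for k, v in base.items() if k != "[C;A;A]")
    freqs = {
        k: (caa if k == "[C;A;A]" else v * (1 - caa) / total_others)
        for k, v in base.items()
    }
    hom = {"[C;A;A]": caa_logor}
    if protective:
        hom.update(protective)
    return SimulationConfig(
        n_subjects=n,
        ancestry_mix={"European": 1.0},
        haplotype_freqs={"European": freqs},
        penetrance=PenetranceModel(
            intercept=math.log(baseline / (1 - baseline)), hom_haplotype_logor=hom
        ),
        trait_models={},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def make_cohort_for_design():
    subjects = []
    ancestries = ["European"] * 6 + ["African", "AdmixedAmerican", "EastAsian", "SouthAsian"]
    for i, anc in enumerate(ancestries):
        subjects.append(
            make_subject(
                f"S{i}",
                status="case" if i % 2 else "control",
                gender="female" if i % 3 else "male",
                ancestry=anc,
                n_rare_dm=i % 3,
            )
        )
    return subjects


def test_build_design_dummy_coding_and_order():
    subjects = make_cohort_for_design()
    X, y, labels, used = build_design(subjects, lambda s: 0)
    # 5 ancestry levels -> 4 dummies against the largest (European) group
    assert sum(lb.startswith("ancestry[") for lb in labels) == 4
    assert "ancestry[European]" not in labels
    assert labels[:2] == ["intercept", "exposure"]
    assert labels[-1] == "n_rare_dm"
    # intercept + exposure + gender + 4 ancestry dummies + n_rare_dm
    assert X.shape == (10, 8) and len(used) == 10


def test_build_design_exposure_column_is_recessive_indicator(panel):
    subjects = [
        make_subject("A", panel=panel, panel_genotypes=[(0, 0), (1, 1), (1, 1)]),
        make_subject("B", panel=panel, panel_genotypes=[(0, 1), (1, 1), (1, 1)]),
    ]
    from tyrhap.haplotypes import resolve_homozygous

    def exposure(s):
        d = resolve_homozygous(s, panel)
        return 1 if d is not None and d.h1.label == "[C;A;A]" else 0

    X, _, _, _ = build_design(subjects, exposure, covariates=())
    assert X[:, 1].tolist() == [1.0, 0.0]


def test_build_design_drops_single_level_covariate(caplog):
    import logging

    subjects = [make_subject(f"S{i}", status="case" if i % 2 else "control") for i in range(6)]
    with caplog.at_level(logging.WARNING):
        X, _, labels, _ = build_design(subjects, lambda s: 0, covariates=("gender", "ancestry"))
    assert labels == ["intercept", "exposure"]  # both single-level, both dropped


def test_build_design_excludes_subjects_missing_gender():
    subjects = make_cohort_for_design()
    subjects[0].gender = ""
    X, y, _, used = build_design(subjects, lambda s: 0)
    assert len(used) == 9 and X.shape[0] == 9


# ---------------------------------------------------------------------------
# Haplotype homozygote scan
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def scan_cohort(panel):
    cohort = simulate_cohort(boosted_config(seed=101), panel)
    return cohort


@pytest.fixture(scope="module")
def scan_results(scan_cohort, panel):
    return haplotype_homozygote_scan(scan_cohort, panel)


def test_scan_recovers_strong_recessive_risk(scan_results):
    caa = next(r for r in scan_results if r.exposure_label == "[C;A;A]")
    assert caa.estimable
    assert caa.odds_ratio > 20
    assert caa.ci95.lower <= 50.0 <= caa.ci95.upper  # simulated odds ratio
    assert caa.p_value < 1e-6


def test_scan_reports_unobserved_haplotype_as_not_estimable(scan_results):
    taa = next(r for r in scan_results if r.exposure_label == "[T;A;A]")
    assert not taa.estimable and math.isnan(taa.odds_ratio)


def test_scan_covers_every_enumerated_haplotype(scan_results):
    assert len(scan_results) == 8
    assert len({r.exposure_label for r in scan_results}) == 8


def test_scan_detects_protective_haplotype(panel):
    config = boosted_config(
        seed=7, n=6000, baseline=0.25, protective={"[T;C;G]": math.log(0.3)}
    )
    cohort = simulate_cohort(config, panel)
    results = haplotype_homozygote_scan(cohort, panel)
    tcg = next(r for r in results if r.exposure_label == "[T;C;G]")
    assert tcg.odds_ratio < 1
    assert tcg.ci95.upper < 1  # CI excludes the null at this n


def test_scan_invariant_to_subject_ordering(scan_cohort, panel, scan_results):
    shuffled = list(scan_cohort)
    random.Random(3).shuffle(shuffled)
    reordered = haplotype_homozygote_scan(shuffled, panel)
    by_label = {r.exposure_label: r for r in reordered}
    for r in scan_results:
        other = by_label[r.exposure_label]
        if r.estimable:
            assert other.odds_ratio == pytest.approx(r.odds_ratio, rel=1e-8)
        else:
            assert not other.estimable


def test_scan_covariate_robustness_without_confounding(scan_cohort, panel):
    """In a single-population, covariate-free simulation, adjusting for
    gender and rare-variant burden moves the estimate by < 10%."""
    adjusted = next(
        r
        for r in haplotype_homozygote_scan(scan_cohort, panel)
        if r.exposure_label == "[C;A;A]"
    )
    crude = next(
        r
        for r in haplotype_homozygote_scan(scan_cohort, panel, covariates=())
        if r.exposure_label == "[C;A;A]"
    )
    assert adjusted.odds_ratio == pytest.approx(crude.odds_ratio, rel=0.10)


# ---------------------------------------------------------------------------
# Risk combination table
# ---------------------------------------------------------------------------


def test_risk_categories_partition_cohort(scan_cohort):
    cells = {}
    for s in scan_cohort:
        cells.setdefault(risk_category(s), []).append(s.subject_id)
    assert None not in cells
    assert sum(len(v) for v in cells.values()) == len(scan_cohort)
    assert all(0 <= c <= 6 and 0 <= r <= 2 for c, r in cells)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_common=st.integers(0, 6),
    n_rare=st.integers(0, 5),
)
def test_risk_category_caps_rare_and_is_exclusive(n_common, n_rare):
    s = make_subject("S1", n_rare_dm=n_rare, n_common_risk=n_common)
    cell = risk_category(s)
    assert cell == (n_common, min(n_rare, 2))


def test_risk_table_ors_increase_with_common_risk_burden(panel):
    config = SimulationConfig(
        n_subjects=5000,
        ancestry_mix={"European": 1.0},
        haplotype_freqs={
            "European": {"[C;A;A]": 0.25, "[C;C;G]": 0.25, "[T;C;G]": 0.25, "[T;C;A]": 0.25}
        },
        penetrance=PenetranceModel(
            intercept=math.log(0.03 / 0.97), per_common_risk_logor=math.log(1.8)
        ),
        trait_models={},
        seed=55,
    )
    cohort = simulate_cohort(config, panel)
    results = risk_combination_table(cohort, include_tyr_rows=False, ci_method="wald")
    ors = {
        r.exposure_label: r.odds_ratio
        for r in results
        if r.estimable and r.exposure_label.endswith("+ 0 rare")
    }
    assert ors["6 common + 0 rare"] > ors["1 common + 0 rare"]
    assert ors["6 common + 0 rare"] > ors["0 common + 0 rare"]


def test_risk_table_flags_small_subgroups():
    subjects = []
    for i in range(60):
        subjects.append(
            make_subject(
                f"S{i}",
                status="case" if i % 2 else "control",
                gender="female" if i % 4 else "male",
                n_common_risk=2 if i < 8 else 0,  # 8-subject category
                n_rare_dm=0,
            )
        )
    results = risk_combination_table(subjects, ci_method="wald", include_tyr_rows=False)
    small = next(r for r in results if r.exposure_label == "2 common + 0 rare")
    assert small.reliability_flag
    assert small.n_exposed_cases + small.n_exposed_controls == 8


def test_risk_table_includes_parallel_rare_tyr_rows(panel):
    subjects = []
    for i in range(80):
        subjects.append(
            make_subject(
                f"S{i}",
                status="case" if i % 2 else "control",
                gender="female" if i % 4 else "male",
                n_common_risk=2,
                n_rare_dm=1 if i < 30 else 0,
                n_rare_dm_tyr=1 if i < 12 else 0,
            )
        )
    results = risk_combination_table(subjects, ci_method="wald")
    labels = {r.exposure_label for r in results}
    assert "2 common + 1 rare" in labels
    assert "2 common + 1 rare TYR" in labels


def test_risk_table_skips_subjects_without_panel_genotype():
    subjects = [make_subject("S1", n_common_risk=None)] + [
        make_subject(
            f"S{i}",
            status="case" if i % 2 else "control",
            gender="female" if i % 4 else "male",
            n_common_risk=0,
        )
        for i in range(2, 40)
    ]
    results = risk_combination_table(subjects, ci_method="wald", include_tyr_rows=False)
    total = sum(r.n_exposed_cases + r.n_exposed_controls for r in results)
    assert total == 38  # S1 never enters any cell


# ---------------------------------------------------------------------------
# Genomic inflation factor
# ---------------------------------------------------------------------------


def test_lambda_from_chi2_arithmetic():
    assert lambda_from_chi2(np.full(35, CHI2_1_MEDIAN)) == pytest.approx(1.0)
    assert lambda_from_chi2(np.array([0.9098728])) == pytest.approx(2.0)


def test_lambda_gc_null_simulation_near_one(rng):
    genotypes, _ = null_marker_panel(n_markers=200, n_subjects=600, seed=42)
    y = np.r_[np.ones(300), np.zeros(300)]
    result = lambda_gc_from_matrix(y, genotypes)
    assert result.n_markers == 200
    assert 0.8 <= result.lambda_median <= 1.2


def test_lambda_gc_excludes_monomorphic_markers():
    y = np.r_[np.ones(50), np.zeros(50)]
    genotypes = np.column_stack([np.zeros(100), np.r_[np.ones(60), np.zeros(40)]])
    result = lambda_gc_from_matrix(y, genotypes)
    assert result.n_markers == 1 and result.n_excluded == 1


def neutral_site(i, cadd=1.0):
    return VariantSite(
        site_id=f"n{i}", label=f"g.{i}A>G", chrom="chr2", pos=1000 + i,
        ref_allele="A", alt_allele="G", consequence="other", cadd_phred=cadd,
        maf_total=0.3, is_eqtl=False, in_regulatory_element=False,
        hgmd_dm=False, hgmd_mutation_type="none", gene="NEUTRAL",
    )


def test_lambda_gc_from_subject_calls(rng):
    sites = [neutral_site(i) for i in range(12)]
    subjects = []
    for j in range(200):
        s = make_subject(f"S{j}", status="case" if j < 100 else "control")
        for v in sites:
            dose = int(rng.binomial(2, 0.3))
            s.calls[v.site_id] = make_call(s.subject_id, v.site_id, tuple(sorted((min(dose, 1), 1 if dose == 2 else 0))))
        subjects.append(s)
    result = lambda_gc(subjects, sites)
    assert result.n_markers <= 12 and result.lambda_median > 0


def test_lambda_gc_rejects_non_neutral_markers():
    sites = [neutral_site(0, cadd=7.0)]
    with pytest.raises(ValueError, match="CADD"):
        lambda_gc([make_subject("S1")], sites)
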
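"""Diagnostic classification rules and nonparametric trait comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tyrhap.diagnostics import (
    assign_diagnosis,
    bh_adjust,
    carries_risk_haplotype,
    classify_cohort,
    diagnostic_yield,
    gene_category,
    kruskal_wallis,
    subject_trait,
    trait_by_diplotype,
)
from tyrhap.simulate import bordeaux_fixture

from conftest import make_call, make_subject


def dm_site(sites, gene):
    return next(v for v in sites if v.site_id == f"dm_{gene}_1")


BASELINE = [(0, 0), (0, 0), (0, 0)]  # homozygous [C;C;G], not a risk haplotype


# ---------------------------------------------------------------------------
# assign_diagnosis
# ---------------------------------------------------------------------------


def test_biallelic_rare_tyr_solved_under_both_rules(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=BASELINE,
        extra_calls=[make_call("S1", dm_site(sites, "TYR").site_id, (1, 1))],
    )
    call = assign_diagnosis(s, sites, panel)
    assert call.category == "TYR"
    assert call.solved_mendelian_only and call.solved_haplotype_aware


def test_single_het_rare_allele_is_unsolved(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=BASELINE,
        extra_calls=[make_call("S1", dm_site(sites, "OCA2").site_id, (0, 1))],
    )
    call = assign_diagnosis(s, sites, panel)
    assert call.category == "unknown"
    assert not call.solved_haplotype_aware


def test_x_linked_gene_solved_with_one_allele(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=BASELINE,
        extra_calls=[make_call("S1", dm_site(sites, "GPR143").site_id, (0, 1))],
    )
    call = assign_diagnosis(s, sites, panel)
    assert call.category == "GPR143" and call.solved_mendelian_only


def test_hps_gene_maps_to_hps_category(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=BASELINE,
        extra_calls=[make_call("S1", dm_site(sites, "HPS1").site_id, (1, 1))],
    )
    assert assign_diagnosis(s, sites, panel).category == "HPS"


def test_unlisted_gene_maps_to_other_category(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=BASELINE,
        extra_calls=[make_call("S1", dm_site(sites, "TYRP1").site_id, (1, 1))],
    )
    assert assign_diagnosis(s, sites, panel).category == "other"
    assert gene_category("LYST") == "other" and gene_category("HPS6") == "HPS"


def test_het_rare_tyr_plus_risk_haplotype_rescued(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=[(0, 0), (0, 1), (0, 1)],  # compatible with [C;A;A]
        extra_calls=[make_call("S1", dm_site(sites, "TYR").site_id, (0, 1))],
    )
    call = assign_diagnosis(s, sites, panel)
    assert not call.solved_mendelian_only
    assert call.solved_haplotype_aware
    assert call.category == "TYR_het_haplotype"


def test_het_rare_tyr_without_risk_haplotype_stays_unsolved(sites, panel):
    s = make_subject(
        panel=panel,
        panel_genotypes=[(1, 1), (0, 0), (0, 0)],  # homozygous [T;C;G]
        extra_calls=[make_call("S1", dm_site(sites, "TYR").site_id, (0, 1))],
    )
    call = assign_diagnosis(s, sites, panel)
    assert call.category == "unknown"


def test_homozygous_risk_haplotype_alone_rescued(sites, panel):
    s = make_subject(panel=panel, panel_genotypes=[(0, 0), (1, 1), (1, 1)])
    call = assign_diagnosis(s, sites, panel)
    assert call.category == "TYR_hom_haplotype"
    assert not call.solved_mendelian_only and call.solved_haplotype_aware


def test_missing_panel_data_yields_unknown_with_reason(sites, panel):
    s = make_subject()  # no genotypes at all
    call = assign_diagnosis(s, sites, panel)
    assert call.category == "unknown" and "insufficient" in call.note


def test_carrier_compatibility_logic(panel):
    hom_ccg = make_subject(panel=panel, panel_genotypes=BASELINE)
    assert carries_risk_haplotype(hom_ccg, panel) is False
    compatible = make_subject(panel=panel, panel_genotypes=[(0, 1), (0, 1), (0, 1)])
    assert carries_risk_haplotype(compatible, panel) is True
    incomplete = make_subject(panel=panel, panel_genotypes=BASELINE[:2])
    assert carries_risk_haplotype(incomplete, panel) is None


# ---------------------------------------------------------------------------
# Yield and monotonicity
# ---------------------------------------------------------------------------


def test_evidence_monotonicity_across_fixture(sites, panel):
    subjects, _ = bordeaux_fixture()
    for call in classify_cohort(subjects, sites, panel):
        assert call.solved_haplotype_aware or not call.solved_mendelian_only


def test_yield_gain_equals_haplotype_category_fraction(sites, panel):
    subjects, _ = bordeaux_fixture()
    calls = classify_cohort(subjects, sites, panel)
    before = diagnostic_yield(calls, "mendelian_only")
    after = diagnostic_yield(calls, "haplotype_aware")
    rescued = sum(c.category in ("TYR_het_haplotype", "TYR_hom_haplotype") for c in calls)
    assert after.n_solved - before.n_solved == rescued
    assert after.fraction >= before.fraction


def test_yield_arithmetic_and_errors(sites, panel):
    subjects, _ = bordeaux_fixture()
    calls = classify_cohort(subjects[:4], sites, panel)
    y = diagnostic_yield(calls, "mendelian_only")
    assert y.n_total == 4 and 0 <= y.percent <= 100
    with pytest.raises(ValueError):
        diagnostic_yield([], "mendelian_only")
    with pytest.raises(ValueError):
        diagnostic_yield(calls, "clairvoyant")


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_kruskal_identical_groups_null():
    H, p = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert H == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_kruskal_known_value_two_disjoint_groups():
    H, p = kruskal_wallis({"lo": [1.0, 2.0, 3.0], "hi": [4.0, 5.0, 6.0]})
    assert H == pytest.approx(3.857142857, abs=1e-6)  # hand rank computation
    h_sp, p_sp = sps.kruskal([1, 2, 3], [4, 5, 6])
    assert H == pytest.approx(h_sp) and p == pytest.approx(p_sp)


def test_kruskal_matches_scipy_with_ties(rng):
    for _ in range(20):
        groups = {
            f"g{j}": rng.integers(0, 6, size=rng.integers(5, 20)).astype(float)
            for j in range(int(rng.integers(2, 5)))
        }
        H, p = kruskal_wallis(groups)
        h_sp, p_sp = sps.kruskal(*groups.values())
        assert H == pytest.approx(h_sp, abs=1e-10)
        assert p == pytest.approx(p_sp, abs=1e-10)


def test_kruskal_excludes_empty_group_and_requires_two():
    H, _ = kruskal_wallis({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": []})
    assert H >= 0
    with pytest.raises(ValueError):
        kruskal_wallis({"a": [1.0, 2.0], "b": []})


def test_all_constant_groups_define_zero_statistic():
    H, p = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
    assert H == 0.0 and p == 1.0


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_bruteforce(p):
    """Definitional step-up: p~(i) = min_{k >= i} min(1, m p(k) / k)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for i in range(m):
        out[order[i]] = min(
            min(1.0, p[order[k]] * m / (k + 1)) for k in range(i, m)
        )
    return out


def test_bh_single_p_unchanged():
    assert bh_adjust([0.04]).tolist() == [0.04]


def test_bh_worked_example():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([0.5, float("nan")])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
def test_bh_matches_bruteforce_definition(p):
    assert np.allclose(bh_adjust(p), bh_bruteforce(p))


def test_bh_matches_statsmodels_oracle(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(10):
        p = rng.random(int(rng.integers(1, 40)))
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), expected)


def test_bh_is_monotone_and_bounded(rng):
    p = rng.random(30)
    q = bh_adjust(p)
    assert np.all(q <= 1.0) and np.all(q >= p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# Trait comparisons across homozygous diplotypes
# ---------------------------------------------------------------------------


def test_subject_trait_eye_averaging():
    both = make_subject(traits={"logmar_va_right": 0.2, "logmar_va_left": 0.4})
    assert subject_trait(both, "logmar_va") == pytest.approx(0.3)
    single = make_subject(traits={"logmar_va_right": 0.2})
    assert subject_trait(single, "logmar_va") == pytest.approx(0.2)  # fallback
    direct = make_subject(traits={"logmar_va": 0.1})
    assert subject_trait(direct, "logmar_va") == pytest.approx(0.1)
    assert subject_trait(make_subject(), "logmar_va") is None


def shifted_cohort(panel, rng, shift=0.10, n_per_group=200):
    genotypes = {
        "[C;A;A]": [(0, 0), (1, 1), (1, 1)],
        "[C;C;G]": [(0, 0), (0, 0), (0, 0)],
        "[T;C;G]": [(1, 1), (0, 0), (0, 0)],
    }
    subjects = []
    for label, g in genotypes.items():
        loc = shift if label == "[C;A;A]" else 0.0
        for i in range(n_per_group):
            s = make_subject(f"{label}-{i}", panel=panel, panel_genotypes=g)
            s.traits["logmar_va"] = float(rng.normal(loc, 0.15))
            subjects.append(s)
    return subjects


def test_trait_comparison_detects_shifted_group(panel):
    rng = np.random.default_rng(2024)
    subjects = shifted_cohort(panel, rng)
    comp = trait_by_diplotype(subjects, "logmar_va", panel)
    assert comp.p < 0.01
    i = comp.group_labels.index("[C;A;A]")
    others = [j for j in range(len(comp.group_labels)) if j != i]
    assert all(comp.pairwise[i, j] < 0.05 for j in others)
    assert np.allclose(comp.pairwise, comp.pairwise.T, equal_nan=True)


def test_trait_comparison_null_when_groups_identical(panel):
    subjects = []
    for label, g in {"[C;A;A]": [(0, 0), (1, 1), (1, 1)], "[C;C;G]": [(0, 0), (0, 0), (0, 0)]}.items():
        for i in range(5):
            s = make_subject(f"{label}-{i}", panel=panel, panel_genotypes=g)
            s.traits["logmar_va"] = 0.0
            subjects.append(s)
    comp = trait_by_diplotype(subjects, "logmar_va", panel)
    assert comp.H == 0.0 and comp.p == 1.0


def test_trait_comparison_requires_two_groups(panel):
    subjects = [make_subject("A", panel=panel, panel_genotypes=[(0, 0), (0, 0), (0, 0)])]
    subjects[0].traits["logmar_va"] = 0.1
    with pytest.raises(ValueError):
        trait_by_diplotype(subjects, "logmar_va", panel)
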
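"""Case-control association analyses.

Three analyses over a cohort of subjects:

* a per-haplotype homozygote scan under a recessive model (exposure =
  homozygosity for one haplotype, comparison = everyone else);
* the common x rare risk-genotype combination table, partitioning subjects
  by (number of common TYR risk alleles, number of rare DM variants);
* a genomic-inflation check (lambda_GC) over presumed-neutral low-CADD
  markers, flagging residual population-stratification confounding.

All fits are Firth-penalized logistic regressions with configurable
covariate sets (gender, ancestry dummies, rare-DM burden).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import Subject, VariantSite
from .firth import (
    FirthModel,
    IntervalEstimate,
    fit_firth,
    plr_statistic,
    plr_test,
    profile_ci,
    wald_ci,
)
from .haplotypes import resolve_homozygous, enumerate_haplotypes
from .variants import Panel

log = logging.getLogger(__name__)

CHI2_1_MEDIAN = 0.4549364  # median of the chi-square(1) distribution


def lambda_from_chi2(chi2: np.ndarray) -> float:
    """Genomic inflation factor: median test chi-square over the
    chi-square(1) median."""
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("no test statistics")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


SCAN_COVARIATES = ("gender", "ancestry", "n_rare_dm")
TABLE_COVARIATES = ("gender", "ancestry")


@dataclass
class AssociationResult:
    """One exposure's odds ratio with uncertainty and context."""

    exposure_label: str
    odds_ratio: float
    ci95: Optional[IntervalEstimate]
    p_value: float
    n_exposed_cases: int
    n_exposed_controls: int
    covariates_used: list[str]
    reliability_flag: bool = False
    estimable: bool = True
    note: str = ""


@dataclass
class LambdaGCResult:
    per_marker_chi2: np.ndarray
    lambda_median: float
    n_markers: int
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def build_design(
    subjects: Sequence[Subject],
    exposure: Callable[[Subject], int],
    covariates: Sequence[str] = SCAN_COVARIATES,
) -> tuple[np.ndarray, np.ndarray, list[str], list[Subject]]:
    """Design matrix for a Firth fit: intercept, exposure indicator, then
    covariate columns in deterministic order.

    Categorical covariates are dummy-coded against the largest level;
    single-level covariates are dropped with a warning.  Subjects with a
    missing required covariate are excluded (count logged).
    """
    usable = []
    dropped = 0
    for s in subjects:
        ok = True
        for c in covariates:
            if c in ("gender", "ancestry") and not getattr(s, c):
                ok = False
        if ok:
            usable.append(s)
        else:
            dropped += 1
    if dropped:
        log.info("build_design: %d subject(s) excluded for missing covariates", dropped)

    y = np.array([1.0 if s.is_case else 0.0 for s in usable])
    cols = [np.ones(len(usable)), np.array([float(exposure(s)) for s in usable])]
    labels = ["intercept", "exposure"]
    for c in covariates:
        if c in ("gender", "ancestry"):
            values = [getattr(s, c) for s in usable]
            levels = sorted(set(values))
            if len(levels) < 2:
                log.warning("covariate %s has a single level; dropped", c)
                continue
            reference = max(levels, key=lambda lv: (values.count(lv), lv))
            for lv in levels:
                if lv == reference:
                    continue
                cols.append(np.array([1.0 if v == lv else 0.0 for v in values]))
                labels.append(f"{c}[{lv}]")
        elif c == "n_rare_dm":
            cols.append(np.array([float(s.n_rare_dm) for s in usable]))
            labels.append("n_rare_dm")
        else:
            raise ValueError(f"unsupported covariate {c!r}")
    X = np.column_stack(cols)
    return X, y, labels, usable


def _fit_exposure(
    subjects: Sequence[Subject],
    exposure: Callable[[Subject], int],
    label: str,
    covariates: Sequence[str],
    ci_method: str = "profile",
) -> AssociationResult:
    X, y, labels, used = build_design(subjects, exposure, covariates)
    exposed = X[:, 1] == 1.0
    n_exp_cases = int(np.sum(exposed & (y == 1)))
    n_exp_controls = int(np.sum(exposed & (y == 0)))
    cells = [
        n_exp_cases,
        n_exp_controls,
        int(np.sum(~exposed & (y == 1))),
        int(np.sum(~exposed & (y == 0))),
    ]
    if not exposed.any() or exposed.all():
        return AssociationResult(
            exposure_label=label,
            odds_ratio=float("nan"),
            ci95=None,
            p_value=float("nan"),
            n_exposed_cases=n_exp_cases,
            n_exposed_controls=n_exp_controls,
            covariates_used=labels[2:],
            estimable=False,
            note="no exposed subject" if not exposed.any() else "no unexposed comparison group",
        )
    model = fit_firth(X, y, labels=labels)
    ci = (
        profile_ci(model, X, y, 1)
        if ci_method == "profile"
        else wald_ci(model, 1)
    )
    p = plr_test(model, X, y, 1)
    return AssociationResult(
        exposure_label=label,
        odds_ratio=float(np.exp(model.coefficients[1])),
        ci95=ci,
        p_value=p,
        n_exposed_cases=n_exp_cases,
        n_exposed_controls=n_exp_controls,
        covariates_used=labels[2:],
        reliability_flag=min(cells) < 10,
    )


# ---------------------------------------------------------------------------
# Per-haplotype homozygote scan
# ---------------------------------------------------------------------------


def haplotype_homozygote_scan(
    subjects: Sequence[Subject],
    panel: Panel,
    covariates: Sequence[str] = SCAN_COVARIATES,
    ci_method: str = "profile",
) -> list[AssociationResult]:
    """Recessive-model scan: one Firth fit per haplotype, exposure being
    homozygosity for that haplotype, against all other subjects.

    Haplotypes with zero homozygotes are returned as not-estimable records
    (they stay visible rather than silently vanishing).
    """
    diplotype = {}
    for s in subjects:
        d = resolve_homozygous(s, panel)
        diplotype[s.subject_id] = d.h1.label if d is not None else None
    results = []
    for h in enumerate_haplotypes(panel):
        label = h.label
        results.append(
            _fit_exposure(
                subjects,
                lambda s, _lab=label: 1 if diplotype[s.subject_id] == _lab else 0,
                label,
                covariates,
                ci_method,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Common x rare combination table
# ---------------------------------------------------------------------------


def risk_category(subject: Subject, max_rare: int = 2) -> Optional[tuple[int, int]]:
    """The mutually exclusive (n_common, n_rare) cell for a subject, with the
    rare count capped at ``max_rare``; ``None`` when the common-risk count is
    unavailable (incomplete panel genotype)."""
    if subject.n_common_risk is None:
        return None
    return subject.n_common_risk, min(subject.n_rare_dm, max_rare)


def risk_combination_table(
    subjects: Sequence[Subject],
    covariates: Sequence[str] = TABLE_COVARIATES,
    max_common: int = 6,
    max_rare: int = 2,
    include_tyr_rows: bool = True,
    ci_method: str = "profile",
) -> list[AssociationResult]:
    """The combination table: category-vs-rest Firth fits for every
    non-empty (n_common, n_rare) cell, plus parallel rows restricted to
    rare variants in TYR.

    The (n_common, n_rare) cells partition the subjects with a resolved
    common-risk count; the rare-TYR rows overlap them by construction and
    are labelled separately.  Cells with fewer than 10 subjects in their
    smallest case/control subgroup carry a reliability flag.
    """
    categorized = [s for s in subjects if s.n_common_risk is not None]
    skipped = len(subjects) - len(categorized)
    if skipped:
        log.info("risk_combination_table: %d subject(s) without panel genotypes skipped", skipped)
    results = []
    for c in range(0, max_common + 1):
        for r in range(0, max_rare + 1):
            label = f"{c} common + {r} rare"
            members = {
                s.subject_id for s in categorized if risk_category(s, max_rare) == (c, r)
            }
            if not members:
                log.info("empty category %s omitted", label)
                continue
            results.append(
                _fit_exposure(
                    categorized,
                    lambda s, _m=members: 1 if s.subject_id in _m else 0,
                    label,
                    covariates,
                    ci_method,
                )
            )
    if include_tyr_rows:
        for c in range(0, max_common + 1):
            for r in range(1, max_rare + 1):
                label = f"{c} common + {r} rare TYR"
                members = {
                    s.subject_id
                    for s in categorized
                    if s.n_common_risk == c and min(s.n_rare_dm_tyr, max_rare) == r
                }
                if not members:
                    continue
                results.append(
                    _fit_exposure(
                        categorized,
                        lambda s, _m=members: 1 if s.subject_id in _m else 0,
                        label,
                        covariates,
                        ci_method,
                    )
                )
    return results


# ---------------------------------------------------------------------------
# Genomic inflation factor
# ---------------------------------------------------------------------------


def lambda_gc_from_matrix(
    y: np.ndarray,
    genotypes: np.ndarray,
    statistic: str = "plr",
) -> LambdaGCResult:
    """lambda_GC from an allele-dosage matrix (subjects x markers).

    Each marker gets an allelic Firth test (intercept + dosage, no
    covariates); the 1-df chi-square statistics' median over markers,
    divided by the chi-square(1) median 0.4549364, is lambda.  Monomorphic
    markers are excluded.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.shape[0]:
        raise ValueError("genotype matrix must be subjects x markers")
    stats_out = []
    excluded = 0
    ones = np.ones(G.shape[0])
    for m in range(G.shape[1]):
        dose = G[:, m]
        if np.all(dose == dose[0]):
            excluded += 1
            log.info("lambda_gc: monomorphic marker %d excluded", m)
            continue
        X = np.column_stack([ones, dose])
        model = fit_firth(X, y)
        if statistic == "plr":
            stat = plr_statistic(model, X, y, 1)
        elif statistic == "wald":
            se = model.wald_se()[1]
            stat = float((model.coefficients[1] / se) ** 2)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        stats_out.append(stat)
    chi2 = np.array(stats_out)
    if chi2.size < 10:
        log.warning("lambda_gc: only %d usable marker(s); estimate unstable", chi2.size)
    if chi2.size == 0:
        raise ValueError("no polymorphic marker available for lambda_GC")
    return LambdaGCResult(
        per_marker_chi2=chi2,
        lambda_median=lambda_from_chi2(chi2),
        n_markers=int(chi2.size),
        n_excluded=excluded,
    )


def lambda_gc(
    subjects: Sequence[Subject],
    neutral_sites: Sequence[VariantSite],
    statistic: str = "plr",
    require_qc: bool = True,
) -> LambdaGCResult:
    """lambda_GC over neutral marker sites carried in the subjects' calls.

    Markers must satisfy the neutrality screen (CADD < 5); a subject's
    dosage at a marker is its QC-passing alt-allele count, treated as
    missing (subject skipped for that marker) otherwise.
    """
    from .cohort import qc_filter_genotype

    bad = [v.site_id for v in neutral_sites if v.cadd_phred >= 5]
    if bad:
        raise ValueError(f"non-neutral marker(s) (CADD >= 5): {', '.join(bad)}")
    y_all = np.array([1.0 if s.is_case else 0.0 for s in subjects])
    stats_out = []
    excluded = 0
    for v in neutral_sites:
        doses, keep = [], []
        for i, s in enumerate(subjects):
            call = s.calls.get(v.site_id)
            if call is None or call.is_missing or (require_qc and not qc_filter_genotype(call)):
                continue
            doses.append(float(call.n_alt))
            keep.append(i)
        dose = np.array(doses)
        if dose.size == 0 or np.all(dose == dose[0]):
            excluded += 1
            continue
        y = y_all[keep]
        X = np.column_stack([np.ones(dose.size), dose])
        model = fit_firth(X, y)
        if statistic == "plr":
            stats_out.append(plr_statistic(model, X, y, 1))
        else:
            se = model.wald_se()[1]
            stats_out.append(float((model.coefficients[1] / se) ** 2))
    chi2 = np.array(stats_out)
    if chi2.size < 10:
        log.warning("lambda_gc: only %d usable marker(s); estimate unstable", chi2.size)
    if chi2.size == 0:
        raise ValueError("no polymorphic marker available for lambda_GC")
    return LambdaGCResult(
        per_marker_chi2=chi2,
        lambda_median=lambda_from_chi2(chi2),
        n_markers=int(chi2.size),
        n_excluded=excluded,
    )
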
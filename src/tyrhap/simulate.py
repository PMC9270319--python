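"""Synthetic cohorts with the statistical structure the analyses assume.

The restricted study data (national genome programmes, a hospital variant
database, a biobank) cannot be redistributed, so every analysis stage is
exercised on simulated cohorts built here:

* Hardy-Weinberg diplotype sampling from per-ancestry haplotype
  frequencies over the common-variant panel — P(h1/h2) = 2 f1 f2 for
  heterozygous pairs, f^2 for homozygous ones;
* a logistic penetrance model with homozygous-haplotype effects (the
  promoter-switched hypomorphic-allele mechanism), plus per-allele effects
  of the common-risk count and the rare-DM burden;
* Poisson per-subject counts of rare disease-causing (DM) alleles;
* diplotype-conditional quantitative traits (e.g. LogMAR acuity).

Also here: the deterministic 1208-proband diagnostic-yield fixture, the
neutral-marker generator for genomic-inflation checks, and the
parameter-recovery harness that validates the recessive-scan estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional, Sequence

import numpy as np

from .association import SCAN_COVARIATES, _fit_exposure
from .cohort import GenotypeCall, Subject, VariantSite
from .firth import fit_logistic_mle
from .haplotypes import (
    Haplotype,
    RiskAlleleScheme,
    enumerate_haplotypes,
    resolve_homozygous,
    risk_alleles_on_haplotype,
)
from .variants import Panel, annotate_rare_dm_counts, build_tyr_panel, default_sites


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# Illustrative per-ancestry haplotype frequencies for the 3-site TYR panel,
# shaped like published population data: the high-expression promoter T
# allele at ~40% in European and ~80% in African ancestries, and the
# high-risk [C;A;A] haplotype at ~1% in Europeans.  Configurable, not claims.
DEFAULT_HAPLOTYPE_FREQS: dict[str, dict[str, float]] = {
    "European": {
        "[C;C;G]": 0.305,
        "[T;C;G]": 0.260,
        "[C;A;G]": 0.160,
        "[T;A;G]": 0.090,
        "[C;C;A]": 0.130,
        "[T;C;A]": 0.040,
        "[C;A;A]": 0.010,
        "[T;A;A]": 0.005,
    },
    "African": {
        "[C;C;G]": 0.170,
        "[T;C;G]": 0.620,
        "[C;A;G]": 0.020,
        "[T;A;G]": 0.090,
        "[C;C;A]": 0.015,
        "[T;C;A]": 0.080,
        "[C;A;A]": 0.005,
        "[T;A;A]": 0.000,
    },
    "SouthAsian": {
        "[C;C;G]": 0.250,
        "[T;C;G]": 0.400,
        "[C;A;G]": 0.100,
        "[T;A;G]": 0.090,
        "[C;C;A]": 0.090,
        "[T;C;A]": 0.050,
        "[C;A;A]": 0.012,
        "[T;A;A]": 0.008,
    },
}

DEFAULT_ANCESTRY_MIX = {"European": 0.85, "African": 0.05, "SouthAsian": 0.10}


@dataclass(frozen=True)
class PenetranceModel:
    """Logistic model for P(case | genotype).

    ``intercept`` is the baseline log-odds; ``hom_haplotype_logor`` maps a
    haplotype label to the log odds-ratio of homozygosity for it (the
    recessive effects the scan estimates); the two per-unit terms act on
    the common-risk allele count and the rare-DM burden.
    """

    intercept: float
    hom_haplotype_logor: dict[str, float] = field(default_factory=dict)
    per_common_risk_logor: float = 0.0
    per_rare_dm_logor: float = 0.0


# Effects loosely shaped like the reported associations: strong recessive
# risk for [C;A;A] and [C;C;A] (the low-expression promoter allele cis to
# the hypomorphic missense alleles) and protection for the high-expression
# promoter haplotypes.
DEFAULT_PENETRANCE = PenetranceModel(
    intercept=log(0.01 / 0.99),
    hom_haplotype_logor={
        "[C;A;A]": log(80.0),
        "[C;C;A]": log(25.0),
        "[T;C;A]": log(0.5),
        "[T;C;G]": log(0.5),
    },
    per_common_risk_logor=log(1.3),
    per_rare_dm_logor=log(2.5),
)


@dataclass(frozen=True)
class TraitModel:
    """Diplotype-conditional Gaussian trait: base location, per-homozygous-
    haplotype shifts, common scale."""

    base: float
    scale: float
    shifts: dict[str, float] = field(default_factory=dict)
    family: str = "normal"


DEFAULT_TRAIT_MODELS = {
    # LogMAR acuity: ~0 is normal; the high-risk homozygotes sit ~0.1 worse.
    "logmar_va": TraitModel(base=0.0, scale=0.15, shifts={"[C;A;A]": 0.10}),
    # central retinal thickness (micrometres); thicker fovea in risk homozygotes
    "central_retinal_thickness": TraitModel(base=270.0, scale=20.0, shifts={"[C;A;A]": 15.0}),
}


@dataclass
class SimulationConfig:
    n_subjects: int = 10_000
    ancestry_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ANCESTRY_MIX))
    haplotype_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HAPLOTYPE_FREQS.items()}
    )
    penetrance: PenetranceModel = DEFAULT_PENETRANCE
    rare_dm_rate: float = 0.2
    rare_dm_tyr_fraction: float = 0.3
    trait_models: dict[str, TraitModel] = field(default_factory=lambda: dict(DEFAULT_TRAIT_MODELS))
    seed: int = 0

    def validate(self, panel: Panel) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if abs(sum(self.ancestry_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("ancestry proportions must sum to 1")
        labels = {h.label for h in enumerate_haplotypes(panel)}
        for ancestry in self.ancestry_mix:
            if ancestry not in self.haplotype_freqs:
                raise ConfigError(f"no haplotype frequencies for ancestry {ancestry!r}")
            freqs = self.haplotype_freqs[ancestry]
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{ancestry}: haplotype frequencies must sum to 1")
            unknown = set(freqs) - labels
            if unknown:
                raise ConfigError(f"{ancestry}: labels not on the panel: {sorted(unknown)}")
            if any(f < 0 for f in freqs.values()):
                raise ConfigError(f"{ancestry}: negative haplotype frequency")
        if self.rare_dm_rate < 0:
            raise ConfigError("rare_dm_rate must be non-negative")
        if not 0.0 <= self.rare_dm_tyr_fraction <= 1.0:
            raise ConfigError("rare_dm_tyr_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _make_call(subject_id: str, site: VariantSite, alleles: tuple[int, int]) -> GenotypeCall:
    depth = 40
    n_alt = sum(alleles)
    return GenotypeCall(
        subject_id=subject_id,
        site_id=site.site_id,
        alleles=tuple(sorted(alleles)),
        genotype_quality=99,
        depth=depth,
        allele_balance=n_alt / 2.0,
        passed_site_filters=True,
    )


def simulate_cohort(config: SimulationConfig, panel: Optional[Panel] = None) -> list[Subject]:
    """Draw a cohort under the configured model; a pure function of
    (config, seed) — the same configuration reproduces the same cohort."""
    if panel is None:
        panel = build_tyr_panel(default_sites())
    config.validate(panel)
    rng = np.random.default_rng(config.seed)
    haplotypes = {h.label: h for h in enumerate_haplotypes(panel)}
    scheme = RiskAlleleScheme.for_panel(panel)
    risk_per_hap = {
        lab: risk_alleles_on_haplotype(h, panel, scheme) for lab, h in haplotypes.items()
    }

    n = config.n_subjects
    ancestry_levels = sorted(config.ancestry_mix)
    ancestry_probs = np.array([config.ancestry_mix[a] for a in ancestry_levels])
    ancestries = rng.choice(len(ancestry_levels), size=n, p=ancestry_probs)

    h1_idx = np.empty(n, dtype=int)
    h2_idx = np.empty(n, dtype=int)
    hap_labels_by_ancestry = {}
    for ai, ancestry in enumerate(ancestry_levels):
        freqs = config.haplotype_freqs[ancestry]
        labels = sorted(freqs)
        probs = np.array([freqs[lab] for lab in labels])
        probs = probs / probs.sum()
        hap_labels_by_ancestry[ai] = labels
        mask = ancestries == ai
        m = int(mask.sum())
        h1_idx[mask] = rng.choice(len(labels), size=m, p=probs)
        h2_idx[mask] = rng.choice(len(labels), size=m, p=probs)

    n_rare = rng.poisson(config.rare_dm_rate, size=n)
    n_rare_tyr = rng.binomial(n_rare, config.rare_dm_tyr_fraction)
    genders = np.where(rng.random(n) < 0.5, "female", "male")

    subjects: list[Subject] = []
    pen = config.penetrance
    uniforms = rng.random(n)
    trait_noise = {
        name: rng.normal(0.0, tm.scale, size=n) for name, tm in config.trait_models.items()
    }
    for i in range(n):
        ancestry = ancestry_levels[ancestries[i]]
        labels = hap_labels_by_ancestry[ancestries[i]]
        lab1, lab2 = labels[h1_idx[i]], labels[h2_idx[i]]
        hap1, hap2 = haplotypes[lab1], haplotypes[lab2]
        n_common = risk_per_hap[lab1] + risk_per_hap[lab2]
        hom_label = lab1 if lab1 == lab2 else None
        lp = (
            pen.intercept
            + (pen.hom_haplotype_logor.get(hom_label, 0.0) if hom_label else 0.0)
            + pen.per_common_risk_logor * n_common
            + pen.per_rare_dm_logor * n_rare[i]
        )
        prob = 1.0 / (1.0 + np.exp(-lp))
        sid = f"S{i:06d}"
        subject = Subject(
            subject_id=sid,
            status="case" if uniforms[i] < prob else "control",
            gender=str(genders[i]),
            ancestry=ancestry,
            n_rare_dm=int(n_rare[i]),
            n_rare_dm_tyr=int(n_rare_tyr[i]),
            n_common_risk=int(n_common),
        )
        for k, site in enumerate(panel):
            subject.calls[site.site_id] = _make_call(
                sid, site, (hap1.alleles[k], hap2.alleles[k])
            )
        for name, tm in config.trait_models.items():
            shift = tm.shifts.get(hom_label, 0.0) if hom_label else 0.0
            subject.traits[name] = float(tm.base + shift + trait_noise[name][i])
        subjects.append(subject)
    return subjects


# ---------------------------------------------------------------------------
# Deterministic diagnostic-yield fixture
# ---------------------------------------------------------------------------

# Gene allocation of the 692 Mendelian-solved probands: published category
# shares renormalized over the Mendelian-only yield, residual rounding
# absorbed by the largest (TYR) category.
_FIXTURE_GENE_COUNTS = {
    "TYR": 190,
    "OCA2": 227,
    "SLC45A2": 95,
    "GPR143": 60,
    "HPS1": 60,
    "SLC24A5": 24,
    "TYRP1": 36,  # reported as "other"
}
_FIXTURE_HET_RESCUE = 185  # one rare TYR allele + carried risk haplotype
_FIXTURE_HOM_RESCUE = 39  # homozygous risk haplotype, no rare TYR allele
_FIXTURE_UNSOLVED = 292
_FIXTURE_DM_SITE = {
    "TYR": "dm_TYR_1",
    "OCA2": "dm_OCA2_1",
    "SLC45A2": "dm_SLC45A2_1",
    "GPR143": "dm_GPR143_1",
    "HPS1": "dm_HPS1_1",
    "SLC24A5": "dm_SLC24A5_1",
    "TYRP1": "dm_TYRP1_1",
}


def bordeaux_fixture() -> tuple[list[Subject], dict]:
    """A deterministic 1208-proband cohort mirroring the published
    diagnostic-yield structure: 692 probands with qualifying biallelic (or
    X-linked hemizygous) rare-DM configurations, 224 carrying a
    haplotype-rescue configuration, 292 with no qualifying configuration.

    Synthetic: category counts reproduce the published structure; the
    allele-level content is illustrative.
    """
    sites = default_sites()
    by_id = {v.site_id: v for v in sites}
    panel = build_tyr_panel(sites)
    subjects: list[Subject] = []
    counter = 0

    def new_subject() -> Subject:
        nonlocal counter
        counter += 1
        return Subject(
            subject_id=f"B{counter:04d}",
            status="case",
            gender="female" if counter % 2 else "male",
            ancestry="European",
        )

    def set_panel(subject: Subject, genotypes: Sequence[tuple[int, int]]) -> None:
        for site, alleles in zip(panel, genotypes):
            subject.calls[site.site_id] = _make_call(subject.subject_id, site, alleles)

    baseline = [(0, 0), (0, 0), (0, 0)]  # homozygous [C;C;G]
    for gene, count in _FIXTURE_GENE_COUNTS.items():
        site = by_id[_FIXTURE_DM_SITE[gene]]
        alleles = (0, 1) if gene == "GPR143" else (1, 1)  # X-linked: one allele suffices
        for _ in range(count):
            s = new_subject()
            set_panel(s, baseline)
            s.calls[site.site_id] = _make_call(s.subject_id, site, alleles)
            subjects.append(s)
    tyr_site = by_id[_FIXTURE_DM_SITE["TYR"]]
    for _ in range(_FIXTURE_HET_RESCUE):
        s = new_subject()
        set_panel(s, [(0, 0), (0, 1), (0, 1)])  # compatible with [C;A;A]/[C;C;A]
        s.calls[tyr_site.site_id] = _make_call(s.subject_id, tyr_site, (0, 1))
        subjects.append(s)
    for _ in range(_FIXTURE_HOM_RESCUE):
        s = new_subject()
        set_panel(s, [(0, 0), (1, 1), (1, 1)])  # homozygous [C;A;A]
        subjects.append(s)
    oca2_site = by_id[_FIXTURE_DM_SITE["OCA2"]]
    for i in range(_FIXTURE_UNSOLVED):
        s = new_subject()
        set_panel(s, baseline)
        if i < 100:  # a single het rare allele never solves an autosomal gene
            s.calls[oca2_site.site_id] = _make_call(s.subject_id, oca2_site, (0, 1))
        subjects.append(s)

    annotate_rare_dm_counts(subjects, sites)
    expected = {
        "n_total": len(subjects),
        "mendelian_solved": sum(_FIXTURE_GENE_COUNTS.values()),
        "haplotype_rescued": _FIXTURE_HET_RESCUE + _FIXTURE_HOM_RESCUE,
        "het_rescued": _FIXTURE_HET_RESCUE,
        "hom_rescued": _FIXTURE_HOM_RESCUE,
        "unsolved": _FIXTURE_UNSOLVED,
    }
    return subjects, expected


# ---------------------------------------------------------------------------
# Neutral markers and parameter recovery
# ---------------------------------------------------------------------------


def null_marker_panel(
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_subjects: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Allele-dosage matrix for presumed-neutral markers, simulated
    independently of any phenotype (a true null for lambda_GC)."""
    if n_markers < 1:
        raise ConfigError("need at least one marker")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_markers)
    genotypes = rng.binomial(2, mafs[None, :], size=(n_subjects, n_markers))
    return genotypes.astype(np.int8), mafs


@dataclass
class RecoverySummary:
    true_or: float
    n: int
    replicates: int
    n_estimable: int
    estimates_logor: np.ndarray
    coverage: float
    mean_logor_bias: float
    median_or: float
    mle_mean_logor_bias: float = float("nan")


def recovery_harness(
    true_or: float,
    n: int,
    replicates: int,
    seed: int,
    hap_label: str = "[C;A;A]",
    hap_freq: float = 0.05,
    baseline_prevalence: float = 0.05,
    level: float = 0.95,
    compare_mle: bool = False,
) -> RecoverySummary:
    """Simulate-and-refit validation of the recessive homozygote scan.

    Each replicate simulates a single-population cohort in which
    homozygosity for ``hap_label`` multiplies the odds of disease by
    ``true_or``, then re-estimates that odds ratio with the Firth fit and
    profile CI used by the scan.  Reports mean log-OR bias, empirical CI
    coverage and the median OR estimate across replicates; replicates
    without any homozygote are counted but not estimable.
    """
    if true_or <= 0 or n <= 0 or replicates <= 0:
        raise ConfigError("harness parameters must be positive")
    panel = build_tyr_panel(default_sites())
    base = dict(DEFAULT_HAPLOTYPE_FREQS["European"])
    others = {k: v for k, v in base.items() if k != hap_label}
    norm = sum(others.values())
    freqs = {k: v * (1.0 - hap_freq) / norm for k, v in others.items()}
    freqs[hap_label] = hap_freq
    true_logor = log(true_or)
    pen = PenetranceModel(
        intercept=log(baseline_prevalence / (1.0 - baseline_prevalence)),
        hom_haplotype_logor={hap_label: true_logor},
    )
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    estimates, covered, mle_estimates = [], [], []
    for rep_seed in seeds:
        config = SimulationConfig(
            n_subjects=n,
            ancestry_mix={"European": 1.0},
            haplotype_freqs={"European": freqs},
            penetrance=pen,
            rare_dm_rate=0.2,
            trait_models={},
            seed=int(rep_seed),
        )
        cohort = simulate_cohort(config, panel)
        hom = {
            s.subject_id
            for s in cohort
            if (d := resolve_homozygous(s, panel)) is not None and d.h1.label == hap_label
        }
        result = _fit_exposure(
            cohort,
            lambda s, _m=hom: 1 if s.subject_id in _m else 0,
            hap_label,
            SCAN_COVARIATES,
            ci_method="profile",
        )
        if not result.estimable:
            continue
        estimates.append(log(result.odds_ratio))
        lo = -np.inf if result.ci95.lower_open else log(result.ci95.lower)
        hi = np.inf if result.ci95.upper_open else log(result.ci95.upper)
        covered.append(lo <= true_logor <= hi)
        if compare_mle:
            from .association import build_design

            X, y, _, _ = build_design(
                cohort, lambda s, _m=hom: 1 if s.subject_id in _m else 0, SCAN_COVARIATES
            )
            beta, ok = fit_logistic_mle(X, y)
            if ok:
                mle_estimates.append(beta[1])
    est = np.array(estimates)
    return RecoverySummary(
        true_or=true_or,
        n=n,
        replicates=replicates,
        n_estimable=est.size,
        estimates_logor=est,
        coverage=float(np.mean(covered)) if covered else float("nan"),
        mean_logor_bias=float(np.mean(est - true_logor)) if est.size else float("nan"),
        median_or=float(np.exp(np.median(est))) if est.size else float("nan"),
        mle_mean_logor_bias=(
            float(np.mean(np.array(mle_estimates) - true_logor)) if mle_estimates else float("nan")
        ),
    )
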
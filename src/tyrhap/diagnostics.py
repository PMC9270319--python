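"""Diagnostic classification and quantitative endophenotype comparisons.

Two classification rules are applied to every proband:

* Mendelian-only — solved iff the subject carries >= 2 rare disease-causing
  (DM) alleles in one recessive albinism gene, or >= 1 in an X-linked gene
  (GPR143);
* haplotype-aware — additionally solved when one rare TYR DM allele
  co-occurs with a carried risk haplotype (presumed in trans), or when the
  subject is homozygous for a risk haplotype with no rare TYR allele.

The second rule is a strict superset of the first, so the haplotype-aware
diagnostic yield can only increase.

Quantitative traits (LogMAR visual acuity, central retinal thickness) are
compared across homozygous-diplotype groups with the Kruskal-Wallis test
plus pairwise comparisons under Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import Subject, VariantSite, qc_filter_genotype
from .haplotypes import resolve_homozygous
from .variants import Panel, classify_rare_dm

log = logging.getLogger(__name__)

X_LINKED_GENES = frozenset({"GPR143"})
DEFAULT_RISK_HAPLOTYPES = frozenset({"[C;A;A]", "[C;C;A]"})
GENE_CATEGORIES = ("TYR", "OCA2", "SLC45A2", "GPR143", "HPS", "SLC24A5", "other")
_HAPLOTYPE_CATEGORIES = ("TYR_het_haplotype", "TYR_hom_haplotype")


def gene_category(gene: str) -> str:
    if gene in ("TYR", "OCA2", "SLC45A2", "GPR143", "SLC24A5"):
        return gene
    if gene.startswith("HPS"):
        return "HPS"
    return "other"


@dataclass(frozen=True)
class DiagnosticCall:
    subject_id: str
    category: str  # gene category, TYR_het_haplotype, TYR_hom_haplotype or unknown
    solved_mendelian_only: bool
    solved_haplotype_aware: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.solved_mendelian_only and not self.solved_haplotype_aware:
            raise ValueError("haplotype-aware evidence cannot be weaker than Mendelian-only")


@dataclass
class YieldResult:
    mode: str
    n_solved: int
    n_total: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.n_solved, self.n_total)

    @property
    def percent(self) -> int:
        """Nearest-integer percent (report convention)."""
        return int(round(100.0 * self.n_solved / self.n_total))


@dataclass
class TraitComparison:
    trait: str
    groups: dict[str, np.ndarray]
    H: float
    p: float
    pairwise: "np.ndarray"  # symmetric matrix of BH-adjusted p-values
    group_labels: list[str]


# ---------------------------------------------------------------------------
# Diagnostic classification
# ---------------------------------------------------------------------------


def _rare_dm_alleles_by_gene(subject: Subject, variants: Sequence[VariantSite]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for v in variants:
        if not classify_rare_dm(v):
            continue
        call = subject.calls.get(v.site_id)
        if call is None or not qc_filter_genotype(call):
            continue
        if call.n_alt:
            counts[v.gene] = counts.get(v.gene, 0) + call.n_alt
    return counts


def carries_risk_haplotype(
    subject: Subject,
    panel: Panel,
    risk_haplotypes: frozenset[str] = DEFAULT_RISK_HAPLOTYPES,
) -> Optional[bool]:
    """Whether the unphased panel genotype is compatible with carrying at
    least one of the risk haplotypes.

    With unphased data a heterozygous carrier cannot be proven; compatibility
    at every site (the haplotype's allele present in the genotype) is the
    presumption used, mirroring clinical "found/presumed to carry" calls.
    Returns ``None`` when any panel genotype is missing or QC-failed.
    """
    genotype_bases = []
    for site in panel:
        call = subject.calls.get(site.site_id)
        if call is None or call.is_missing or not qc_filter_genotype(call):
            return None
        genotype_bases.append({site.base(a) for a in call.alleles})
    for label in risk_haplotypes:
        wanted = label.strip("[]").split(";")
        if len(wanted) == len(panel) and all(
            b in g for b, g in zip(wanted, genotype_bases)
        ):
            return True
    return False


def assign_diagnosis(
    subject: Subject,
    variants: Sequence[VariantSite],
    panel: Panel,
    risk_haplotypes: frozenset[str] = DEFAULT_RISK_HAPLOTYPES,
) -> DiagnosticCall:
    """Classify one proband under both diagnostic rules.

    Gene attribution picks the gene with the most qualifying alleles
    (ties broken by the fixed category order, TYR first).  Rare TYR alleles
    at sites distinct from the panel cannot be double-counted as part of a
    risk haplotype — panel sites are common by construction, so the rare
    allele and the haplotype's defining alleles never coincide.
    """
    by_gene = _rare_dm_alleles_by_gene(subject, variants)

    def _threshold(gene: str) -> int:
        return 1 if gene in X_LINKED_GENES else 2

    solved_genes = [g for g, n in by_gene.items() if n >= _threshold(g)]
    if solved_genes:
        order = {c: i for i, c in enumerate(GENE_CATEGORIES)}
        best = max(
            solved_genes,
            key=lambda g: (by_gene[g], -order.get(gene_category(g), len(order))),
        )
        return DiagnosticCall(
            subject_id=subject.subject_id,
            category=gene_category(best),
            solved_mendelian_only=True,
            solved_haplotype_aware=True,
        )

    tyr_alleles = by_gene.get("TYR", 0)
    carrier = carries_risk_haplotype(subject, panel, risk_haplotypes)
    if tyr_alleles == 1 and carrier:
        return DiagnosticCall(
            subject_id=subject.subject_id,
            category="TYR_het_haplotype",
            solved_mendelian_only=False,
            solved_haplotype_aware=True,
            note="one rare TYR allele + risk haplotype presumed in trans",
        )
    if tyr_alleles == 0:
        d = resolve_homozygous(subject, panel)
        if d is not None and d.homozygous and d.h1.label in risk_haplotypes:
            return DiagnosticCall(
                subject_id=subject.subject_id,
                category="TYR_hom_haplotype",
                solved_mendelian_only=False,
                solved_haplotype_aware=True,
            )
    note = "insufficient panel genotype data" if carrier is None else ""
    return DiagnosticCall(
        subject_id=subject.subject_id,
        category="unknown",
        solved_mendelian_only=False,
        solved_haplotype_aware=False,
        note=note,
    )


def classify_cohort(
    subjects: Sequence[Subject],
    variants: Sequence[VariantSite],
    panel: Panel,
    risk_haplotypes: frozenset[str] = DEFAULT_RISK_HAPLOTYPES,
) -> list[DiagnosticCall]:
    return [assign_diagnosis(s, variants, panel, risk_haplotypes) for s in subjects]


def diagnostic_yield(calls: Sequence[DiagnosticCall], mode: str) -> YieldResult:
    """Fraction of probands solved under ``mendelian_only`` or
    ``haplotype_aware`` classification."""
    if not calls:
        raise ValueError("empty cohort has no diagnostic yield")
    if mode == "mendelian_only":
        solved = sum(c.solved_mendelian_only for c in calls)
    elif mode == "haplotype_aware":
        solved = sum(c.solved_haplotype_aware for c in calls)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return YieldResult(mode=mode, n_solved=int(solved), n_total=len(calls))


# ---------------------------------------------------------------------------
# Nonparametric trait comparisons
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H on midranks with tie correction; p from a
    chi-square with (#groups - 1) df.

    Empty groups are excluded with a warning.  When every observation is
    tied the statistic is defined as 0 (p = 1).
    """
    cleaned = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 1}
    for k in groups:
        if k not in cleaned:
            log.warning("kruskal_wallis: empty group %r excluded", k)
    if len(cleaned) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(list(cleaned.values()))
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    offset = 0
    for v in cleaned.values():
        r = ranks[offset : offset + v.size]
        h += r.sum() ** 2 / v.size
        offset += v.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
    if correction <= 0.0:
        return 0.0, 1.0
    h /= correction
    h = max(0.0, h)
    p = float(sps.chi2.sf(h, len(cleaned) - 1)) if h > 0 else 1.0
    return float(h), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def subject_trait(subject: Subject, trait: str) -> Optional[float]:
    """Per-subject trait value, averaging right/left eye measurements when
    both are present and falling back to the single available eye."""
    if trait in subject.traits:
        return subject.traits[trait]
    eyes = [subject.traits[k] for k in (f"{trait}_right", f"{trait}_left") if k in subject.traits]
    if not eyes:
        return None
    if len(eyes) == 1:
        log.info("subject %s: single-eye %s measurement used", subject.subject_id, trait)
    return float(np.mean(eyes))


def trait_by_diplotype(
    subjects: Sequence[Subject],
    trait: str,
    panel: Panel,
    min_group_size: int = 1,
) -> TraitComparison:
    """Compare a quantitative trait across homozygous-diplotype groups.

    Omnibus Kruskal-Wallis over all groups, then every pairwise two-group
    comparison with BH adjustment over the pairwise family.
    """
    groups: dict[str, list[float]] = {}
    for s in subjects:
        d = resolve_homozygous(s, panel)
        if d is None:
            continue
        value = subject_trait(s, trait)
        if value is None:
            continue
        groups.setdefault(d.h1.label, []).append(value)
    groups = {k: v for k, v in groups.items() if len(v) >= min_group_size}
    if len(groups) < 2:
        raise ValueError("need at least two homozygous-diplotype groups with trait data")
    arrays = {k: np.asarray(v) for k, v in groups.items()}
    H, p = kruskal_wallis(arrays)
    labels = sorted(arrays)
    pairs = list(combinations(range(len(labels)), 2))
    raw = [
        kruskal_wallis({labels[i]: arrays[labels[i]], labels[j]: arrays[labels[j]]})[1]
        for i, j in pairs
    ]
    adj = bh_adjust(raw) if raw else np.array([])
    matrix = np.full((len(labels), len(labels)), np.nan)
    np.fill_diagonal(matrix, 1.0)
    for (i, j), q in zip(pairs, adj):
        matrix[i, j] = matrix[j, i] = q
    return TraitComparison(
        trait=trait, groups=arrays, H=H, p=p, pairwise=matrix, group_labels=labels
    )
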
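"""Haplotype enumeration and homozygous-diplotype resolution.

A panel of K biallelic sites admits 2^K haplotypes and
2^(K-1) x (2^K + 1) unordered haplotype pairs (diplotypes).  The analysis
deliberately restricts itself to the 2^K all-site-homozygous diplotypes:
only there can the underlying haplotypes be read off unphased genotypes
with certainty, so no statistical phasing is ever attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

from .cohort import ALT, REF, Subject, VariantSite, qc_filter_genotype
from .variants import Panel, classify_regulatory


class IncompletePanelError(ValueError):
    """A subject lacks a usable genotype at one or more panel sites."""


@dataclass(frozen=True)
class Haplotype:
    """An ordered K-tuple of allele codes aligned to the panel.

    ``label`` renders the nucleotide letters in panel order, e.g.
    ``"[C;A;A]"``.  ``expression_class`` annotates the promoter allele
    (reference -> low expression, alternate -> high); it is metadata, not
    part of identity.
    """

    alleles: tuple[int, ...]
    bases: tuple[str, ...]

    @classmethod
    def from_alleles(cls, panel: Panel, alleles: Sequence[int]) -> "Haplotype":
        if len(alleles) != len(panel):
            raise ValueError("haplotype length must match panel size")
        return cls(
            alleles=tuple(int(a) for a in alleles),
            bases=tuple(site.base(a) for site, a in zip(panel, alleles)),
        )

    @property
    def label(self) -> str:
        return "[" + ";".join(self.bases) + "]"

    @property
    def expression_class(self) -> str:
        return "low" if self.alleles[0] == REF else "high"


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotypes; stored in canonical (sorted) order."""

    h1: Haplotype
    h2: Haplotype

    def __post_init__(self) -> None:
        if self.h2.alleles < self.h1.alleles:
            first, second = self.h2, self.h1
            object.__setattr__(self, "h1", first)
            object.__setattr__(self, "h2", second)

    @property
    def homozygous(self) -> bool:
        return self.h1.alleles == self.h2.alleles

    @property
    def label(self) -> str:
        return f"{self.h1.label}/{self.h2.label}"


def enumerate_haplotypes(panel: Panel) -> list[Haplotype]:
    """All 2^K haplotypes in deterministic lexicographic order (ref < alt)."""
    if len(panel) == 0:
        raise ValueError("panel must contain at least one site")
    return [Haplotype.from_alleles(panel, combo) for combo in product((REF, ALT), repeat=len(panel))]


def count_diplotypes(k: int) -> int:
    """Number of unordered haplotype pairs over a K-site panel:
    2^(K-1) x (2^K + 1).  K=3 gives 36."""
    if k <= 0:
        raise ValueError("panel size must be positive")
    return 2 ** (k - 1) * (2**k + 1)


def resolution_status(subject: Subject, panel: Panel, require_qc: bool = True) -> str:
    """``"resolved"``, ``"heterozygous"`` or ``"incomplete"`` for a subject."""
    hom = True
    for site in panel:
        call = subject.calls.get(site.site_id)
        if call is None or call.is_missing or (require_qc and not qc_filter_genotype(call)):
            return "incomplete"
        if call.is_het:
            hom = False
    return "resolved" if hom else "heterozygous"


def resolve_homozygous(
    subject: Subject, panel: Panel, require_qc: bool = True
) -> Optional[Diplotype]:
    """The unique homozygous diplotype, or ``None``.

    Returns a diplotype only when the subject carries a usable homozygous
    genotype at every panel site; heterozygosity or a missing/failed call
    anywhere yields ``None`` (no imputation, no phasing).
    """
    alleles = []
    for site in panel:
        call = subject.calls.get(site.site_id)
        if call is None or call.is_missing or (require_qc and not qc_filter_genotype(call)):
            return None
        if call.is_het:
            return None
        alleles.append(call.alleles[0])
    h = Haplotype.from_alleles(panel, alleles)
    return Diplotype(h, h)


@dataclass(frozen=True)
class RiskAlleleScheme:
    """Which allele counts as the risk allele at each panel site.

    For the TYR panel the risk alleles are the promoter reference C (lower
    TYR expression) and the alternate alleles of the two missense changes
    (c.575A, c.1205A).
    """

    risk_allele: dict[str, int]  # site_id -> REF|ALT

    def __post_init__(self) -> None:
        for sid, a in self.risk_allele.items():
            if a not in (REF, ALT):
                raise ValueError(f"{sid}: risk allele must be 0 (ref) or 1 (alt)")

    @classmethod
    def for_panel(cls, panel: Panel) -> "RiskAlleleScheme":
        """Default scheme: regulatory sites risk on the reference allele,
        coding sites on the alternate allele."""
        return cls(
            {site.site_id: (REF if classify_regulatory(site) else ALT) for site in panel}
        )


def count_common_risk_alleles(
    subject: Subject,
    panel: Panel,
    scheme: Optional[RiskAlleleScheme] = None,
    require_qc: bool = True,
) -> int:
    """Total risk alleles carried across the panel (0..2K).

    Each copy of the per-site risk allele counts once, so a homozygous
    risk-haplotype carrier on a 3-site panel scores 6.  Raises
    :class:`IncompletePanelError` on any unusable panel genotype.
    """
    if scheme is None:
        scheme = RiskAlleleScheme.for_panel(panel)
    total = 0
    for site in panel:
        call = subject.calls.get(site.site_id)
        if call is None or call.is_missing or (require_qc and not qc_filter_genotype(call)):
            raise IncompletePanelError(
                f"subject {subject.subject_id}: unusable genotype at {site.site_id}"
            )
        risk = scheme.risk_allele[site.site_id]
        total += sum(1 for a in call.alleles if a == risk)
    return total


def risk_alleles_on_haplotype(h: Haplotype, panel: Panel, scheme: Optional[RiskAlleleScheme] = None) -> int:
    if scheme is None:
        scheme = RiskAlleleScheme.for_panel(panel)
    return sum(1 for site, a in zip(panel, h.alleles) if a == scheme.risk_allele[site.site_id])


def annotate_common_risk(subjects: Sequence[Subject], panel: Panel) -> None:
    """Fill ``n_common_risk`` in place; subjects with incomplete panel
    genotypes keep ``None`` (excluded from haplotype analyses upstream)."""
    scheme = RiskAlleleScheme.for_panel(panel)
    for s in subjects:
        try:
            s.n_common_risk = count_common_risk_alleles(s, panel, scheme)
        except IncompletePanelError:
            s.n_common_risk = None
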
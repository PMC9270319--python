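"""Variant-selection rules and the TYR analysis panel.

Three mutually independent predicates partition the functional evidence:

* common protein-coding — CADD PHRED >= 20, total MAF >= 1%, and a
  protein-altering consequence (splice-type changes excluded);
* regulatory — a known eQTL that also lies in a cis-regulatory element;
* rare Mendelian — an HGMD "disease-causing" (DM) label, total MAF < 1%,
  in a point/small-lesion mutation category (gross/complex events excluded).

The first two rules define the common-variant panel whose haplotypes are the
exposures of the association analyses; the third defines the per-subject
rare-variant burden used as a covariate and in diagnostic classification.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Optional, Sequence

from .cohort import Subject, VariantSite, qc_filter_genotype, read_variant_table

log = logging.getLogger(__name__)

PROTEIN_ALTERING = frozenset({"missense", "nonsense", "small_indel"})
RARE_DM_TYPES = frozenset(
    {"missense_nonsense", "splicing", "small_del", "small_ins", "small_indel"}
)

Panel = Sequence[VariantSite]


class PanelError(ValueError):
    """No variant qualifies for the analysis panel."""


def classify_common_coding(v: VariantSite) -> bool:
    """Common, likely-functional protein-coding change.

    Inclusive cut-offs: CADD >= 20 and MAF >= 0.01 both qualify at the
    boundary.  Splice-relevant consequences (synonymous, splicing) never
    qualify regardless of score.
    """
    return (
        v.cadd_phred >= 20.0
        and v.maf_total >= 0.01
        and v.consequence in PROTEIN_ALTERING
    )


def classify_regulatory(v: VariantSite) -> bool:
    """Known eQTL that overlaps a cis-regulatory element (conjunction)."""
    return v.is_eqtl and v.in_regulatory_element


def classify_rare_dm(v: VariantSite) -> bool:
    """Rare HGMD disease-causing point/small lesion (MAF < 1%, strict)."""
    return v.hgmd_dm and v.maf_total < 0.01 and v.hgmd_mutation_type in RARE_DM_TYPES


def build_tyr_panel(sites: Sequence[VariantSite], gene: str = "TYR") -> list[VariantSite]:
    """Assemble the common-variant panel for ``gene``.

    Regulatory-qualifying sites come first, then common-coding sites, each
    block ordered by genomic position, so a promoter variant leads.  The
    panel size K is whatever the annotations support — nothing is
    hard-coded to three sites.
    """
    in_gene = [v for v in sites if v.gene == gene]
    regulatory = sorted((v for v in in_gene if classify_regulatory(v)), key=lambda v: (v.chrom, v.pos))
    coding = sorted(
        (v for v in in_gene if classify_common_coding(v) and not classify_regulatory(v)),
        key=lambda v: (v.chrom, v.pos),
    )
    panel = regulatory + coding
    if not panel:
        raise PanelError(f"no {gene} site qualifies for the common-variant panel")
    if not regulatory:
        log.warning("panel for %s has no regulatory/promoter site", gene)
    return panel


def count_rare_dm(
    subject: Subject,
    sites: Sequence[VariantSite],
    gene_filter: Optional[str] = None,
) -> int:
    """Number of rare-DM risk genotypes carried by a subject.

    Counted per allele: a heterozygote contributes 1, a homozygous-alternate
    genotype 2.  Only QC-passing calls count.  ``gene_filter`` restricts to
    one gene (e.g. ``"TYR"``).
    """
    total = 0
    for v in sites:
        if not classify_rare_dm(v):
            continue
        if gene_filter is not None and v.gene != gene_filter:
            continue
        call = subject.calls.get(v.site_id)
        if call is None or not qc_filter_genotype(call):
            continue
        total += call.n_alt
    return total


def annotate_rare_dm_counts(subjects: Sequence[Subject], sites: Sequence[VariantSite]) -> None:
    """Fill ``n_rare_dm`` / ``n_rare_dm_tyr`` on every subject in place."""
    for s in subjects:
        s.n_rare_dm = count_rare_dm(s, sites)
        s.n_rare_dm_tyr = count_rare_dm(s, sites, gene_filter="TYR")


def default_sites() -> list[VariantSite]:
    """The packaged TYR-centred annotation table (panel + example DM sites)."""
    with resources.as_file(resources.files("tyrhap.data") / "tyr_variants.tsv") as p:
        return read_variant_table(p)


def default_panel() -> list[VariantSite]:
    """The three-site TYR panel (promoter c.-301C>T, c.575C>A, c.1205G>A)."""
    return build_tyr_panel(default_sites())
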
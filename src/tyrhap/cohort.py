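"""Cohort data model and I/O.

Holds the three primary inputs of the analysis — an annotated variant table,
unphased genotypes from a VCF, and a phenotype/covariate table — together with
the per-genotype quality-control filter applied before any haplotype work.

All genotype handling is explicitly unphased: phased (``|``) and unphased
(``/``) separators are read identically, because downstream haplotype
resolution relies only on all-site homozygosity, never on phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "small_indel", "splicing", "synonymous", "regulatory", "other"}
)
HGMD_MUTATION_TYPES = frozenset(
    {
        "missense_nonsense",
        "splicing",
        "small_del",
        "small_ins",
        "small_indel",
        "gross_del",
        "gross_ins",
        "complex",
        "none",
    }
)
ANCESTRIES = frozenset(
    {"European", "African", "AdmixedAmerican", "EastAsian", "SouthAsian", "Unknown"}
)
STATUSES = frozenset({"case", "control"})

REF, ALT = 0, 1  # allele codes used throughout


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class DuplicateIdError(FormatError):
    """An identifier that must be unique appears more than once."""


class UnsupportedRecordError(FormatError):
    """A VCF record cannot be represented (e.g. multi-allelic at a panel site)."""


class JoinError(KeyError):
    """Genotype and phenotype tables disagree about sample membership."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSite:
    """One annotated biallelic SNV with the functional evidence the
    selection rules consume.

    ``maf_total`` is the cohort-wide ("total") minor/alternate allele
    frequency on [0, 1]; ``cadd_phred`` the PHRED-scaled deleteriousness
    score (>= 20 ~ top 1% of possible substitutions).
    """

    site_id: str
    label: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    consequence: str
    cadd_phred: float
    maf_total: float
    is_eqtl: bool
    in_regulatory_element: bool
    hgmd_dm: bool
    hgmd_mutation_type: str
    gene: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.site_id}: ref and alt alleles are identical")
        if not 0.0 <= self.maf_total <= 1.0:
            raise ValueError(f"{self.site_id}: maf_total={self.maf_total} outside [0, 1]")
        if self.cadd_phred < 0:
            raise ValueError(f"{self.site_id}: negative CADD score")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.site_id}: unknown consequence {self.consequence!r}")
        if self.hgmd_mutation_type not in HGMD_MUTATION_TYPES:
            raise ValueError(
                f"{self.site_id}: unknown HGMD mutation type {self.hgmd_mutation_type!r}"
            )

    def base(self, allele: int) -> str:
        """Nucleotide letter for allele code 0 (ref) or 1 (alt)."""
        return self.ref_allele if allele == REF else self.alt_allele


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid, unphased genotype at one site for one subject.

    ``alleles`` is a sorted pair of allele codes (0 = ref, 1 = alt), or
    ``None`` when the call is missing.  ``allele_balance`` is the fraction of
    alt-supporting reads, defined only when read depth is positive and AD was
    reported.
    """

    subject_id: str
    site_id: str
    alleles: Optional[tuple[int, int]]
    genotype_quality: Optional[int] = None
    depth: Optional[int] = None
    allele_balance: Optional[float] = None
    passed_site_filters: bool = True
    half_missing: bool = False

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if len(self.alleles) != 2:
                raise ValueError("diploid call requires exactly two alleles")
            if tuple(sorted(self.alleles)) != tuple(self.alleles):
                object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if self.allele_balance is not None and not (self.depth or 0) > 0:
            raise ValueError("allele_balance defined only when depth > 0")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def n_alt(self) -> int:
        if self.alleles is None:
            raise ValueError("missing call has no allele count")
        return sum(self.alleles)


@dataclass
class Subject:
    """A study participant: phenotype, covariates, genotype calls and the
    derived risk-allele counts used as exposures/covariates downstream."""

    subject_id: str
    status: str
    gender: str
    ancestry: str
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    n_rare_dm: int = 0
    n_rare_dm_tyr: int = 0
    n_common_risk: Optional[int] = None
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"{self.subject_id}: status must be case/control, got {self.status!r}")
        if self.ancestry not in ANCESTRIES:
            raise ValueError(f"{self.subject_id}: unknown ancestry {self.ancestry!r}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


# ---------------------------------------------------------------------------
# Genotype quality control
# ---------------------------------------------------------------------------


class QCVerdict(NamedTuple):
    keep: bool
    reason: Optional[str]

    def __bool__(self) -> bool:  # allows `if qc_filter_genotype(call): ...`
        return self.keep


def qc_filter_genotype(call: GenotypeCall) -> QCVerdict:
    """Per-genotype quality filter.

    A call is kept when it passed site-level filters and, where the
    supporting FORMAT fields are present, GQ >= 20, depth >= 10 and the
    allele balance is consistent with the called genotype: within
    [0.2, 0.8] for heterozygotes, <= 0.1 for homozygous-reference and
    >= 0.9 for homozygous-alternate calls.  Boundary values are kept
    (the filters reject on strict inequality).  A clause whose FORMAT
    field is absent is not applicable and does not reject.

    Pure predicate: missing calls return ``(False, "missing")``.
    """
    if call.is_missing:
        return QCVerdict(False, "missing")
    if not call.passed_site_filters:
        return QCVerdict(False, "site_filter")
    if call.genotype_quality is not None and call.genotype_quality < 20:
        return QCVerdict(False, "genotype_quality")
    if call.depth is not None and call.depth < 10:
        return QCVerdict(False, "depth")
    ab = call.allele_balance
    if ab is not None:
        if call.is_het:
            if not 0.2 <= ab <= 0.8:
                return QCVerdict(False, "allele_balance")
        elif call.n_alt == 0:  # hom-ref
            if ab > 0.1:
                return QCVerdict(False, "allele_balance")
        else:  # hom-alt
            if ab < 0.9:
                return QCVerdict(False, "allele_balance")
    return QCVerdict(True, None)


# ---------------------------------------------------------------------------
# Variant table I/O
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "site_id",
    "label",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "consequence",
    "cadd_phred",
    "maf_total",
    "is_eqtl",
    "in_regulatory_element",
    "hgmd_dm",
    "hgmd_mutation_type",
    "gene",
]

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n", ""}


def _parse_bool(token: object, column: str) -> bool:
    if isinstance(token, bool):
        return token
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise FormatError(f"cannot parse boolean {token!r} in column {column}")


def read_variant_table(path: str | Path) -> list[VariantSite]:
    """Read an annotated variant TSV; every row must parse (no silent skips)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing mandatory column(s): {', '.join(missing)}")
    dup = df["site_id"][df["site_id"].duplicated()]
    if not dup.empty:
        raise DuplicateIdError(f"duplicate site_id(s): {', '.join(sorted(set(dup)))}")
    sites = []
    for _, row in df.iterrows():
        sites.append(
            VariantSite(
                site_id=row["site_id"],
                label=row["label"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                consequence=row["consequence"],
                cadd_phred=float(row["cadd_phred"]),
                maf_total=float(row["maf_total"]),
                is_eqtl=_parse_bool(row["is_eqtl"], "is_eqtl"),
                in_regulatory_element=_parse_bool(
                    row["in_regulatory_element"], "in_regulatory_element"
                ),
                hgmd_dm=_parse_bool(row["hgmd_dm"], "hgmd_dm"),
                hgmd_mutation_type=row["hgmd_mutation_type"] or "none",
                gene=row["gene"],
            )
        )
    return sites


def write_variant_table(sites: Iterable[VariantSite], path: str | Path) -> None:
    rows = []
    for v in sites:
        rows.append(
            {
                "site_id": v.site_id,
                "label": v.label,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref_allele": v.ref_allele,
                "alt_allele": v.alt_allele,
                "consequence": v.consequence,
                "cadd_phred": v.cadd_phred,
                "maf_total": v.maf_total,
                "is_eqtl": int(v.is_eqtl),
                "in_regulatory_element": int(v.in_regulatory_element),
                "hgmd_dm": int(v.hgmd_dm),
                "hgmd_mutation_type": v.hgmd_mutation_type,
                "gene": v.gene,
            }
        )
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype table I/O
# ---------------------------------------------------------------------------

_PHENO_CORE = ["subject_id", "status", "gender", "ancestry"]


def read_phenotypes(path: str | Path) -> list[Subject]:
    """Read the phenotype/covariate TSV.

    Columns beyond the core four are treated as quantitative traits; empty
    cells mean the trait is absent for that subject.  Unknown ancestry
    tokens map to ``Unknown`` with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _PHENO_CORE if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing mandatory column(s): {', '.join(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise DuplicateIdError(f"duplicate subject_id(s): {', '.join(sorted(set(dup)))}")
    trait_cols = [c for c in df.columns if c not in _PHENO_CORE]
    subjects = []
    for _, row in df.iterrows():
        ancestry = row["ancestry"]
        if ancestry not in ANCESTRIES:
            log.warning("subject %s: unknown ancestry %r mapped to Unknown", row["subject_id"], ancestry)
            ancestry = "Unknown"
        traits = {}
        for c in trait_cols:
            if row[c] != "":
                value = float(row[c])
                if value != value or value in (float("inf"), float("-inf")):
                    raise FormatError(f"subject {row['subject_id']}: non-finite trait {c}")
                traits[c] = value
        subjects.append(
            Subject(
                subject_id=row["subject_id"],
                status=row["status"],
                gender=row["gender"],
                ancestry=ancestry,
                traits=traits,
            )
        )
    return subjects


def write_phenotypes(subjects: Sequence[Subject], path: str | Path) -> None:
    trait_cols = sorted({t for s in subjects for t in s.traits})
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "status": s.status,
            "gender": s.gender,
            "ancestry": s.ancestry,
        }
        for t in trait_cols:
            row[t] = s.traits.get(t, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_PHENO_CORE + trait_cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_genotypes_vcf(path: str | Path, sites: Sequence[VariantSite]) -> list[GenotypeCall]:
    """Read genotype calls for the given sites from a VCF.

    Records are matched to sites by ID, falling back to (chrom, pos, ref,
    alt).  Phase separators are ignored.  Half-missing genotypes (``0/.``)
    are recorded as missing with ``half_missing`` set, never guessed.
    """
    from cyvcf2 import VCF

    by_id = {v.site_id: v for v in sites}
    by_locus = {(v.chrom, v.pos, v.ref_allele, v.alt_allele): v for v in sites}
    calls: list[GenotypeCall] = []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    seen: set[str] = set()
    for rec in vcf:
        site = by_id.get(rec.ID) if rec.ID else None
        if site is None:
            site = by_locus.get((rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else ""))
        if site is None:
            continue
        if len(rec.ALT) != 1:
            raise UnsupportedRecordError(
                f"multi-allelic record at panel site {site.site_id} ({rec.CHROM}:{rec.POS})"
            )
        seen.add(site.site_id)
        passed = rec.FILTER is None  # cyvcf2: None means PASS/'.'
        gqs = rec.format("GQ")
        dps = rec.format("DP")
        ads = rec.format("AD")
        for i, sample in enumerate(samples):
            a1, a2 = rec.genotypes[i][0], rec.genotypes[i][1]
            half = (a1 < 0) != (a2 < 0)
            alleles = None if (a1 < 0 or a2 < 0) else tuple(sorted((int(a1), int(a2))))
            gq = int(gqs[i][0]) if gqs is not None and gqs[i][0] >= 0 else None
            dp = int(dps[i][0]) if dps is not None and dps[i][0] >= 0 else None
            ab = None
            if ads is not None:
                ref_d, alt_d = int(ads[i][0]), int(ads[i][1])
                if ref_d >= 0 and alt_d >= 0 and ref_d + alt_d > 0:
                    if dp is None:
                        dp = ref_d + alt_d
                    ab = alt_d / (ref_d + alt_d)
            calls.append(
                GenotypeCall(
                    subject_id=sample,
                    site_id=site.site_id,
                    alleles=alleles,
                    genotype_quality=gq,
                    depth=dp,
                    allele_balance=ab if (dp or 0) > 0 else None,
                    passed_site_filters=passed,
                    half_missing=half,
                )
            )
    absent = sorted(set(by_id) - seen)
    if absent:
        log.warning("VCF lacks %d panel site(s): %s", len(absent), ", ".join(absent))
    return calls


def write_genotypes_vcf(
    path: str | Path,
    sites: Sequence[VariantSite],
    subjects: Sequence[Subject],
) -> None:
    """Write a minimal VCF v4.2 (GT:GQ:DP:AD) for the subjects' calls.

    AD is reconstructed from depth and allele balance; allele balance is
    therefore preserved on re-read up to read-count granularity (1/depth).
    """
    ordered = sorted(sites, key=lambda v: (v.chrom, v.pos))
    contigs = sorted({v.chrom for v in ordered})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.subject_id for s in subjects),
    ]
    for v in ordered:
        fields = [v.chrom, str(v.pos), v.site_id, v.ref_allele, v.alt_allele, ".", "PASS", ".", "GT:GQ:DP:AD"]
        entries = []
        for s in subjects:
            call = s.calls.get(v.site_id)
            if call is None or call.is_missing:
                entries.append("./.:.:.:.")
                continue
            gt = "/".join(str(a) for a in call.alleles)
            gq = "." if call.genotype_quality is None else str(call.genotype_quality)
            dp = "." if call.depth is None else str(call.depth)
            if call.depth and call.allele_balance is not None:
                alt_d = round(call.depth * call.allele_balance)
                ad = f"{call.depth - alt_d},{alt_d}"
            else:
                ad = "."
            entries.append(f"{gt}:{gq}:{dp}:{ad}")
        lines.append("\t".join(fields + entries))
    Path(path).write_text("\n".join(lines) + "\n")


def attach_calls(subjects: Sequence[Subject], calls: Iterable[GenotypeCall]) -> list[Subject]:
    """Join genotype calls onto subjects in place (returned for chaining).

    Every sample in the calls must exist in the phenotype table; otherwise a
    :class:`JoinError` lists the offending ids.
    """
    calls = list(calls)
    by_id: Mapping[str, Subject] = {s.subject_id: s for s in subjects}
    orphans = sorted({c.subject_id for c in calls if c.subject_id not in by_id})
    if orphans:
        raise JoinError(f"VCF sample(s) absent from phenotype table: {', '.join(orphans)}")
    for c in calls:
        by_id[c.subject_id].calls[c.site_id] = c
    return list(subjects)
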
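# Methods

This note documents the models and procedures implemented in `tyrhap`,
their assumptions, the parameters that matter, and the design decisions
taken where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cohort model and genotype quality control

A cohort is a set of subjects (case/control status, gender, ancestry
group, quantitative traits) joined to unphased diploid genotype calls at
annotated biallelic SNVs. Genotypes are read from VCF v4.x
(`GT:GQ:DP:AD`); phased and unphased separators are treated identically
because nothing downstream uses phase.

Per-genotype QC keeps a call iff it passed site-level filters and

* genotype quality (FORMAT/GQ) ≥ 20,
* read depth ≥ 10,
* allele balance (alt reads / total reads): within [0.2, 0.8] for
  heterozygotes, ≤ 0.1 for homozygous-reference, ≥ 0.9 for
  homozygous-alternate calls.

Boundary values are kept: the filters reject on strict inequality
(GQ < 20, depth < 10, balance outside the stated bands). "Genotype
score" is read as FORMAT/GQ, the only per-genotype quality a short-read
small-variant caller emits. A call lacking GQ, DP or AD cannot be
evaluated against the corresponding clause, which is then not applied
rather than treated as a failure. Half-missing genotypes (`0/.`) are
recorded as missing with a flag and never imputed. A subject missing a
usable genotype at any panel site is excluded from haplotype resolution
but retained for covariate-only analyses.

## Variant selection and the TYR panel

Three mutually independent predicates:

* **common protein-coding**: CADD PHRED ≥ 20 (inclusive), total
  MAF ≥ 1% (inclusive), consequence ∈ {missense, nonsense, small indel}.
  Synonymous and splice-region changes are excluded regardless of score.
* **regulatory**: known eQTL AND located in a cis-regulatory element
  (conjunction; the annotation flags abstract the tissue question).
* **rare Mendelian (rare-DM)**: HGMD "disease-causing" label, total
  MAF < 1% (strict), mutation type ∈ {missense/nonsense, splicing, small
  del/ins/indel}. Gross deletions/insertions and complex rearrangements
  are out of scope.

The common-variant panel is the regulatory-qualifying sites followed by
the common-coding sites, each ordered by genomic position, so a promoter
variant leads. Nothing fixes the panel at three sites; for the packaged
TYR annotations it is (c.−301C>T, c.575C>A, c.1205G>A), K = 3.

Rare-DM burden is counted per allele (heterozygote 1, homozygote 2),
overall and restricted to *TYR* — consistent with a combination table
that contains a "0 common + 2 rare" cell reachable by a single
homozygote.

## Haplotypes, diplotypes, risk alleles

A K-site panel admits 2^K haplotypes and 2^(K−1)(2^K + 1) unordered
pairs (8 and 36 at K = 3; verified against brute-force pair enumeration
for K ≤ 5). Only the 2^K all-site-homozygous diplotypes are ever
resolved from unphased data: there the phase is unambiguous without
segregation data, and a recessive phenotype isolates the haplotype's
effect. Heterozygous configurations return "unresolved" by design; no
EM or reference-panel phasing is attempted, and the two haplotypes never
observed homozygous are still enumerated and reported as zero-exposed.

Haplotype labels are nucleotide letters in panel order (`[C;A;A]`); the
promoter expression class (reference C → low expression, alternate T →
high) is metadata, not identity. The risk-allele scheme marks one risk
allele per site — the reference allele at regulatory sites (low
expression is the risk direction) and the alternate allele at coding
sites — so a homozygous `[C;A;A]` carrier counts 6 of 6 possible risk
alleles.

## Firth bias-reduced logistic regression

Implemented from scratch (no wrapper): the estimate maximizes the
Jeffreys-penalized log-likelihood ℓ*(β) = ℓ(β) + ½ log det I(β) with
I(β) = XᵀWX, W = diag(πᵢ(1−πᵢ)). Newton steps use the modified score
U*ⱼ = Uⱼ + ½ Σᵢ hᵢ(½ − πᵢ)xᵢⱼ, hᵢ the hat diagonals of
W^½X(XᵀWX)⁻¹XᵀW^½.

Numerical choices: start at β = 0; convergence when the largest
coefficient change is < 1e−8 or after 100 iterations; up to 25
step-halvings enforce monotone ascent of ℓ*; log det via Cholesky; a
singular information at an extreme trial point evaluates to ℓ* = −∞ and
is rejected by the halving loop; rank-deficient designs raise with the
suspect columns named. The reported covariance is the inverse
information at the estimate.

Confidence intervals default to profile penalized likelihood: the bounds
solve 2[ℓ*(β̂) − ℓ*profile(b)] = χ²₁,0.95, with the profile re-maximized
under the pinned coefficient (penalty always from the full design),
found by outward bracketing from the estimate and Brent refinement. A
bound not bracketed within ±15 log-odds is flagged as an open interval
side instead of raising. Wald intervals are available by flag; the two
agree within a few percent at large n and separate exactly where the
penalized likelihood is asymmetric (sparse cells). Hypothesis tests are
penalized likelihood-ratio (PLR) χ²₁ tests with the null coefficient
pinned at zero.

Test oracles: on saturated single-binary-covariate 2×2 designs the
penalized mode equals the add-½ contingency estimator (agreement to
1e−6); for p ≤ 2 the estimates match coarse-to-fine grid maximization of
an independently coded ℓ* to 3 decimals; 20 seeded datasets match
quasi-Newton (BFGS) maximization of that objective to 1e−4. A plain
unpenalized Newton MLE is included solely for bias comparisons.

## Association analyses

**Design matrices.** Columns: intercept, exposure indicator, then gender
dummy, ancestry dummies (reference = largest level), and the rare-DM
count, in deterministic order. Single-level covariates are dropped with
a warning; subjects missing a required covariate are excluded with a
logged count. The homozygote scan adjusts for gender + ancestry +
rare-DM burden; the combination table for gender + ancestry only. Both
sets are explicit configuration.

**Homozygote scan.** For each haplotype, exposure = homozygosity for it,
comparison = all other subjects (one odds ratio per haplotype against
the cohort at large, matching the category-vs-rest logic of the
combination table). Zero-homozygote haplotypes yield not-estimable
records; so does a degenerate exposure covering everyone. A result is
flagged low-reliability when the smallest of the four exposure × status
cells holds fewer than 10 subjects.

**Combination table.** Subjects partition into mutually exclusive cells
(common risk alleles 0–6) × (rare-DM count 0, 1, 2+, capped at 2), each
fitted category-vs-rest; parallel rows restrict the rare count to *TYR*
variants. Empty cells are omitted with a log entry.

**Genomic inflation.** Each neutral marker (screened to CADD < 5) gets an
allelic Firth test (intercept + allele dosage, no covariates by default;
PLR statistic by default, Wald by flag — the choice is configuration
because either is defensible). λ = median χ² / 0.4549364 (χ²₁ median, 6
s.f.). Monomorphic markers are excluded; fewer than 10 markers triggers
an instability warning. With the study-realistic 35 markers the median
estimator has null sampling s.d. ≈ 0.3, so single-panel λ values well
away from 1 are expected noise; calibration is asserted on 1000-marker
panels, where the median over 50 replicates sits within ±0.05 of 1.

## Diagnostic classification

Mendelian-only rule: solved iff ≥ 2 rare-DM alleles in one autosomal
recessive albinism gene, or ≥ 1 in an X-linked gene (GPR143). Gene
attribution takes the gene with most qualifying alleles (ties broken by
a fixed category order); HPS1–10 map to an "HPS" category and unlisted
albinism genes to "other".

Haplotype-aware rule additionally solves, with risk haplotypes
defaulting to {`[C;A;A]`, `[C;C;A]`}:

* one rare-DM *TYR* allele + a carried risk haplotype ("TYR het
  haplotype"). With unphased data a heterozygous carrier cannot be
  proven, so carriage means genotype compatibility at every panel site,
  and the trans configuration is presumed — made explicit in the call's
  note. A rare *TYR* allele cannot double as part of the haplotype
  because the panel sites are common by construction and distinct from
  any rare site.
* homozygosity for a risk haplotype with no rare *TYR* allele ("TYR hom
  haplotype").

The haplotype-aware rule is a strict superset of the Mendelian-only
rule, so yield is monotone. Yields are reported both as exact fractions
and nearest-integer percentages.

## Nonparametric trait comparisons

Kruskal–Wallis on midranks with tie correction, p from χ² with
(groups − 1) df; a fully tied sample defines H = 0, p = 1. Per-subject
trait values average the right/left eye measurements when both exist and
fall back to the single available eye (logged) — maximizing usable n.
Pairwise two-group comparisons are adjusted by Benjamini–Hochberg
step-up over the pairwise family; the BH implementation is verified
against the brute-force definition and an external reference
implementation.

## Synthetic cohorts

`simulate_cohort` draws, per subject: ancestry from a mixture; two
haplotypes i.i.d. from the ancestry's frequency vector (hence
Hardy–Weinberg diplotypes, P = 2f₁f₂ or f²); unphased panel genotypes
from the diplotype (GQ 99, depth 40, exact allele balance — QC-clean by
construction); a Poisson rare-DM burden (default mean 0.2, of which a
Binomial 0.3 fraction in *TYR*); case status from a logistic penetrance
model (intercept + homozygous-haplotype log-ORs + per-common-risk-allele
and per-rare-variant terms); Gaussian traits with
homozygous-diplotype-specific locations. Everything is a pure function
of configuration + seed.

Default frequencies are shaped like published population data — the
high-expression promoter T allele near 40% (European) and 80% (African),
`[C;A;A]` near 1% in Europeans — and the default penetrance mirrors the
reported association pattern (strong recessive risk for `[C;A;A]` and
`[C;C;A]`, protection for the high-expression promoter haplotypes, OR
≈ 1.3 per common risk allele, ≈ 2.5 per rare allele, ~1% baseline).
These defaults are illustrative study conditions, not estimates. The
generator does not simulate reads, genome-wide LD, genotyping error or
ancestry admixture; passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to real-data
artefacts.

The deterministic 1208-proband fixture reproduces the published
diagnostic-yield structure: 692 Mendelian-solved probands allocated
across gene categories by the published shares renormalized over the
Mendelian-only yield (TYR 190, OCA2 227, SLC45A2 95, GPR143 60, HPS 60,
SLC24A5 24, other 36; rounding residual absorbed by TYR), 224
haplotype-rescue probands split 185 heterozygous-carrier + 39
homozygous (the integer split consistent with the published 15%/3%
rounding and the 224 total), and 292 unsolved. Its content is synthetic
at the allele level; per-gene splits are fixture parameters, not
predictions.

`null_marker_panel` draws marker dosages Binomial(2, MAF), MAF uniform
on [0.05, 0.5], independent of phenotype — a true null for λ.
`recovery_harness` simulates single-population cohorts with a
homozygous-haplotype effect and re-estimates it through the scan's own
fit; its default risk-haplotype frequency is 0.05 so that a
30,000-subject replicate carries ~75 homozygotes — enough to estimate a
recessive effect per replicate, where the realistic 1% frequency would
leave most replicates with a single-digit exposure cell.

## Problem sizes used in the checks

Acceptance-level simulations run at: 200 replicates of n = 30,000 for
OR-80 recovery and CI coverage; 50 replicates of 1000 null markers
(n = 1000, balanced) for λ calibration; 1000 replicates of three 25-
observation groups for the Kruskal–Wallis type-I rate. The analysis
drivers use one n = 30,000 case-control cohort and one n = 60,000 trait
cohort (with rare-haplotype frequencies raised so all homozygote groups
are populated). These sizes were chosen to make the Monte-Carlo error
small relative to the asserted tolerances.

## Known limitations

* No CNV/structural variation, no splicing re-assessment, no live
  database queries — all functional evidence arrives pre-annotated.
* Carrier status for the het-haplotype rescue is a compatibility
  presumption, not proof; family segregation data would be needed to
  confirm trans configuration.
* λ_GC addresses only mean-level stratification confounding; no PCA or
  mixed-model correction is provided (none was used in the analysis this
  mirrors).
* The Firth module is binomial-logistic only: no FLIC/FLAC variants,
  weights, conditional or multinomial models.
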
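# tyrhap

Haplotype-aware penetrance analysis of common and rare *TYR* variation in
albinism cohorts.

## The problem

Oculocutaneous albinism type 1 is classically a recessive Mendelian
disorder of the tyrosinase gene (*TYR*), yet a large fraction of probands
leave clinical testing without a molecular diagnosis. Part of the missing
risk hides in plain sight: three *common* functionally relevant *TYR*
variants — the promoter SNP c.−301C>T [rs4547091] (an eQTL in a
cis-regulatory element; the reference C allele lowers *TYR* expression)
and the missense changes c.575C>A (p.Ser192Tyr) [rs1042602] and c.1205G>A
(p.Arg402Gln) [rs1126809] — form haplotypes whose joint effect is invisible
to variant-by-variant filtering. In particular, the penetrance of the
hypomorphic c.1205G>A allele is switched by the promoter allele in cis:
homozygosity for the c.[−301C;575A;1205A] haplotype (written `[C;A;A]`)
behaves like a Mendelian mutation, while the same coding alleles on a
high-expression promoter background are benign or even protective.

`tyrhap` implements that haplotype-based analysis as a tested, reusable
pipeline for geneticists working with case-control cohorts:

* **variant selection** — three explicit rules: common protein-coding
  (CADD PHRED ≥ 20, total MAF ≥ 1%, protein-altering), regulatory
  (eQTL ∩ cis-regulatory element), and rare Mendelian (HGMD "DM",
  MAF < 1%, point/small lesions);
* **haplotype engine** — a K-site panel admits 2^K haplotypes and
  2^(K−1)(2^K + 1) unordered pairs (8 and 36 for K = 3); only the 2^K
  all-homozygous diplotypes are resolved from unphased genotypes, because
  only there is the phase unambiguous — no statistical phasing, ever;
* **Firth bias-reduced logistic regression** — written from scratch:
  maximizes ℓ*(β) = ℓ(β) + ½ log det I(β) via modified-score Newton with
  step-halving, profile-penalized-likelihood CIs and penalized LR tests.
  Estimates stay finite under complete separation, the regime of
  one-homozygote exposure cells;
* **association pipeline** — per-haplotype recessive homozygote scan,
  the common × rare risk-genotype combination table, and the genomic
  inflation factor λ_GC (median marker χ² / 0.4549) over low-CADD neutral
  markers;
* **diagnostics & endophenotypes** — diagnostic yield under a
  Mendelian-only rule vs a haplotype-aware rule that treats `[C;A;A]` and
  `[C;C;A]` as Mendelian alleles, plus Kruskal–Wallis /
  Benjamini–Hochberg comparisons of quantitative traits (LogMAR acuity,
  central retinal thickness) across homozygous diplotype groups;
* **synthetic cohorts** — Hardy–Weinberg diplotype sampling, logistic
  penetrance, Poisson rare-variant burdens and diplotype-conditional
  traits, standing in for the access-restricted study data.

## Worked example

```python
import numpy as np
from tyrhap import (bordeaux_fixture, classify_cohort, diagnostic_yield,
                    default_sites, build_tyr_panel, fit_firth, profile_ci)

# 1. Diagnostic yield on the packaged 1208-proband fixture cohort
sites = default_sites()
panel = build_tyr_panel(sites)
subjects, _ = bordeaux_fixture()
calls = classify_cohort(subjects, sites, panel)
for mode in ("mendelian_only", "haplotype_aware"):
    y = diagnostic_yield(calls, mode)
    print(mode, f"{y.percent}% ({y.n_solved}/{y.n_total})")

# 2. Firth fit of a sparse 2x2 exposure (4 exposed cases, 0 exposed controls)
y = np.r_[np.ones(4), np.ones(4), np.zeros(4)]
x = np.r_[np.ones(4), np.zeros(8)]
X = np.column_stack([np.ones(12), x])
m = fit_firth(X, y)
print("OR =", round(float(np.exp(m.coefficients[1])), 2))
```

prints

```
mendelian_only 57% (692/1208)
haplotype_aware 76% (916/1208)
OR = 9.0
```

Counting the two risk haplotypes as Mendelian alleles lifts the solved
fraction from 57% to 76% (24% remain unsolved), and the zero-cell odds
ratio comes back finite at the add-½ value 9.0 — an ordinary logistic fit
would diverge there.

## Analysis drivers

`analysis/01_simulate_cohort.py` … `07_endophenotypes.py` are thin,
numbered narratives over the library: simulate the 30,000-subject
case-control cohort, classify variants and build the panel, run the
homozygote scan, the risk-combination table and the λ_GC check, then the
yield reclassification and trait comparisons. Each writes its tables
under `results/` and prints what it found.

## Limitations

Cohort-level inputs are synthetic: the generator reproduces the
statistical structure the methods assume (HWE diplotypes, logistic
penetrance, neutral markers), not real linkage disequilibrium, genotyping
artefacts or ancestry substructure. See `docs/methods.md` for the model,
parameter defaults and design decisions.
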
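# assortmate

Humans pair assortatively for height: the correlation between partners'
heights in large cohorts is about 0.26, far above chance. `assortmate` is a
toolkit for asking whether that preference is itself genetic — it estimates
the SNP heritability of *choice of mate height* (the partner's height
treated as a trait of the focal individual), the genetic correlation between
own height and mate-height choice, and the quantitative-genetic consequences
of phenotype-driven assortment. It is aimed at statistical geneticists who
want a self-contained, testable reimplementation of this analysis that runs
on synthetic cohorts or on user-supplied PLINK genotypes.

## The model

For a standardized phenotype P = A + E with heritability h², phenotype-driven
mate choice implies the ante-dependence chain A_i → P_i → P_m(i):

    P_m(i) = b·P_i + E_m(i),   b = r_P,

so cov(A_i, P_m(i) | P_i) = 0 and the expected heritability of the partner's
phenotype as one's own trait is **h²_Pm = r_P²·h²** — about 0.04 for height.
The package estimates this quantity by GREML: restricted maximum likelihood
for y = Xβ + g + e with g ~ N(0, A·σ_g²), where A = ZZᵀ/M is the genomic
relationship matrix over standardized genotypes, fitted by an EM first step
followed by average-information (AI) REML, in the eigenbasis of A. A
bivariate GREML with components (σ²_g1, σ²_g2, σ_g1g2, σ²_e1, σ²_e2, σ_e1e2)
yields r_G = σ_g1g2/√(σ²_g1·σ²_g2) between own and partner height. BLUPs
g = σ_g²·A·V⁻¹(y − Xβ) and a = σ_u²·ZᵀV⁻¹(y − Xβ) provide polygenic
prediction of a partner's height from the focal genotype.

Closed-form theory (module `assortmate.theory`) complements the estimates:
the breeding-value correlation among mates m = r_P·h², and the
random-mating heritability implied by the equilibrium one,
h₀² = h²(1 − m)/(1 − m·h²) — assortment inflates height heritability by
about 5 %.

The package also ships the supporting machinery: a synthetic-cohort
generator (HWE genotypes, additive height architecture, rank-matched couple
formation calibrated to a target couple correlation, structured covariates
and optional isolation-by-distance population structure), biobank-style QC
filters (SNP missingness > 2 %, platform-bias Fisher p < 1e-100, HWE exact
p < 1e-50, MAF < 0.05; sample missingness > 5 %, heterozygosity ±3 SD;
height outliers ±3 SD per gender), GRM/LD-pruning/PCA with an ethnicity-core
filter, a couple-swap permutation control, and PLINK .bed/.bim/.fam and
GCTA-GRM I/O. See `docs/methods.md` for the full model description and
numerical choices.

## Worked example

```python
import numpy as np
import assortmate as am
from assortmate.pipeline import Cohort, run_mate_choice_univariate, run_mate_choice_bivariate

cfg = am.SimConfig(n_couples=1000, n_snps=2000, h2_height=0.8, target_rp=0.26, seed=7)
G, phenos, couples = am.simulate_cohort(cfg)
rp = np.corrcoef(couples["female_height"], couples["male_height"])[0, 1]
print(f"realized couple height correlation: {rp:.3f}")

uni = run_mate_choice_univariate(Cohort(G, phenos, couples), covariates=("sex",))
print(f"h2 of mate-height choice: {uni.h2:.3f} (SE {uni.se_h2:.3f})")
print(f"expected r_p^2 h^2:       {am.expected_mate_choice_h2(rp, 0.8):.3f}")

biv = run_mate_choice_bivariate(Cohort(G, phenos, couples), covariates=("sex",))
print(f"h2 own height:   {biv.h2_1:.3f} (SE {biv.se_h2_1:.3f})")
print(f"h2 mate choice:  {biv.h2_2:.3f} (SE {biv.se_h2_2:.3f})")
print(f"r_G = {biv.r_g:.3f} (SE {biv.se_r_g:.3f}), r_P = {biv.r_p:.3f}")
```

Output:

```
realized couple height correlation: 0.269
h2 of mate-height choice: 0.086 (SE 0.034)
expected r_p^2 h^2:       0.058
h2 own height:   0.760 (SE 0.019)
h2 mate choice:  0.088 (SE 0.033)
r_G = 0.729 (SE 0.134), r_P = 0.269
```

The couple correlation lands on its 0.26 target; own-height heritability is
recovered near the generating 0.8; the mate-choice heritability (0.086 ±
0.034) brackets its theoretical value r_P²·h² ≈ 0.058 — at 1,000 couples a
single replicate is noisy, and averaging replicates converges on the
expectation; and the genetic correlation between own height and mate choice
is high (0.73 ± 0.13, consistent with the generative value of 1), saying the
same variants drive both.

The closed-form table for the study conditions:

```console
$ assortmate theory --h2 0.8 --rp 0.26
expected_mate_choice_h2                  0.05408
expected_breeding_value_correlation      0.208
random_mating_h2                         0.7601
heritability_increase_pct                5.253
```

## Command line

`assortmate simulate|qc|grm|pca|reml|reml2|predict|permute|gwas|theory|pipeline`
operate on PLINK .bed/.bim/.fam plus phenotype/couples TSVs (written by
`simulate`) and GCTA-format binary GRMs; `pipeline` runs the whole analysis
from a TOML config and writes a JSON report. Exit codes: 0 success,
2 configuration error, 3 data error.

```bash
assortmate simulate --seed 11 --n-couples 300 --n-snps 500 --out demo
assortmate reml --in demo          # univariate GREML of partner height
assortmate permute --in demo --out demo_perm --n-perm 1000
```

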
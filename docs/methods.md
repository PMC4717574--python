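# Methods

## The question and the model

Couples resemble each other in height (phenotypic correlation among mates
r_P ≈ 0.26 in large cohorts, ≈ 0.23 after adjusting for ancestry and
socio-economic covariates). `assortmate` asks how much of the variation in
*choice of mate height* — the partner's height treated as a trait of the
focal individual — is tagged by the focal individual's own genotype, and
whether those variants are the same ones that determine own height.

Under a standard additive model for a standardized phenotype,
P_i = A_i + E_i with h² = var(A)/var(P), and phenotype-driven mate choice
(the ante-dependence chain A_i → P_i → P_m(i): one's genes act on one's own
height, which drives the partner's height), the partner's phenotype is

    P_m(i) = b P_i + E_m(i),   b = r_P for standardized traits,

so cov(A_i, P_m(i) | P_i) = 0 and the expected heritability of "partner's
height" as one's own trait is

    h²_Pm = r_P² h².

At h² = 0.8 and the covariate-adjusted r_P = 0.232 this is 0.043; a
genotyped-couples cohort should therefore yield a small but nonzero GREML
heritability for partner height, a genetic correlation near 1 between own
and partner height, and polygenic scores for own height that predict the
partner's height up to the √h²_Pm ceiling.

Two further closed-form results are exposed in `assortmate.theory`:

* the expected correlation of breeding values among mates, m = r_P h²
  (≈ 0.21 at r_P = 0.26, h² = 0.8);
* the heritability the trait would have under random mating given its
  equilibrium value, h₀² = h²(1 − m)/(1 − m h²). This is the
  disequilibrium-removal form: normalizing the equilibrium phenotypic
  variance to 1, assortment contributes a fraction m of the additive
  variance as between-locus coupling (directional LD), so V_A0 = (1 − m)h²
  while V_E = 1 − h² is unchanged, giving h₀² = V_A0/(V_A0 + V_E). A
  (1 + m h²) denominator is sometimes quoted; it is inconsistent with this
  variance accounting (it yields 0.55 rather than 0.76 at h² = 0.8,
  m = 0.2) and is not used. At h² = 0.8, m = 0.2: h₀² = 16/21 ≈ 0.762, an
  inflation of exactly 5 %.

## GREML

Variance components are estimated by REML for the mixed model
y = Xβ + g + e, g ~ N(0, A σ_g²), e ~ N(0, I σ_e²), with
A = ZZᵀ/M the genomic relationship matrix over standardized genotypes
z_ij = (d_ij − 2p_j)/√(2p_j(1−p_j)) (missing dosages mean-imputed to z = 0).
This is algebraically the SNP-effects model y = Xβ + Za + e with
a ~ N(0, I σ_u²) and σ_g² = M σ_u², an identity the tests assert exactly.

The restricted log-likelihood (constants dropped consistently) is
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy]. Optimization is one EM update from a
variance-split start (σ_g² = σ_e² = var(y − Xβ_OLS)/2),

    σ_i² ← σ_i² + (σ_i⁴/n)(yᵀP G_i P y − tr(P G_i)),   G_g = A, G_e = I,

which never decreases the restricted likelihood, followed by
average-information (AI) Newton steps, AI_ij = ½ yᵀP G_i P G_j P y, with
step-halving whenever a proposal lowers the likelihood or exits the
parameter space, a variance floor of 1e-8 × var(y), convergence at
|Δ log L| < 1e-6 and an iteration cap of 100. Standard errors come from
the inverse AI matrix at the optimum; the SE of h² = σ_g²/(σ_g² + σ_e²) is
by the delta method. Fixed effects are re-estimated by GLS at the current
variances every iteration.

Because V shares eigenvectors with A, all quantities are computed in the
eigenbasis of A (one symmetric eigendecomposition, then O(nL²) per
iteration where L is the number of fixed effects). A dense
Cholesky-based evaluation of the same likelihood (`reml_loglik`) serves as
the reference formula and is cross-checked against an independently coded
dense oracle in the tests.

BLUPs follow the closed forms g = σ_g² A V⁻¹(y − Xβ) and
a = σ_u² ZᵀV⁻¹(y − Xβ); the identity Σ_j z_ij a_j = g_i holds exactly when
A = ZZᵀ/M, which `snp_effects_from_estimator` verifies by random probes
before scoring.

The bivariate model stacks two traits with genetic covariance blocks
A σ_g1², A σ_g1g2, A σ_g2² and residual blocks I σ_e1², I₁₂ σ_e1e2,
I σ_e2², where the overlap map I₁₂ marks which trait-1 individual is which
trait-2 individual. Six (co)variance components are fitted by the same
EM-then-AI schedule. For the study design — both traits on the same
individuals, one GRM, I₁₂ = I — the stacked covariance is block-diagonal
(2×2 per eigenvalue) in the GRM eigenbasis, and the exact matrix EM update
Σ ← Σ + (1/n) Σ Q Σ is available. A dense path accepts arbitrary overlap
maps and distinct A-blocks; it uses guarded AI steps throughout (with a
damped scaled-gradient first step) and is intended for small n — the two
paths agree on shared inputs to the convergence tolerance.
Correlations are r_G = σ_g1g2/√(σ_g1²σ_g2²), r_E analogous, and
r_P = (σ_g1g2 + σ_e1e2)/√((σ_g1²+σ_e1²)(σ_g2²+σ_e2²)); the model-based r_P
and the covariate-adjusted Pearson correlation of the two traits are both
reported, since they estimate the same quantity by different routes.
Non-PSD proposals are rejected by step-halving; reported correlations are
clipped to [−1, 1].

## Quality control

Thresholds mirror stringent biobank practice: SNPs are excluded for overall
missingness > 2 %, platform-specific missingness bias (two-sided Fisher
exact p < 1e-100), Hardy–Weinberg departure (exact conditional test,
p < 1e-50, no mid-p correction — the plain exact test is the conservative
default), and minor allele frequency < 0.05 computed on the analysis
subset; the filter order is missingness → platform bias → HWE → MAF.
Samples are excluded for missingness > 5 % or an autosomal heterozygosity
rate beyond 3 SD of the cohort mean (the ±3 SD cut is this package's
choice; the heterozygosity criterion is usually delegated to array-specific
internal QC that cannot be reproduced generically). Height outliers beyond
3 SD of their own gender's mean are removed in a single pass (strict
inequality; no iterative re-estimation). The HWE exact test enumerates
heterozygote counts conditional on the allele counts in log space, so it is
stable at p-values far below 1e-100.

Population structure is handled as in large-cohort practice: PCA of the GRM
built from an LD-pruned marker set (greedy sliding window, defaults
window = 50 SNPs, step = 5, r² > 0.2 drops the later SNP), a 3-SD
"ethnicity core" filter on the leading 20 PCs among samples with the
matching self-report label, and the 20 PCs as fixed effects. PCs are
unit-norm eigenvectors (not scaled by √eigenvalue) with the sign fixed so
each vector's largest-magnitude entry is positive. Couples with GRM
relatedness ≥ 0.0625 (closer than first cousins once removed) are excluded
as couples, while related individuals in different households stay in the
sample.

## Synthetic cohorts

The generator (`assortmate.simulate`) emulates a post-QC biobank cohort;
its defaults are the study conditions the analyses assume.

* **Genotypes**: biallelic dosages binomial(2, p) per individual (HWE),
  p ~ Uniform(0.05, 0.5) per SNP — the MAF floor matches the QC threshold.
  With `fst > 0`, per-cluster allele-frequency deviations are Gaussian with
  variance fst·p(1−p) and between-cluster correlation exp(−d/geo_range)
  over cluster-centre distance d (isolation by distance), so genetic
  similarity decays smoothly with geography. Default fst = 0 (panmictic):
  the headline analyses assume a structure-free cohort, and structure is
  switched on only where it is the object of study (the permutation
  diagnostics). Missing genotypes are injected at a configurable rate
  (default 0) to exercise QC.
* **Heights**: A_i from a random causal subset (default 10 % of SNPs) of
  standardized dosages with normal effects, rescaled so the sample variance
  of A is exactly h² (default 0.8) on a standardized phenotype scale;
  E_i independent normal with variance 1 − h²; height in cm is
  165 + 7·P plus a 13 cm male shift (sexes alternate along the sample
  order and are independent of genotype — sex enters the analyses only as
  a fixed effect, so a mean shift suffices).
* **Couples**: the generative pairing mechanism is deliberately minimal,
  since only the regression form P_m = bP_i + E_m is specified by the
  theory. Each individual gets a matching score: sex-standardized height
  plus independent noise with variance (1 − r)/r, and the sexes are paired
  by score rank, which yields expected couple correlation r; a calibration
  loop then rescales the implied correlation until the realized one is
  within 0.02 of the target (default 0.26). One generation of assortment
  only — no multi-generation build-up of directional LD is simulated;
  equilibrium statements are handled analytically in `theory`. Pairing is
  within geographic cluster for 80 % of couple slots (20 % join a mixed
  pool), so couples share local environment without being genetically
  deterministic about it.
* **Covariates**: shared household id; birthplaces scattered 50 km around
  each member's own cluster centre on a ~500 × 800 km grid; ages correlated
  0.9 within couples; a shared couple-level Townsend-style deprivation
  score plus individual noise; parental ages, a cohabitation flag (92 %)
  and an ethnicity label to exercise the couple-identification and core
  filters. All randomness flows from a single seed through per-stage
  streams, so equal configurations reproduce bit-identical cohorts.

What the generator does **not** emulate: linkage disequilibrium between
markers (SNPs are independent, so LD pruning is exercised only by
duplicated/correlated test fixtures), dominance and epistasis, X-linked
variation, genotyping batch effects beyond a platform label, age or cohort
trends in height, and multi-generation assortment. Passing tests therefore
demonstrate the estimators' statistical behaviour under the assumed model,
not robustness to the full messiness of real biobank data.

## Permutation control

To show that couple similarity is phenotype-driven rather than an artefact
of shared geography, age or social stratum, couples are sorted
lexicographically by (female height, male height) — stable sort, ties in
input order; the "order by both heights" instruction is ambiguous and
lexicographic is the convention chosen here — and male partners are swapped
between successive couples (1↔2, 3↔4, …; an odd trailing couple is left
unswapped). The swap preserves each sex's marginal height distribution
exactly and the couple height correlation up to o(1), while destroying
within-couple covariate and relatedness structure. Dependence diagnostics:
Pearson correlation (analytic p) for continuous covariates; plug-in mutual
information (natural log, no bias correction — the permutation null absorbs
the bias) with p = (1 + #{perm ≥ obs})/(n_perm + 1) from permutations of
the female values for categorical covariates; and OLS of within-couple GRM
relatedness on planar Euclidean birthplace distance.

## Pipeline defaults and problem sizes

Both couple members serve as focal individuals (2C records over one GRM;
each individual enters the GRM once). Default fixed effects: intercept,
20 PCs, sex, age, deprivation. Partner-height prediction holds out 20 % of
couples, fits own height on the rest, converts the fit to SNP effects and
scores the genotyped holdout members (whose partners are absent from the
training GRM) against the partner's height; the reported ratio is
accuracy/√ĥ²_choice. The GWAS comparison removes related individuals
(greedy: repeatedly drop the individual with the most relatedness ties
> 0.0625) and runs covariate-adjusted single-marker least squares per
trait. The test suite and acceptance script use cohorts of 2,000 couples ×
5,000 SNPs for GREML recovery (the eigendecomposition of the 4,000×4,000
GRM dominates at ~12 s), 10,000 couples for breeding-value checks, and a
few hundred couples for structural property tests.

## Numerical choices and known limitations

* Variance floors at 1e-8 × phenotypic variance; estimates at the floor or
  a singular information matrix raise an identifiability warning (e.g.
  A = I, where σ_g² and σ_e² are confounded).
* Eigenvalues of the GRM are clipped at 0 (they can be −1e-15 numerically).
* LD pruning keeps the earlier SNP of any offending pair, making the result
  deterministic and order-stable.
* The GRM divisor is the marker count M with mean imputation (not per-pair
  non-missing counts), preserving the exact σ_g² = Mσ_u² algebra.
* GREML standard errors are asymptotic (inverse AI); on traits with
  heritability near 0 the sampling distribution of ĥ² is right-skewed and
  a single replicate can sit at the variance floor.
* The mate-choice model is slightly misspecified by construction: the
  partner's own genetic effect on "partner height" is absorbed into the
  residual (partners are unrelated, so it is orthogonal to the focal
  genotype), and the two focal records of a couple have correlated
  residuals that the univariate model ignores. This mirrors the design of
  the cohort analyses the package reproduces and biases nothing in
  expectation, but the nominal SEs are mildly optimistic.
* `random_mating_h2` equals h² exactly at h² = 1 (no environmental
  variance), so "assortment inflates heritability" is strict only for
  h² < 1.
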
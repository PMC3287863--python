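# Methods

This note documents the statistical models implemented in `famcombine`, the
choices made where the published verbal descriptions leave the algebra open,
the synthetic-data model used by the tests, and known limitations.

## Study design and data model

The unit of analysis is a *mixed sample*: `n_unrelated` unrelated subjects
with binary affection status, plus `n_trios` complete father-mother-offspring
trios. Genotypes are additive minor-allele counts (0/1/2; −1 = missing).
*Founders* — unrelated subjects and trio parents — are the reference set for
allele frequencies and for the principal-component (PC) basis; offspring
alleles duplicate parental alleles and are excluded from both.

Per-SNP hygiene rules, applied identically by every method:

* a SNP monomorphic among founders is skipped (`monomorphic`, no p-value);
* a trio with a missing member genotype, or with an offspring genotype
  incompatible with Mendelian transmission (offspring count outside
  `[#hom-alt parents, 2 − #hom-ref parents]`), is dropped *for that SNP only*;
* individuals with missing phenotype never enter testing;
* any other failure to produce a p-value is flagged (`degenerate`,
  `no_informative_trios`) rather than raised, so panel scans always finish.

MAF classes default to rare &lt; 0.01 ≤ moderate ≤ 0.05 &lt; common
(configurable); phenotype files may use 0/1 or PLINK-style 1/2 coding,
detected per file.

## Chen–Lin weighted combination

Arm 1 is the conditional-on-parental-genotypes (CPG) likelihood over case
trios: P(g_o | g_f, g_m, affected) ∝ τ(g_o|g_f,g_m) e^{β g_o}, where τ is
the Mendelian transmission law (a parent of genotype g transmits the minor
allele with probability g/2, independently). The score and observed
information are the tilted-distribution mean and variance of g_o, so the
log likelihood is concave; β̂₁ is found by Newton iteration from 0 with
step-halving, tolerance |Δβ| &lt; 1e−8, at most 50 iterations, and a
divergence cap |β| ≤ 10 (one-sided transmission patterns have no finite
MLE and are flagged). Trios with two homozygous parents are uninformative.
With only het×hom-ref parents the score at β = 0 reduces to the
transmission contrast (b−c)/2 with information (b+c)/4 — the TDT.

Arm 2 is a logistic regression (statsmodels, Newton MLE) of affection on
allele count over the *case-control subsample*: all trio offspring (affected
probands and unaffected control offspring) plus the unrelated controls.
Unrelated cases are excluded under the default rule (the arm is built around
probands and unrelated controls; an `all_unrelated` rule includes them).

Because the probands appear in both arms, the estimates are correlated. The
cross-covariance is estimated with a stacked influence-function (sandwich)
argument: each independent unit (a trio; an unrelated subject) contributes
its per-unit score to each estimator (zero where it does not enter), and
cov(β̂₁, β̂₂) = Σ_units infl₁ · infl₂ with infl = I⁻¹ × score. Disjoint
arms give exactly 0; a config switch (`assume_independent`) forces 0 for
sensitivity analysis.

A Wald pre-test of β̂₁ = β̂₂ at α_h = 0.05 guards pooling. If it rejects,
the package reports the within-family CPG Wald test for that SNP (flagged
`homogeneity_rejected`) rather than abstaining, preserving per-SNP output.
Otherwise β_c = W₁β̂₁ + W₂β̂₂ with (W₁,W₂) = Σ⁻¹1/(1ᵀΣ⁻¹1) and
se_c = (1ᵀΣ⁻¹1)^{−1/2}; the test is (β_c/se_c)² vs χ²(1). The pre-test is
known to be weakly powered; the suite records but does not assert its power.

## Zhu PC-residual covariance test

PCs are fitted to founders' genotypes standardized by the founder mean and
√(2p̂(1−p̂)) (constant columns dropped, deterministic loading signs:
largest-magnitude entry positive). Genotypes and phenotypes are regressed
on the top L scores (OLS with intercept, coefficients estimated on founders
only and applied to everyone); offspring receive scores by projecting their
standardized rows onto the founder-fitted loadings (the projection of a
fitting-set row equals its fitted score exactly).

The statistic over families i (trio = one family of 3, unrelated subject =
singleton) with residuals ỹ, g̃:

    T = (1/N_T) Σ_i Σ_j ỹ_ij g̃_ij,
    var(T) = (1/N_T²) Σ_i (Σ_j ỹ_ij g̃_ij)²,     Wald = T²/var(T) ~ χ²(1).

The published description specifies the covariance-of-residuals form and
that within-family correlation enters the *variance*; the 1/N_T scaling is a
reconstruction, and any constant scaling cancels in T²/var(T), so the test
is insensitive to that choice. With singleton families and L = 0 the Wald
statistic is asymptotically the classical score test of regressing y on g
(verified to p-value correlation &gt; 0.99 at n = 2,000).

## Zhang GEE-style score test

The score decomposes over the two disjoint subsets, traits treated as
constants:

    U = Σ_unrelated (y_i − μ̂_y,i)(g_i − μ̂_g,i)
    R = Σ_offspring (y_ij − μ̂_y,ij)(r_o − (r_m + r_f)/2)
    var(Z) = Σ_unrelated (y−μ̂_y)² σ̂²_g + Σ_offspring (y−μ̂_y)² v_g
    stat = (U+R)²/var(Z) ~ χ²(1)

μ̂_y, μ̂_g are fitted values of OLS regressions on the PC scores (sample
means at L = 0); σ̂²_g is the residual genotype variance among unrelateds;
v_g = (1{g_m=1}+1{g_f=1})/4 is the exact Mendelian transmission variance.
The published account gives the decomposition verbally but not the algebra;
the form above is a reconstruction validated by its calibration and its
exact reductions (no trios + L = 0 → the closed-form covariance score test;
trios-only with het×hom-ref parents → the TDT χ², for any trait-centering
constant, since the centering factor cancels between R and var(R)).

Choices within the reconstruction: the TDT-like family adjustment
residualizes father, mother *and* offspring genotypes with the same
founder-fitted coefficients, so the adjustment cancels exactly in
r_o − (r_m+r_f)/2 at L = 0 and approximately otherwise while R keeps
conditional mean ≈ 0 given parents under any population structure.
Offspring traits are centered at the founder-fitted trait regression
evaluated at the offspring's projected scores (founder mean at L = 0;
overall offspring mean if there is no unrelated arm). Trios with a missing
parent are excluded at that SNP — handling missing parents by integrating
over parental genotypes is out of scope here.

Both PC-adjusted tests share one basis per dataset (L = 10 by default,
configurable), so they see identical adjustment inputs.

## Synthetic mini-exome generator

The generator emulates the *structure* of a sequenced mini-exome evaluation
cohort, not any particular dataset:

* **MAF spectrum** (`rare_skewed`): a three-stratum mixture — 55% rare
  (log-uniform on [5e−4, 0.01]), 22.5% moderate ([0.01, 0.05]), 22.5% common
  ([0.05, 0.5]) — so most sites are rare, with the lower edge near
  singleton frequencies in a ~700-founder cohort. `uniform` and
  `fixed_list` spectra are available.
* **Genotypes**: founders in Hardy–Weinberg equilibrium, Binomial(2, MAF),
  independent across SNPs (no LD; the tests are single-SNP). Offspring by
  Mendelian transmission.
* **Phenotype**: liability ℓ = Σ_j β_j g_j + ε, ε ~ N(0, 1); affected =
  1{ℓ &gt; c}, with c the empirical (1−K) liability quantile from a
  100,000-individual probe cohort (closed form c = Φ⁻¹(1−K) under the null).
  The default model makes 1% of SNPs causal with β ~ U(0.2, 1.2) — mirroring
  a rare-variant architecture with effects spanning roughly 0.1–1.4 — and
  targets prevalence K = 0.32, a common disease comfortably above the 30%
  bound the package treats as a floor rather than a point target.
* **Design**: 697 unrelated subjects + 194 trios (582 family members) by
  default. Replicates default to the shared-genotype mode: one fixed genotype
  matrix, phenotype noise redrawn per replicate, each replicate on its own
  deterministic child stream of the master seed. Trio ascertainment defaults
  to `random` because phenotype-based ascertainment of a *fixed* trio panel
  is incompatible with redrawing phenotypes across replicates;
  `offspring_affected` and `mixed` (configurable case:control trio ratio)
  are available for freshly drawn designs. Unrelateds are a population
  cohort (case fraction ≈ prevalence) unless a case-fraction quota is set.
* **Stratification** (off by default): two or more Balding–Nichols
  subpopulations (p_k ~ Beta with divergence Fst) with optional
  per-subpopulation liability shifts to create genuine confounding.

What the generator does *not* emulate: linkage disequilibrium, gene-level
clustering of causal variants, covariates (age, smoking), extended
pedigrees, genotyping error. Passing tests therefore demonstrate
correctness and calibration under the idealized single-SNP additive model,
not performance on real exome data.

## Evaluation harness and problem sizes

`run_experiment` tests every SNP with every method per replicate and returns
a tidy frame plus the truth table; summaries follow the standard shapes:
noncausal vs causal rejection rates (with an optional exclusion list of
suspect noncausal SNPs recomputed as a sensitivity column), per-SNP power by
MAF class and effect size, and a top-SNP table (any method ≥ 0.2 power, best
per row flagged, ties shared). Degenerate outcomes count as non-rejections
in headline rates (conservative; counts logged), with `*_valid` columns
restricted to tests that produced a p-value; monomorphic SNPs are excluded
from denominators since they are never tested. No multiple-testing
adjustment is applied — the harness compares methods at a common nominal 5%.

Problem sizes used by the shipped checks (chosen to give stable Monte-Carlo
error at interactive runtimes on one CPU): null calibration uses the full
697 + 194 design with a fixed 2,000-SNP rare-skewed panel and accumulates
phenotype-redraw replicates until every method has ≥ 2,000 valid tests
(99% binomial band around 0.05 at that count ≈ [0.037, 0.063]); the power
grid runs 200 single-SNP replicates per effect size at MAF 0.05 with L = 0
(no structure is simulated, and a one-SNP panel carries no ancestry
information); prevalence is checked on a 100,000-individual cohort drawn at
causal sites only (noncausal sites cannot move the liability).

## Numerical notes

* CPG Newton: concave objective, start 0, step-halving, |β| ≤ 10,
  |Δβ| &lt; 1e−8, ≤ 50 iterations; separation in either arm → `degenerate`.
* Logistic arm: statsmodels Newton MLE, non-convergence or |β̂| &gt; 10
  treated as separation.
* PCA: scikit-learn SVD on the standardized founder matrix with a fixed
  random state, loading signs fixed by convention, so refits are
  bit-reproducible; rank-deficient score regressions fall back to the
  least-squares pseudoinverse.
* Ties at MAF = 0.5 keep the column's coding as drawn; offspring rows never
  influence allele-frequency or basis estimation.
* All randomness flows from `numpy.random.Generator` objects or integer
  seeds via `SeedSequence` spawning; identical seeds give bit-identical
  samples, replicates and p-values.

## Limitations

* Only trios + unrelateds; extended pedigrees are out of scope (the family
  grouping in the covariance test is general, but no other component is).
* The Chen–Lin validity conditions (rare disease, no stratification) are
  knowingly violated by the ~32%-prevalence simulated disease; the method is
  applied anyway, as in the comparison it reimplements, and its homogeneity
  pre-test is too weak to flag the violation reliably.
* The exact published algebra for the covariance statistic's scaling and
  the score test's variance is not recoverable from the verbal
  descriptions; the reconstructions here are validated by calibration and
  reduction identities, not formula-by-formula identity.
* X chromosome, imputation of missing parents, multivariate phenotypes and
  covariate adjustment are not implemented.
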
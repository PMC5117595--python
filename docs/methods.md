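# Methods

## Model

The package implements the standard biometrical decomposition of trait
variance in pedigrees. For one trait observed on n individuals,

    y = Xβ + g + e,   g ~ N(0, A σ²_A),   e ~ N(0, I σ²_E),

with A the additive relationship matrix from the pedigree, so the
phenotypic covariance of two relatives is a_ij σ²_A. Heritability is
h² = σ²_A/(σ²_A + σ²_E): the share of phenotypic variance attributable to
additive genetic effects. Because household and shared-environment effects
are not modelled, anything shared by relatives that mimics additive
relatedness inflates h²; estimates should be read as "familial, consistent
with additive genetic" rather than as strictly genetic causation.

For T traits (T ≤ 4 here) the genetic effects have covariance A ⊗ G and
the residuals I ⊗ E in the individuals × traits layout. r_G and r_E are
the correlation forms of G and E; per-trait h²_t = G_tt/(G_tt + E_tt).

A measured genotype enters as a fixed covariate, coded either *carrier*
(any risk allele vs none — appropriate when the risk homozygote is
essentially absent, as for an allele at frequency 0.10) or *additive*
(risk-allele count). The share of genetic variance explained by a locus is
its Hardy–Weinberg variance over the base model's σ²_A:
2p(1−p)β²/σ²_A (additive) or c(1−c)β²/σ²_A with carrier frequency
c = 1−(1−p)² (carrier). Both fits in this comparison are restricted to
genotyped rows so the two σ²_A estimates are comparable. The reported
proportion is capped at 1 with a flag when the locus variance exceeds the
base σ²_A (possible by sampling noise).

## Kinship

A is built by the tabular (Henderson) recursion in a topological order of
the pedigree: a_ii = 1 + ½ a_fm and a_ij = ½(a_jf + a_jm), with terms for
missing parents dropped; an individual with exactly one recorded parent is
treated as having a unique unrelated non-inbred founder for the other.
Storage is dense, which is exact and comfortably fast at the intended
scale (≲ a few thousand individuals); inbreeding loops are handled by the
recursion itself. The matrix object caches its eigendecomposition and an
eigenvalue-based PSD Cholesky factor, which both the REML fits and the
phenotype simulator reuse. The test suite checks the recursion entrywise
(to 1e-12) against an independent path-counting oracle that sums
(½)^(path length)(1 + F_ancestor) over non-intersecting ancestral path
pairs.

## Estimation

REML is the default (ML available for comparing fixed-effect structures).
All likelihoods are evaluated exactly; no sparse or approximate methods
are used.

*Univariate.* After rotating data and design into the eigenbasis of A the
covariance is diagonal, making each likelihood evaluation O(n). Both β and
the total variance are profiled out analytically, leaving a 1-D problem in
the heritability ratio γ = σ²_A/(σ²_A+σ²_E) ∈ [0, 1]. This is solved by a
deterministic 101-point grid scan followed by bounded Brent refinement
(xatol 1e-10), which is reproducible without seeds, cannot leave the
feasible region, and makes boundary solutions explicit: γ̂ ≤ 1e-8 is
reported as σ²_A = 0 with a boundary flag. (An unconstrained log-variance
parameterisation was considered; the profiled 1-D search is equally exact
and strictly more robust near the γ = 0 boundary, where log-variances push
to −∞.) When A is proportional to I (founders-only data) the likelihood is
flat in γ; the fit is flagged non-identifiable and only the total variance
is meaningful.

*Multivariate.* G and E are parameterised by their Cholesky factors with
log-transformed diagonals, so both matrices are positive (semi-)definite by
construction, and optimised by L-BFGS-B from a deterministic start
(half the per-trait phenotypic variance on each side, identity
correlations) with ftol 1e-9. With rectangular data the fit runs in the
eigenbasis of A (O(n T³) per evaluation); individuals missing some traits
contribute their observed block through a dense likelihood over the
observed entries of A ⊗ G + I ⊗ E — slower, but exact. The dense evaluator
(`loglik_direct`) doubles as the oracle the fast path is verified against
(agreement to 1e-8 at the fitted parameters, and the optimum is checked
against 1000-point random multistarts).

*Uncertainty.* Standard errors come from the numerically differentiated
observed information on (σ²_A, σ²_E), with the delta method for h²; they
are suppressed (NaN) at boundary or non-identifiable solutions, where the
asymptotics do not hold. Fixed-effect covariance is (X'V⁻¹X)⁻¹ at the
fitted variance parameters; Wald p-values are two-sided normal. The test
of h² = 0 is a likelihood-ratio statistic clamped at zero and referred to
the boundary mixture ½χ²₀ + ½χ²₁.

## Supporting statistics

- TDT: transmissions of the risk allele from heterozygous parents with
  both parents and child genotyped; McNemar statistic (b−c)²/(b+c) on
  1 df. Parents heterozygous for two non-risk alleles are uninformative.
- Hardy–Weinberg: 1-df χ² goodness of fit at the sample allele frequency.
- Allele frequencies: allele counting over all genotyped individuals by
  default (matching how sample-wide tables are usually reported), with a
  founders-only option that avoids double-counting transmitted alleles.
- Albuminuria categories: normo < 3.4, micro 3.4–33, macro > 33 g/mol;
  the macro cut is configurable (some displays use 30 g/mol).
- eGFR: re-expressed 4-variable MDRD, 175 × (Scr/88.4)^−1.154 ×
  age^−0.203 × 0.742 if female, serum creatinine in µmol/L, no ethnicity
  multiplier (derived for populations this package does not target).
- Relative risk: risk ratio from a 2×2 table with a log-scale Wald CI
  (1.96 multiplier); swapping the reference group returns exactly 1/RR. A
  zero unexposed risk yields an infinite RR with the CI flagged undefined
  rather than an exception.
- Log transforms are base 10 by default, so a genotype coefficient β on a
  log trait converts to a 10^β-fold multiplicative effect; e.g. β = 0.20
  is a 1.585 ≈ 1.6-fold effect. (Natural-log is available; with it the
  same coefficient would imply only a 1.22-fold effect, which is
  inconsistent with the fold effects this package is designed to mirror.
  Note that under base 10 a coefficient of 0.47 implies 10^0.47 ≈ 2.95-
  fold; the package always reports the exact power.)

## Synthetic data

The simulator is the model's exact forward process, so fitted estimates
can be validated against known truth.

- Pedigrees: founder couples found families; each couple has 1 + Poisson
  (λ = 1.2) children; each child independently marries in a new founder
  and reproduces with probability 0.15, to a maximum depth of 5
  generations. With these defaults the mean family size is ≈ 5.7
  (empirically 5.8 ± 0.25 over seeds) and 135 families give ≈ 771 members,
  the shape of the emulated survey.
- Genotypes: gene dropping — founders from Hardy–Weinberg proportions at
  the configured frequency (ACE-like D at 0.10; TP53-like P at 0.57),
  offspring receive one uniformly chosen allele per parent, so data are
  Mendelian-consistent by construction.
- Phenotypes: y = Xβ + g + e with g = L_A Z L_G', e = Z' L_E' (Z standard
  normal), covariates age ~ U(18, 76), sex ~ Bernoulli(0.515 male),
  weight ~ N(65, 12) truncated at 35 kg. Trait heritabilities (sBP 0.26,
  dBP 0.11, logACR 0.55, logFPG 0.06), the genetic/environmental
  correlation structure, the covariate effects and the genotype effects
  (ACE carrier: 0.47 on logACR, 6.8 on sBP, 8.2 on dBP, 0.050 on logFPG;
  TP53 additive: 0.20 on logACR, −0.5, −0.6, 0.0019) are the emulated
  study's reported values. Total phenotypic variances are *not* reported
  quantities and are emulation choices (sBP 225, dBP 144, logACR 0.64 on
  the log10 scale, logFPG 0.0225), recorded as such in the truth record;
  recovery tests are therefore calibrated against configured truth, not
  against any absolute field-data scale.
- Phenotyping: a fixed fraction (357/771) of members is phenotyped and
  genotyped; the rest are unphenotyped connecting relatives, mirroring
  field studies where pedigree structure is known more widely than
  measurements. Masking is whole-individual.
- All randomness flows from a single `numpy` Generator; identical config
  and seed give bit-identical output.

What the simulator does **not** emulate: household/shared-environment
clustering (e.g. familial infection exposure), nonlinear age trends,
assortative mating, selective mortality, genotyping error and admixture.
Passing recovery tests therefore demonstrate that the estimators are
correct and calibrated *under the model's own assumptions*; they cannot
show that real familial aggregation is free of shared-environment
confounding — the usual caveat for non-twin, non-adoption designs.

## Problem sizes and numerical conventions

- Recovery studies: 100 study-shaped replicates in the test suite (60 in
  the acceptance script) of ~771 members / ~357 phenotyped; calibration
  studies: 1000 null replicates (LRT), 500 (Wald), on 60 nuclear families
  of 5.
- Criterion for "recovered": means over replicates within ±0.05 (h²),
  ±0.10 (r_G) or a small multiple of the Monte-Carlo standard error (β).
- Ties and degeneracies: duplicated trait *names* are an error; duplicated
  trait *values* fit to the r = 1 boundary and are flagged degenerate.
  Monomorphic loci are an error for coding/association. Non-positive-
  definite covariance parameters raise rather than being silently clamped.
- Convergence: univariate, Brent xatol 1e-10 on γ; multivariate, L-BFGS-B
  ftol 1e-9 / gtol 1e-7 with parameter bounds that keep the Cholesky
  factors in a numerically safe range.

## Known limitations

- Dense linear algebra bounds practical size to a few thousand
  individuals (the target scale is hundreds).
- Dominance, epistasis, household effects, linkage and genome-wide
  relationship matrices are out of scope.
- Multivariate standard errors are reported for fixed effects only; SEs
  for elements of G and E (and hence for r_G) are not computed — recovery
  is assessed by simulation instead.
- The multivariate missing-data path scales as O((nT)³) per likelihood
  evaluation and is intended for moderate n.
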
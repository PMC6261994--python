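# Methods

`crosspop` compares genome-wide association results between two ancestry
groups using only per-SNP summary statistics and haplotype reference panels.
This note documents the statistical models, the synthetic-data generator that
the test suite runs against, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Phenotype model and association testing

Quantitative blood-pressure traits are analyzed after imputing pre-treatment
values for treated individuals (+15 mmHg systolic, +10 mmHg diastolic).
Mean arterial pressure is (2·DBP + SBP)/3 and pulse pressure SBP − DBP, both
computed from treatment-adjusted values (configurable — the adjusted-first
order is a package choice; the alternative changes MAP by at most 35/3 mmHg
for treated individuals). Hypertension status uses the *raw* readings plus
the treatment flag: cases have SBP ≥ 160 or DBP ≥ 100 or treatment, with
onset age ≤ 65; controls have SBP < 130 and DBP < 85, no treatment, and age
≥ 50; everyone else — including threshold-qualifying individuals with
unknown onset age — is excluded. Single-SNP tests are ordinary least squares
(quantitative traits) or logistic regression by IRLS (tolerance 1e-8, 50
iterations) on allele dose with covariates; monomorphic SNPs are skipped and
separated logistic fits are omitted. `run_association` accepts a known
residual variance (`resid_var`): with it, the fixed-effects inverse-variance
meta-analysis of disjoint sub-cohorts is *algebraically identical* to the
pooled regression with a study fixed effect (Frisch–Waugh), which the test
suite verifies to 1e-6; with estimated residual variances the identity is
only approximate.

## QC, inflation correction and meta-analysis

Per-study QC removes SNPs with call rate < 0.95, imputation R² < 0.5 or
MAF < 0.01 (strict inequalities; a SNP failing in one study is only missing
from that study). Genomic-control λ is median(χ²)/0.45494. The LD-score
regression intercept comes from a weighted regression of χ² on N·ℓ/M with
weights 1/(2(1 + N·ĥ²·ℓ/M)²) iterated once from an unweighted first pass.
Studies with N > 3000 are corrected by the intercept, others by λ; the
factor is floored at 1 (intercepts below 1 occur by sampling noise and
deflating significance is non-standard), and correction divides χ² (SE ×
√factor). Pooling is fixed-effects inverse-variance; heterogeneity is
Cochran's Q with a χ²ₖ₋₁ upper tail. Reported SNPs need heterogeneity
P > 1e-6 and effective N at least half the total. Follow-up takes the union
over the five traits of SNPs with P < 1.6e-5; a signal validates when the
combined P < 5e-8, the stage-2 P < 0.05 (two-sided, with the direction
handled by the separate concordance criterion), the lookup P < 0.05/k for k
lookup SNPs, and all directions agree.

## Loci and cross-population classification

A locus is the transitive closure of the "≤ 500 kb apart on the same
chromosome" relation over significant SNPs ("at most" inclusive). Sentinels
minimize P, with ties broken by position then identifier. A sentinel is
novel only if every known trait SNP is > 500 kb away *and* has r² < 0.1
with it in the designated reference panel. Loci are classified by the
sentinel's MAF pair: group 1 (≥ 0.01 in both populations), group 2a (< 0.01
in one, ≥ 0.05 in the other), group 2b (< 0.01 in one, 0.01–0.05 in the
other), excluded when rare in both. Ancestry-specific flags require the
index-population sentinel to be genome-wide significant while the other
population shows MAF < 0.05 and no window-Bonferroni signal (min P >
0.05/m over the m SNPs within ±500 kb).

## Heterogeneity of genetic impact and the haplo-SNP procedure

The genetic impact of a SNP is b = β·σ with σ = √(2·MAF·(1−MAF)) — the
genotype–phenotype correlation. Cross-population heterogeneity is
Q = (b₁−b₂)²/(se₁²+se₂²) against χ²₁, computed only for SNPs non-rare
(MAF ≥ 0.01) in both groups on an allele-aligned universe (misaligned input
is refused). Scan labels: significant (P < 5e-8), suggestive (5e-8 ≤ P <
1e-6). At ancestry-specific loci the three-step procedure selects (ii) the
haplo-SNP — smallest heterogeneity P within ±500 kb of and r² ≥ 0.1 to the
sentinel, with r² taken in the index population's panel — declared
significant at the region-wise threshold 1.5e-4 = 5e-8 × (3 Gb / 1 Mb), and
(iii) the alternate ancestry-specific SNP with the smallest association P in
the second population within ±500 kb of and r² ≥ 0.1 to the haplo-SNP (r² in
the second population's panel, since that is where the SNP is polymorphic).
Both effects are oriented onto the haplo-SNP's effect allele by the sign of
their LD correlation with it before classification: neutral when the smaller
|b| is below τ = 0.25 of the larger (τ configurable; no published numeric
rule exists), otherwise inverted or concordant by sign.

## Transethnic genetic correlation

The estimator is a cross-population, moment-based generalization of LD-score
regression with MAF- and LD-dependent per-SNP heritability (a
maximum-likelihood fit in the style of the original transethnic-correlation
programs is deliberately out of scope; the moment version captures the
per-SNP weighting at a fraction of the cost). Per-SNP variance weights are
w_j ∝ [2p_j(1−p_j)]^(1+α) times an LD-score-quintile multiplier
(mean-normalized; defaults α = −1 and unit multipliers give the
equal-standardized-variance model). Generalized scores are
ℓ̃_ki = Σ_j r_k(i,j)² w_kj within population k and
ℓ̃x_i = Σ_j r₁(i,j)·r₂(i,j)·√(w₁j·w₂j) across (signed r products,
geometric-mean weights). The fitted moments are

    E[χ²_ki]  = intercept_k + N_k·h²_k·ℓ̃_ki/M_k
    E[Z₁ᵢZ₂ᵢ] = intercept_x + √(N₁N₂)·C·ℓ̃x_i/√(M₁M₂)

with C the coheritability and ρ = C/√(h²₁·h²₂). Within-population sums run
over each panel's full polymorphic SNP universe M_k (a SNP absent from the
other panel still pushes signal into its shared neighbors); regression rows
are the shared SNPs. The cross intercept defaults to 0 (non-overlapping
cohorts) and can be set (1 for complete overlap); the within intercepts are
free by default and can be fixed. Weights are inverse-variance
approximations updated once from an unweighted first pass. Uncertainty is a
200-contiguous-block jackknife; the reported ρ is the jackknife
bias-corrected ratio, which removes the O(1/B) inflation of a ratio of noisy
estimates (about +0.05 at ρ = 0.9 under the test conditions). Impact mode
correlates standardized effects; effect mode re-aggregates the same fitted
per-SNP covariances and variances on the per-allele scale (dividing by the
allele SDs before summing); the two coincide when the populations share
frequencies. The test against ρ = 1 is a one-sided normal upper tail on
(1−ρ)/SE.

## Synthetic data generator

The generator is the package's test bed and defines the study conditions:

* **Frequencies** — ancestral ALT frequencies uniform on [floor, 1−floor];
  each population Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) around the
  ancestral value. Default F_ST 0.11 (an East Asian/European-scale
  divergence); with F_ST ≥ 0.15 and a small floor a nonzero fraction of SNPs
  is rare in one population and common in the other, emulating group-2a
  architecture.
* **Haplotypes** — per-block Gaussian-copula AR(1) thresholded at each SNP's
  frequency quantile. Defaults: 20 000 SNPs in 800 independent blocks of 25
  with adjacent-latent correlation 0.9 (binary adjacent r² ≈ 0.51 at
  p = 0.5). Small blocks were chosen so that a 2e4-SNP genome has enough
  independent LD units for the 200-block jackknife to be valid and for the
  score regressions to be well conditioned; an optional per-block
  correlation range (`rho_range`) produces heterogeneous LD strength.
  Positions are uniform over 22 equal chromosomes of a 3-Gb genome so the
  500-kb locus rules are exercised.
* **Effects** — a fraction π of SNPs is causal (default 0.05); shared causal
  effects are bivariate normal with correlation ρ_g and per-SNP variance ∝
  [2p(1−p)]^α per population, rescaled so Σβ²·2p(1−p) equals h² exactly
  (defaults 0.107 and 0.086, the systolic-pressure scale). Effects are drawn
  against *panel-realized* frequencies: a SNP monomorphic in a panel cannot
  carry heritability there, so the h² target refers to panel-observable
  SNPs — the estimand a summary-statistics method can actually see. An
  optional fraction of causal SNPs is private to one population.
* **Summary statistics** — per block, Z ~ MVN(√n·R·b, R) with R the realized
  panel correlation matrix and b the standardized effects; β = Z/(√n·σ),
  SE = 1/(√n·σ). Near-singular R is Cholesky-factored with an escalating
  ridge starting at 1e-8 (with a warning).
* **Cohorts** — genotypes Binomial(2, p); SBP/DBP are intercepts plus
  genetic value, an age term and Gaussian noise (zero noise allowed for
  exact-fit tests; negative rejected); a configurable fraction is treated,
  and hypertensive individuals receive an onset age below their current age.
* **Planted ancestry-specific locus** — a 51-SNP shared AR(0.95) haplotype
  block (10-kb spacing) with one causal SNP private to each population
  (standardized impact ±0.02, the magnitude typical of genome-wide
  significant blood-pressure SNPs) and opposite signs. This is the positive
  control for the haplo-SNP procedure: at N = 1e5 per population the
  procedure recovers an inverted-type result significant at 1.5e-4 in ≳95%
  of replicates.

All generators are pure functions of (configuration, seed).

## Power and cross-ancestry overlap

True standardized effects are point-normal (Bernoulli(π) causal indicators,
variance h²/(mπ), cross-population correlation ρ_g); observed Z ~
Normal(√N·b, 1) independently per SNP (an LD-free observation model — locus
counts, not fine-mapping, are the quantity of interest). Significant SNPs
(two-sided P < 5e-8) merge into loci by 500-kb chaining; loci overlap across
populations when any significant SNP of one lies within 500 kb of a
significant SNP of the other. Counts and the nonoverlap proportion
(nonoverlap/(overlap+nonoverlap)) are averaged over 100 trials with
Monte-Carlo SEs, on a default desk-scale genome of 1e5 SNPs. Expected
behavior — counts non-decreasing and nonoverlap non-increasing in N, with a
floor when private causal variants exist — is asserted by the tests;
absolute nonoverlap values depend on the full SNP count and fitted real-data
parameters and are not comparable to published consortium figures at this
scale.

## Selection-region enrichment

Sentinels (1-based positions) hit 0-based half-open regions after a
coordinate-convention shift. The background probability p₀ defaults to the
merged-region genome fraction but should be supplied explicitly when
reproducing published analyses, because the enrichment P is sensitive to it
and published analyses rarely print it. The test is the exact upper-tail
binomial P(X ≥ k | n, p₀) by direct pmf summation (matches integer-exact
enumeration to 1e-12 for n ≤ 100).

## What the synthetic experiments do and do not show

Passing tests demonstrate that the estimators are unbiased and calibrated
*under the generator's assumptions*: Balding–Nichols drift, block-diagonal
AR(1) LD shared in structure across populations, point-normal effects, exact
per-SNP variance models, and panels drawn from the same process as the GWAS.
Real data violate several of these (continuous recombination-driven LD,
population-specific LD patterns, MAF spectra from demography, stratification
and overlap between cohorts, imputation error), so recovery here bounds
methodological error, not total real-data error. Headline published values
(h² of 0.107/0.086, ρ of 0.898/0.851, specific locus counts, nonoverlap
ranges) require the original consortium data and are out of scope; the
package reproduces the printed *derived* quantities (thresholds, Wald P
values, proportions) exactly from their printed inputs.

## Problem sizes

Default experiment sizes — 2e4 SNPs for correlation recovery, 1e4 SNPs for
calibration, 1e5 SNPs and 100 trials for power, 100 replicates for the
planted-locus control — were chosen as the smallest sizes at which the
statistical assertions have comfortable margins; all scale up linearly via
their configuration objects.
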
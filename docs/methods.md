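# Methods

This note documents the statistical models, numerical choices and known
limitations of `magblup`. Nothing here asserts an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Growth traits

Seventeen weekly weights per animal span four consecutive 4-week
intervals. ADG_k is the ordinary-least-squares slope (kg/day) of weight
on the recorded day offsets over a 5-point window; windows share their
boundary points ({1–5}, {5–9}, {9–13}, {13–17}), which is the only
layout in which four 5-point windows tile 17 points. Regression uses
actual day offsets rather than nominal week indices, so modest schedule
jitter is tolerated. Slopes are invariant to adding a constant to all
weights and scale inversely with day spacing (both property-tested).

## Genotype QC and the GRM

QC order is fixed: SNP call rate (≥ 0.95) → minor allele frequency
(≥ 0.05) → Hardy–Weinberg χ² (1 df, removal when p < 1e-8) → animal call
rate (≥ 0.90) → per-SNP mean imputation of residual missing dosages.
Two conventions worth flagging:

* the HWE filter removes SNPs *deviating* from HW proportions
  (p below the threshold); the opposite direction would remove nearly
  every SNP and cannot be the intended rule;
* only integer-coded genotypes enter the HWE genotype counts, so that a
  table containing mean-imputed (fractional) dosages passes through the
  filter unchanged — QC is idempotent.

The GRM standardises each SNP by its own heterozygosity,
G = (1/m) Σ z_i z_iᵀ / (2 p_i (1 − p_i)) with z_i the dosage centred at
2p_i. Allele frequencies are the observed ones; no base-population
frequencies exist without a pedigree. Mean imputation stands in for
haplotype-based imputation, which is out of scope; on near-complete data
the difference is negligible.

## Compositional treatment of the microbial counts

Core filtering keeps MG with non-zero counts in at least
⌈0.70 · n_samples⌉ samples and reports the fraction of total counts
retained. Zeros in the core table are replaced by the geometric
Bayesian-multiplicative rule: with prior proportions t_j proportional to
the column geometric means of the observed non-zero proportions and a
prior strength s (default √(mean depth), configurable — the published
method does not pin the hyperparameters), a zero in a sample of depth N
becomes t_j · s/(N + s), and the sample's non-zero proportions are
multiplied by one minus the imputed mass. This preserves the ratios
between observed parts and exact closure.

The alr reference is chosen by a two-condition trade-off: among
candidates whose alr geometry has a Procrustes correlation with the clr
("exact") geometry in the top decile (configurable), take the one with
the smallest variance of log relative abundance. Both configurations
are column-centred before the Procrustes statistic
Σσ(AᵀB)/√(tr AᵀA · tr BᵀB). Full dimensionality is used (no principal
sub-space truncation). The alr transform and its softmax inverse
round-trip to 1e-12, and clr/alr agree with scikit-bio's implementations
(cross-checked in the tests).

## The Gibbs GBLUP engine

The model for t traits on n genotyped animals is
y = Xb + u + e, u ~ N(0, G ⊗ K), e ~ N(0, R ⊗ I), flat priors on b.
The sampler rotates once into the eigenbasis of K (K = VDVᵀ): the
rotated breeding values are conditionally independent across animals, so
each scan costs O(nT³) and a univariate 3000-iteration chain on 400
animals takes well under a second. The rotation is exact. Eigenvalues
below `jitter` (1e-6) are floored and the count logged.

Full conditionals:

* b — matrix-normal with row covariance (XᵀX)⁻¹ and column covariance R;
* rotated u — per-animal T-variate normal with precision
  R⁻¹ + G⁻¹/d_i (precomputed per eigenvalue when (G, R) are fixed);
* variances — scaled-inverse-χ²(df0 + q, (SS + df0·S0)/(df0 + q)) in one
  dimension and the matching inverse-Wishart IW(df0 + q, df0·S0 + SS)
  for matrices;
* missing phenotypes — data augmentation from the residual conditional
  normal, grouped by missingness pattern. Genotyped-only sires are
  all-missing rows; the microbiome-driven strategy sets every ADG record
  missing.

**Prior-scale convention.** The conventional prior scale is
S0 = var(Y)·(df0 + t + 1)·R², with R² = 0.5 by default and df0 = 5
(univariate), 3 (multivariate genomic), 5 (residual). The conditional
above uses the textbook scaled-inverse-χ²(df0, s0²) parametrisation, in
which that conventional S0 equals df0·s0²; auto-derived scales therefore
divide by df0, putting the prior mode of σu² at R²·var(y) as intended.
A note on one published inconsistency: with var(y) = 0.148, df0 = 5,
t = 1, R² = 0.5 the S0 formula yields 0.518, not the 0.48 that
accompanies it in one supplementary figure; the formula is implemented
as printed in the main text.

Posterior summaries report the median, the shortest 95% HPD interval
(via `arviz.hdi`), the sign probability P0 (posterior mass on the side
of zero matching the median's sign), a Geweke Z comparing the first 10%
against the last 50% of the chain with batch-means window variances, and
a batch-means MCSE (⌊√n⌋ batches) flagged when it exceeds sd/10.
Chains with |Geweke Z| > 3 or a failing MCSE check are flagged but kept.

The sampler was validated three independent ways: the variance full
conditional against its closed form (Kolmogorov–Smirnov), the posterior
mean of u against the direct mixed-model-equations BLUP solution under
fixed covariances, and the full univariate posterior against a
brute-force two-dimensional grid evaluation of the exact marginal
posterior (during development; the first two are kept as tests).

## Estimation campaign

Per-MG univariate h² scans and per-MG×ADG bivariate rg scans derive each
model's seed as a 31-bit hash of the master seed and the trait ids, so
results are independent of execution order and resumable. Growth-trait
parameters come from the six pairwise bivariate models; each trait's h²
posterior concatenates its three thinned chains. The permutation null
shuffles the phenotype vector only, leaving GRM and fixed-effect design
in place (permuting X with y would preserve the fixed-effect alignment
and break only the genotype link — the stricter option is the default).
Prior sensitivity re-runs a model over df0 grids with S0 recomputed per
setting.

## Covariance assembly and bending

Multi-trait (G, R) for the 36-trait evaluations are assembled from
pairwise bivariate estimates: off-diagonals from the pair's covariance,
diagonals as the arithmetic mean of the trait's variance estimates
across all bivariates containing it (an unbiased combination that avoids
re-running models; the source model of every entry is recorded).
Bending floors eigenvalues at 1e-3 without touching eigenvectors, hence
is idempotent and a no-op above tolerance. Validation checks, with
inclusive boundaries (robust to roundoff at exactly the threshold), that
no entry moved more than its posterior SE and no trait's h² shifted by
more than 5%.

## MG subset selection

Candidates need P0 ≥ 0.85 against at least one ADG trait and numerator
mean relative abundance ≥ 0.001% (both inclusive; the abundance rule
keeps the abundant genes — low-count genes are the technically noisy
ones). The uniform-sign variant additionally requires the four rg
medians to share a sign; exact zeros carry no sign and are excluded.
Forward selection cycles ADG_1→ADG_2→ADG_3→ADG_4, regressing the current
trait's GEBV on the other three ADG GEBV, all previously selected MG
GEBV and one candidate, adding the candidate that minimises
AIC = n·ln(RSS/n) + 2k (constant terms dropped; ties break on candidate
id). It stops at 8 selections per trait (32 total); the fixed count is
the stopping rule.

## Breeding strategies, accuracy, response

All strategies fix (G, R) at the assembled, bent estimates and sample
only b, u and missing phenotypes. Accuracy_i = √(1 − sd_i²/(g_ii σu²));
finite-chain noise can push sd_i² above g_ii·σu², in which case the
accuracy is clipped to 0 and counted rather than propagated as NaN.
Response to selection fixes the selected set by ranking posterior-mean
GEBV (top ⌈p·n⌉, p = 0.10, intensity φ(z_{1−p})/p = 1.755) and
summarises the posterior of mean(selected) − mean(all); the sign
convention makes upward selection positive. Accuracies are reported over
all animals in the GEBV tables; averaging over phenotyped animals only
is a row subset away.

## Synthetic herd generator

The generator emulates the statistical structure the analysis assumes:
~359 phenotyped cattle plus ~30 genotyped-only sires; unlinked biallelic
SNPs with allele frequencies uniform on the MAF window; a multi-breed
herd (3 breeds, Balding–Nichols differentiation Fst = 0.10) with
half-sib families (each animal draws one allele from its sire, one from
its breed); breeding values drawn with covariance (scale matrix) ⊗ GRM
through factorisations of both; 17 weekly weights from a continuous
piecewise-linear trajectory with interval slopes
adg_means + b + u + e and 2 kg i.i.d. weighing noise (weekly platform
weighings; within-animal autocorrelation of the measurement error is not
modelled); and multinomial KO counts with softmax link from Gaussian
latent log abundances — the simplest generative model consistent with
the alr-Gaussian analysis — with depths uniform on 50k–200k so
structural zeros arise naturally. Default trait levels: ADG means
1.57/1.50/1.48/1.41 kg/day, phenotypic sd 0.42 kg/day (CV ≈ 27%),
h² = 0.31/0.27/0.29/0.27 with the moderate positive ADG correlation
block (0.39 between intervals 1 and 3, −0.13 between 3 and 4); MG h²
uniform on 0.19–0.44, latent sd 0.55; a 17-level fixed factor with
effect sd 0.10 (ADG) / 0.30 (MG, log scale).

What the generator does *not* emulate: linkage disequilibrium,
genotype-by-environment interaction, compositional measurement artefacts
beyond multinomial sampling, and pedigree depth beyond one sire
generation. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not
robustness to violations of them.

**Information limits at desk scale.** The reference validation scenario
(400 animals, 2000 SNPs, h² ≈ 0.3) carries limited information about
heritability: the profile-likelihood standard error is ≈ 0.11–0.13, so
point estimates scatter broadly around the truth no matter the
estimator, and posterior medians additionally lean toward the prior mode
(R² = 0.5) — genomic correlations correspondingly shrink toward zero
through their inflated variance denominators. HPD95% intervals remain
well calibrated (coverage is what the acceptance suite asserts tightly).
This mirrors the prior sensitivity that herd-scale analyses of a few
hundred animals report, and is why the tests emphasise interval coverage
and qualitative orderings (combined > direct accuracy) over point
accuracy.

## Problem sizes used in validation

Chain lengths in tests and the acceptance script are desk-scale:
3000–4000 iterations with 1000 burn-in and thinning 5 for parameter
estimation, 1500/300/4 for strategy runs, 110k/10k/5 for the BLUP
equivalence check; recovery uses 20 seeds, strategy ordering 10, the
permutation null 50 permutations. Production settings (500k iterations,
100k burn-in, thin 50; 1000 permutations) are reachable through
`McmcSettings`/`RunConfig` without code changes.
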
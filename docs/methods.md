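# Methods

## Problem and model

Phenome-scale analyses test one hypothesis per trait, but traits are
correlated, so a Bonferroni correction by the raw trait count over-corrects.
When individual-level phenotypes are unavailable, the trait correlation
matrix can be reconstructed from GWAS summary statistics and then reduced to
an effective number of independent tests.

The package implements the pipeline

1. harmonize per-trait summary statistics to a common SNP set and effect
   allele;
2. estimate each pairwise phenotypic correlation from summary statistics;
3. condition the resulting matrix (symmetrize, clip to [-1, 1], unit
   diagonal, resolve missing cells);
4. eigendecompose it and report the effective number of independent tests
   and the adjusted significance threshold.

### Cross-trait LD score regression

For SNP j with LD score `l_j` (the sum of squared correlations with the
SNPs in a local window, including itself), the product of two traits'
association Z scores satisfies

    E[z1_j z2_j] = sqrt(N1 N2) * rho_g_cov * l_j / M  +  rho * Ns / sqrt(N1 N2)

where `M` is the number of SNPs in the model, `N1`, `N2` the GWAS sample
sizes, `Ns` the number of shared individuals, `rho_g_cov` the genetic
covariance and `rho` the total phenotypic correlation.  The slope of the
regression of `z1*z2` on `l_j` therefore carries the genetic covariance and
the intercept carries `rho * Ns / sqrt(N1 N2)` — equal to the phenotypic
correlation itself when both GWAS were run on the same sample.  In the
univariate special case (`z1 = z2`) the slope scales to the SNP
heritability and the intercept estimates the confounding inflation.

Fits use a two-step weighting scheme: an unweighted first pass estimates
the (co)heritability terms, then weights
`1/(max(l,1) * [(1 + N1 h1 l/M)(1 + N2 h2 l/M) + (sqrt(N1 N2) cov_g l/M + a)^2])`
(univariate analogue with a squared term) are applied in a second pass.
Standard errors come from a delete-one-block jackknife over contiguous SNP
blocks (default 200 blocks; equal spans in input order, remainder to the
last block), which is robust to local LD between neighbouring regression
observations.

No chi-square cap is applied by default: filtering out strongly associated
SNPs truncates the `z1*z2` distribution and drags the intercept away from
the observed correlation (the filtering experiment in the acceptance suite
demonstrates this), so all SNPs should be kept when the intercept is the
quantity of interest.  A cap remains available for genetic-correlation use.

### Slope identifiability and the degeneracy guard

The slope is identified only insofar as LD scores vary across SNPs.  For a
panel of independent SNPs the true `l_j` is exactly 1 for every SNP and
in-sample estimates differ from a constant only through chance-LD sampling
noise with coefficient of variation of order `sqrt(2w)/n` (window `w`,
panel size `n`) — well under 1% in the regimes this package simulates.
Ordinary least squares on such a regressor is numerically meaningless: the
intercept inherits the slope noise amplified by the lever arm
`mean(l)/sd(l)`, giving per-replicate standard deviations above 1 for an
intercept whose true value is below 1.

Both fits therefore apply a conditioning guard, analogous to an `rcond`
threshold in least squares: when the weighted CV of the LD scores is below
`min_l2_cv` (default 0.05), the slope is declared unidentified, pinned at
0 with a warning, and the intercept becomes the weighted mean of the
response (jackknifed over the same blocks).  The threshold separates
chance-only variation (CV well below 1% at the simulated sizes) from any
real LD structure (CV of order 1 for human panels and for the block-LD
simulations, which reach CV > 30%).

The guard has one quantifiable consequence for independent-SNP designs:
the genetic term `sqrt(N1 N2) * cov_g * mean(l)/M` cannot be separated out,
so the intercept estimates

    rho * Ns / sqrt(N1 N2)  +  sqrt(N1 N2) * cov_g / M.

The second ("finite-M leakage") term vanishes at genome scale
(M = 200K gives 0.006 at N = 5000 and cov_g = 0.25) but matters at
desk-scale M; the problem sizes below were chosen with it in mind.  This is
not an artifact of the guard — with constant LD scores the two terms are
structurally confounded in the summary statistics, and no estimator can
separate them without external LD information.

### The beta-correlation (metaCCA-style) estimator

The Pearson correlation of two traits' per-SNP effect sizes is provided as
an alternative estimator.  Its expectation is a variance-weighted blend of
the genetic correlation (through shared causal effects) and the phenotypic
correlation (through sampling covariance of the two GWAS in shared
individuals): it approaches the realized genetic correlation when genetics
dominate and shrinks toward zero when the trait correlation is
environmental and the cohorts are disjoint.  It carries no standard error
and is most defensible for trait families where genetic and phenotypic
correlations coincide.  The within-group pair policy exists for this
estimator: pairs are only estimated inside user-declared cohort groups
where sample overlap is known to be good.

### Effective number of tests

Given the conditioned correlation matrix with eigenvalues `lambda_1..M`,

    Veff = 1 + (M - 1) * (1 - Var(lambda) / M)

with `Var` the sample variance (denominator M - 1) — the convention of the
published SNPSpD code, which makes the all-ones matrix give exactly 1 and
the identity give exactly M.  Negative eigenvalues (possible for pairwise-
estimated matrices, which are not guaranteed PSD) are kept in the variance;
Veff is the divisor of alpha without rounding to an integer.  The Li & Ji
count `sum_i [I(lambda_i >= 1) + frac(lambda_i)]` is reported as a
cross-check, with eigenvalues snapped to integers within 1e-9 first (the
fractional part is discontinuous there) and floored at 0, following matSpD
practice.  The matrix is deliberately not projected to the nearest PSD
matrix by default; conditioning (clipping and symmetrizing) happens before
eigendecomposition because the spectrum of a matrix with |r| > 1 entries is
not interpretable as a correlation spectrum.

## Simulation engine

The generator emulates two GWAS cohorts A and B drawn from one union
sample laid out `[A-only | shared | B-only]`, so shared individuals have
identical genotypes, environmental factors and phenotype values in both
cohorts.

* Genotypes: per-SNP MAF ~ Uniform(0.05, 0.5); dosages Binomial(2, MAF)
  (drawn as one uniform against the two cumulative cut points — identical
  in law, one RNG stream).  With `ld_blocks = k > 0`, SNPs are split into k
  equal blocks and each haplotype is dichotomized from a latent AR(1)
  Gaussian whose adjacent correlation is `sqrt(ld_r_max)`, so neighbouring
  latents have squared correlation `ld_r_max` (genotype-scale r2 is
  slightly lower after dichotomization).
* Phenotypes: `y_t = X_std b_t + F c_t` with `X_std` the union-standardized
  dosages and `F` a shared bank of `n_env_factors` standard-normal
  environmental factors.  Weight vectors are random directions
  (Gram-Schmidt-adjusted so the weight-level correlation is exact), scaled
  so each phenotype has unit variance, genetics contribute `genetic_pct`%
  of it, and the cross-trait covariance splits genetic:environmental in the
  same proportion, giving `corr(y1, y2) = rho_target` in expectation.
  Per-factor variance shares are thus random (normalized squared
  Gaussians), not uniform.
* GWAS: per-SNP simple linear regression of phenotype on dosage
  (`beta = cov/var`, textbook standard error, `z = beta/se`); monomorphic
  or zero-residual SNPs are dropped with a warning.  Inside the scenario
  runner the Z statistics are computed from the union-standardized matrix
  (z is invariant to per-SNP linear rescaling); the beta-correlation
  estimator uses raw-dosage effect sizes.
* Scenario runner: per replicate, GWAS of phenotype 1 in A and phenotype 2
  in B; LD scores computed in-sample from the union genotypes; the chosen
  estimator applied; the observed correlation recorded as the Pearson
  correlation in the union sample.  Replicates use counter-derived RNG
  streams `(seed, replicate)` (Philox), so runs are bit-reproducible and
  order-independent.

Defaults mirror the published simulation grids: `rho_target = 0.5`,
`n_env_factors = 1000`, 100 replicates per scenario.  (The accompanying
description of those grids mentions a correlation of -0.7 and 100
environmental factors in prose, but every tabulated result is consistent
with 0.5 and 1000; the tabulated values are the ones this package
reproduces and are therefore the defaults.)  For the unbalanced-cohort
rows, the printed overlap counts exceed the smaller cohort, so the overlap
*percentage* is treated as authoritative:
`n_overlap = round(pct * min(nA, nB))`.

### What the generator does not emulate

Independent SNPs (or stylized AR(1) blocks) rather than realistic human LD;
no allele-frequency/effect-size coupling; no case/control traits,
covariates, relatedness or population stratification; no strand errors or
imputation noise (harmonization code paths for those are exercised with
constructed tables instead).  Passing simulation tests therefore validate
the estimators' sampling behavior under the stated model, not robustness to
real-data pathologies.

## Problem sizes used by the test and reproduction scripts

Simulation checks run at reduced SNP counts and replicate numbers chosen so
that Monte-Carlo error and the finite-M leakage term stay within each
check's stated tolerance:

* overlap-attenuation series: M = 20K, N = 5000, 12-50 replicates, purely
  environmental correlation (leakage-free by construction);
* 10%/90%-overlap deviation checks: M = 24K / 20K, 50% genetic share,
  50 replicates;
* 7.5K-SNP scenario: native size, 30-100 replicates;
* full-overlap purely genetic recovery: M = 80K, 8-50 replicates (at this
  M the leakage term contributes ~3 points of deviation; at 20K it would
  contribute ~25 and the check could not be met by any estimator without
  external LD information — see the identifiability note above);
* beta-correlation checks: M = 1000, N = 5000, 50 replicates;
* LD-score windows of 20-50 SNPs for independent-SNP panels, where the
  window only shifts the constant offset of the near-constant LD scores.

## Numerical and format choices

* Matrix conditioning order: symmetrize, clip, unit diagonal; missing-cell
  policies `fail` (error listing pairs), `drop_trait` (iteratively remove
  the trait with most missing cells; ties drop the lexicographically last
  id, for determinism), `zero` (substitute 0, logged loudly).  The chosen
  policy is recorded in output metadata.  Conditioning is idempotent.
* Strand handling: allele matching retries on the complementary strand;
  A/T and C/G SNPs are dropped by default (orientation unresolvable from
  alleles), exposed as a flag.
* When both a Z column and beta/se are present and disagree beyond 1e-6
  relative, beta/se wins with a warning (it is the primary statistic).
* Dosage work happens in float32 (int8 storage) for large panels; float64
  inputs and an explicit `dtype=float64` LD-score path keep reference-grade
  precision for small panels and oracle comparisons.
* Writers emit LF endings; summary statistics at `%.6g`, matrices at
  `%.6f`; effective-test counts print to one decimal in reports while JSON
  carries full precision.
* M in the slope scaling defaults to the regression SNP count; an external
  M (companion `.l2.M` file) is accepted as data, not computed.

## Known limitations

* The intercept estimator needs substantial sample overlap; with none its
  expectation is zero and conversion to a phenotypic correlation is
  refused.
* With known overlap `Ns`, `rp = intercept * sqrt(N1 N2)/Ns` is exact in
  expectation but inflates the SE by the same factor at small overlap.
* Pairwise-estimated matrices can be non-PSD; downstream consumers needing
  PSD should use the optional nearest-PSD projection knob rather than the
  default.
* The trait-QC heritability gate is meaningful only when LD scores carry
  real LD variation; on independent-SNP toy panels the degeneracy guard
  pins the heritability slope to 0 and such traits fail the gate by
  construction.
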
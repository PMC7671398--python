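# Methods

## The model

Two-sample MR treats genetic variants as instruments for an exposure–outcome
pair when only GWAS summary statistics are available. Given marginal
(single-variant) effect estimates γ̂ with standard errors Ŝ_γ from the
exposure GWAS, under polygenicity and large sample size the sampling
distribution of the vector γ̂ around the joint effects γ is approximately

    γ̂ | γ ~ N(Ŝ_γ R Ŝ_γ⁻¹ γ,  Ŝ_γ R Ŝ_γ),

where R is the LD correlation matrix of the variants. The same form holds
for the outcome statistics (Γ̂, Ŝ_Γ) around Γ. The structural link is
Γ = β₀γ (MR-LD) or Γ = β₀γ + α (MR-LDP), where β₀ is the causal effect and
α_k is variant k's direct (horizontally pleiotropic) effect on the outcome.
Independent Gaussian priors γ_k ~ N(0, σ_γ²), α_k ~ N(0, σ_α²) complete an
empirical-Bayes model whose parameters θ = {β₀, σ_γ², σ_α²} are estimated by
maximum marginal likelihood. Because R comes from a reference panel rather
than the GWAS samples, the likelihood is approximate; the approximation is
accurate when the panel matches the GWAS population and per-variant trait
correlations are small.

Key assumptions: (i) the two GWAS samples do not overlap; (ii) pleiotropic
effects are exchangeable across variants and independent of γ (an InSIDE-type
condition — directional pleiotropy correlated with instrument strength is
outside the model); (iii) the per-SNP standard errors are treated as known.

## LD estimation

R is modelled block-diagonally over a precomputed partition (e.g. LDetect
blocks, supplied as a BED-like table; the package consumes, never computes,
block boundaries). Per block the empirical dosage correlation R̂_emp from
the reference panel is replaced by the penalized estimate

    argmin_{R ≻ 0} ‖R − R̂_emp‖²_F/2 − τ log|R| + λ‖R⁻‖₁,

solved by proximal-gradient (ISTA) iteration with backtracking and
soft-thresholding of the off-diagonals; a block of size 1 uses the scalar
closed form (1+√(1+4τ))/2. The objective is strongly convex, so the
iteration converges linearly; we stop at relative objective change < 1e-12
(at most 2·10⁴ iterations). Parameters: λ ≥ 0 controls off-diagonal
sparsity/shrinkage — default 0.055 for simulation workflows and 0.1 for data
workflows; τ > 0 is only required to be small and defaults to 1e-3. The
barrier pushes the diagonal slightly above 1 (r_ii = 1 + τ(R⁻¹)_ii at
stationarity); downstream code uses the shrunk diagonal as-is, with no
renormalization, so the fitted likelihood matches the estimator output
exactly. Correctness is pinned to an independent convex-solver oracle in the
test suite rather than to a particular solver.

## PX-VBEM

The marginal likelihood integrates out 2p latent effects; a conventional EM
would invert R at O(p³) per iteration. Instead the posterior over (γ, α) is
approximated by a fully factorized Gaussian (mean-field), giving closed-form
coordinate updates, e.g.

    v_γk = (ξ² R_kk/ŝ²_γk + β₀² R_kk/ŝ²_Γk + 1/σ_γ²)⁻¹,

with the means combining both likelihood cross-terms minus LD-weighted
contributions of the other coordinates (Gauss–Seidel sweeps, γ then α,
blocks independent). The expansion parameter ξ scales the exposure mean
(γ̂ mean ξ·A_γγ); fitting it jointly and reducing at convergence
(γ' = ξγ ⇒ σ_γ'² = ξ²σ_γ², β₀' = β₀/ξ) removes the slow one-dimensional
drift that plain VBEM exhibits in this model. Given the factorized q, the
ELBO is separable in (ξ, β₀), so the M-step solves two scalar linear
equations plus the usual second-moment updates for σ_γ², σ_α².

Initialization is deterministic (μ_γ = γ̂, μ_α = 0, v = ŝ², σ_γ² = var(γ̂)/2,
σ_α² = 1e-4, β₀ = 0, ξ = 1); convergence is declared at relative ELBO change
< 1e-7 (both exposed as options). The ELBO is monotone across every E- and
M-step — this is asserted in the test suite on every fitted instance.

Degenerate inputs: MR-LD accepts p = 1; MR-LDP with a single variant cannot
separate β₀γ from α and is refused with an explanatory error.

## Calibrated inference

Mean-field VB underestimates posterior variance, so the ELBO cannot back a
likelihood-ratio test. Because every component here is Gaussian and R is
block-diagonal, the exact marginal log-likelihood is available in closed
form at O(Σ_b (2p_b)³): per block the observation vector (γ̂, Γ̂) is
zero-mean Gaussian with covariance assembled from Ŝ R Ŝ plus the prior
variances propagated through the mean maps. The causal test therefore:

1. fits the alternative (β₀ free) and the null (β₀ ≡ 0) by PX-VBEM;
2. **refines** each fit by directly maximizing the exact marginal
   log-likelihood over (β₀, log σ_γ², log σ_α²) with analytic gradients,
   warm-started at the reduced VB estimates;
3. forms 2(ℓ₁ − ℓ₀) from the two maximized exact log-likelihoods and refers
   it to χ²₁; the Wald standard error comes from the observed information
   (numerical Hessian of the analytic gradient, profile block of the
   inverse).

The refinement step is this package's design choice where the calibration
recipe was open: evaluating the exact likelihood *at* the VB estimates
already calibrates the test, but the VB point estimate itself carries a
small mean-field attenuation (the factorized posterior ignores the
γ_k–α_k coupling, which at moderate sample sizes biases β̂₀ toward zero by
about 2% of the effect in the dense-pleiotropy design below). Maximizing
the tractable exact likelihood removes that attenuation, guarantees a
nonnegative LRT (the null space is nested), and costs a few dozen cheap
likelihood evaluations. The VB stage still does the heavy lifting — it
supplies the posterior effect moments and a warm start a few steps from the
optimum. ℓ₁ is additionally floored at ℓ₀ as a numerical safeguard.

## The synthetic-data generator

The simulator emulates the full data-generating chain the model is meant
for: individual-level two-sample data reduced to summary statistics.

    x = G₁γ + U_x η_x + e₁,    y = β₀x₂ + G₂α + U_y η_y + e₂,

with genotype dosages in {0,1,2} produced by cutting a latent Gaussian with
block-autoregressive correlation Σ(ρ)_ij = ρ^|i−j| at the Hardy–Weinberg
thresholds for MAF f ~ U(0.05, 0.5) (one MAF vector shared by the exposure
sample, outcome sample and reference panel). The outcome sample's exposure
x₂ is generated from the same structural equation with the same confounder
matrix U_y used for y, preserving the within-sample confounding path; each
row of (η_x, η_y) is bivariate normal with unit variances and correlation
0.8, so naive regression of outcome on exposure is confounded while the
genetic instruments are not. Summary statistics are per-SNP univariate
regressions after mean-centering trait and dosages, with the squared
standard error using divisor exactly n.

Signal sizes are set through heritabilities on the outcome,
h_γ² = var(β₀Gγ)/var(y) and h_α² = var(Gα)/var(y) (defaults 0.1 and 0.05;
pleiotropy dense by default, sparse supports drawn uniformly). Scaling is
*empirical*: effect vectors and noise scales are solved against realized
variances on the generated sample (absorbing cross-covariances), so the
configured ratios hold per replicate, with var(y) normalized to 1. The
confounder share is fixed at 30% of the trait variance and the exposure's
non-genetic budget at 0.9, which reduces to var(x) = 1 under the null;
under β₀ ≠ 0 the exposure's genetic variance is whatever the outcome-side
target implies (strong instruments — p causal SNPs explaining most of x),
mirroring how a fixed mediated heritability forces instrument strength.
Under the null (β₀ = 0) the outcome-side ratio is identically zero, so
h_γ² is applied to the exposure side instead. Effects are scaled on raw
(uncentered-variance) dosages; genotype columns are not standardized.

What the generator does **not** emulate: real LD (blocks are stationary
AR(1), real blocks are not), allele-frequency/effect-size coupling,
population stratification, sample overlap, binary outcomes, and selection
of instruments through a screening study. Passing tests therefore certify
the estimator under the stated generative model, not robustness to these
real-data complications.

Default study conditions follow the simulation design the package targets:
n₁ = n₂ = 20 000 (reduced to 5000 in the replicated acceptance checks so
hundreds of replicates fit a desktop budget), n₃ = 500, M = 10 blocks of 50
SNPs, ρ ∈ {0, 0.4, 0.8} (default 0.4), q = 50 confounders, β₀ = 0.1,
λ = 0.055.

## Baselines

IVW (β = Σw_kγ̂_kΓ̂_k / Σw_kγ̂_k², w_k = ŝ_Γk⁻², se = (Σw_kγ̂_k²)^{-1/2}) and
MR-Egger (weighted regression of Γ̂ on γ̂ with a free intercept absorbing
directional pleiotropy; standard errors scale (XᵀWX)⁻¹ by the ML residual
variance RSS_w/n, with an optional multiplicative random-effects inflation
max(1, RSS_w/(n−2))). Both assume independent instruments, so a greedy
pruner visits SNPs by ascending priority p-value (normally from an
independent screening study) and keeps a SNP only if its squared correlation
with everything kept so far is below the threshold (default r² = 0.001 for
IVW/Egger-style comparisons; 0.05 for GSMR-style). Egger's estimate depends
on allele orientation; MR-LD/MR-LDP are orientation-invariant (asserted in
the tests).

## Harmonization rules

Studies are aligned to the reference panel's allele orientation: effect
signs flip when a study's effect allele is the panel's other allele;
variants whose allele pair cannot be matched even after swapping are
dropped; strand-ambiguous (A/T, C/G) variants are dropped by default (no
strand information is assumed; a flag retains them). Duplicate records
resolve to the smallest standard error. Instrument selection uses a third,
independent screening table (default Wald p < 1e-4) — never the exposure
study, which would induce winner's-curse selection bias.

## Numerical choices and limitations

- Convergence: relative ELBO change < 1e-7, max 10⁴ sweeps; refinement
  L-BFGS-B with analytic gradients, ftol 1e-15.
- Variance floors at 1e-12 prevent division blow-ups when σ_α² → 0 under no
  pleiotropy; a σ_α² estimate at the boundary is dropped from the observed
  information.
- Block processing is exact, not an approximation, because R is
  block-diagonal by construction.
- Ties at block boundaries: intervals are half-open [start, stop), so a
  boundary SNP belongs to the right-hand block.
- Known limitations: overlapping samples are not modelled; correlated
  (InSIDE-violating) pleiotropy biases all estimators here; the
  reference-panel likelihood is approximate, so a badly matched panel
  (wrong population, tiny n₃) degrades both estimate and test.
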
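# mrlink

Two-sample Mendelian randomization (MR) from GWAS summary statistics that
keeps **all** instrumental variants — including correlated ones — by modelling
linkage disequilibrium (LD) through a reference panel, and that stays valid
under pervasive **horizontal pleiotropy** by giving every variant a direct
outcome effect drawn from a random-effect prior. The package implements the
MR-LD model (LD-aware, no pleiotropy) and the MR-LDP model (LD-aware with
pleiotropy), fitted by a parameter-expanded variational-Bayes EM (PX-VBEM)
with a calibrated likelihood-ratio test for the causal effect.

It is written for statistical geneticists who have per-SNP marginal effects
and standard errors from an exposure GWAS and an outcome GWAS, plus reference
genotypes for LD — the standard two-sample MR setting where classical
estimators (IVW, MR-Egger) must first prune correlated SNPs and assume away
pleiotropy.

## Model

For `p` variants with marginal effect estimates and standard errors
(γ̂, Ŝ_γ) on the exposure and (Γ̂, Ŝ_Γ) on the outcome, and a block-diagonal
LD correlation matrix R̂ estimated from a reference panel,

    γ̂ | γ ~ N(Ŝ_γ R̂ Ŝ_γ⁻¹ γ,  Ŝ_γ R̂ Ŝ_γ)
    Γ̂ | γ, α ~ N(Ŝ_Γ R̂ Ŝ_Γ⁻¹ (β₀γ + α),  Ŝ_Γ R̂ Ŝ_Γ)
    γ_k ~ N(0, σ_γ²),   α_k ~ N(0, σ_α²)

where β₀ is the causal effect of the exposure on the outcome and α captures
horizontal pleiotropy (α ≡ 0 gives MR-LD). Each LD block of R̂ is a sparse
positive-definite shrinkage estimate,

    R̂ = argmin_{R ≻ 0}  ‖R − R̂_emp‖²_F / 2 − τ log|R| + λ‖R⁻‖₁ ,

with λ the shrinkage weight (0.055 for simulation workflows, 0.1–0.15 for
real data) and τ a small log-det barrier weight.

Fitting uses mean-field PX-VBEM: closed-form coordinate updates for the
Gaussian posteriors of γ and α, closed-form M-steps for
θ = {β₀, σ_γ², σ_α², ξ} (ξ is the expansion scale that accelerates EM), then
a reduction back to the ξ = 1 model. Because the model is linear-Gaussian
and block-diagonal, the *exact* marginal likelihood is tractable; the causal
test maximizes it from the VB solution and refers 2(ℓ₁ − ℓ₀) to χ²₁
("calibrated" likelihood-ratio test — the raw ELBO underestimates variance
and cannot be used directly).

## Worked example

```python
import mrlink

# a synthetic two-sample study: 500 SNPs in 10 LD blocks, moderate LD,
# true causal effect 0.1, dense pleiotropy at h2_alpha = 0.05
cfg = mrlink.SimulationConfig(n1=5000, n2=5000, n3=500, rho=0.4,
                              beta0=0.1, h2_alpha=0.05, seed=3)
data, R, truth = mrlink.make_dataset(cfg)          # summary stats + shrunk LD
res = mrlink.causal_test(data, R, model="mr-ldp")  # calibrated LRT
print(f"beta_hat = {res.beta_hat:.4f} (se {res.se_hat:.4f}), "
      f"LRT = {res.lrt_stat:.1f}, p = {res.p_value:.2e}")
```

Output:

```
beta_hat = 0.1032 (se 0.0063), LRT = 215.8, p = 7.28e-49
```

The estimate recovers the simulated causal effect (0.1) despite every SNP
having a direct pleiotropic outcome effect; the tiny p-value reflects the
strong simulated signal. `examples/` contains short scripts for each
capability (simulation and fitting, LD shrinkage, baseline comparison,
harmonizing summary tables); the same steps are available from the shell via
the `mrlink` command (`simulate`, `ldmat`, `harmonize`, `fit`, `baseline`,
`benchmark`).

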